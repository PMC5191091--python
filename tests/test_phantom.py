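"""Phantom geometry, diffusion solver and speckle statistics."""

from __future__ import annotations

import numpy as np
import pytest

from svoct import phantom
from svoct.phantom import (
    MAZSpec,
    PhantomConfig,
    build_static_phantom,
    cfl_substep_s,
    make_fixture,
    render_series,
    simulate_concentration,
)


class TestGeometry:
    def test_no_maz_plate_mask_is_full_band(self):
        cfg = PhantomConfig()
        truth = build_static_phantom(cfg)
        t_px = cfg.plate_thickness_px
        z = np.arange(cfg.grid_nz)[:, None]
        band = (z >= truth.surface_rows) & (z < truth.surface_rows + t_px)
        assert np.array_equal(truth.plate_mask, band)
        assert not truth.maz_mask.any()

    def test_maz_depth_in_pixels_matches_preset(self, single_maz_phantom):
        truth, cfg = single_maz_phantom
        zs, xs = np.nonzero(truth.maz_mask)
        apex_offset = zs.max() - truth.surface_rows[96]
        assert apex_offset == round(372.0 / 7.0) == 53

    def test_maz_aperture_spans_expected_columns(self, single_maz_phantom):
        truth, cfg = single_maz_phantom
        surf = truth.surface_rows[96]
        assert truth.maz_mask[surf].sum() == round(203.0 / 5.0) == 41

    @pytest.mark.parametrize(
        "maz_list",
        [
            (MAZSpec(10, 372.0, 203.0),),  # aperture past the left edge
            (MAZSpec(90, 372.0, 203.0), MAZSpec(110, 372.0, 203.0)),  # overlap
            (MAZSpec(96, 2000.0, 100.0),),  # deeper than the plate
        ],
    )
    def test_invalid_maz_configurations_rejected(self, maz_list):
        with pytest.raises(ValueError):
            build_static_phantom(PhantomConfig(maz_list=maz_list))


class TestDiffusion:
    def test_zero_diffusivity_confines_concentration_to_sources(self):
        cfg = PhantomConfig(
            maz_list=(MAZSpec(96, 372.0, 203.0),),
            diffusion_coefficient_um2_per_s=0.0,
        )
        truth = build_static_phantom(cfg)
        (c,) = simulate_concentration(truth, cfg, [5.0])
        src, _, strength = phantom._source_mask(truth)
        assert np.all(c[~src] == 0.0)
        assert np.all(c[src] == strength[src])

    def test_total_mass_nondecreasing_while_source_on(self):
        cfg = PhantomConfig(
            maz_list=(MAZSpec(96, 372.0, 203.0),),
            diffusion_coefficient_um2_per_s=500.0,
        )
        truth = build_static_phantom(cfg)
        fields = simulate_concentration(truth, cfg, [0.5, 1.0, 2.0, 4.0, 8.0])
        masses = [f.sum() for f in fields]
        assert np.all(np.diff(masses) >= 0)

    def test_matches_brute_force_stencil_on_small_grid(self):
        cfg = PhantomConfig(
            grid_nx=20,
            grid_nz=20,
            surface_row=2,
            plate_thickness_um=100.0,
            diffusion_coefficient_um2_per_s=50.0,
        )
        truth = build_static_phantom(cfg)
        dt = cfl_substep_s(cfg)
        t_end = 5 * dt
        (c_impl,) = simulate_concentration(truth, cfg, [t_end])

        # independent dense stencil: same explicit Euler scheme written as a
        # plain per-pixel loop with mirrored/absorbing ghost values
        src, t_act, strength = phantom._source_mask(truth)
        domain = truth.plate_mask
        nz, nx = domain.shape
        bed = np.zeros_like(domain)
        bed[np.arange(nz)[:, None] >= truth.bed_rows[None, :]] = True
        bed &= ~domain
        D = cfg.diffusion_coefficient_um2_per_s
        C = np.zeros((nz, nx))
        C[src] = strength[src]
        n_sub = int(np.ceil(t_end / dt))
        h = t_end / n_sub
        for _ in range(n_sub):
            new = C.copy()
            for z in range(nz):
                for x in range(nx):
                    if not domain[z, x]:
                        continue
                    lap = 0.0
                    for dz_, dx_, d2 in (
                        (-1, 0, cfg.pixel_dz_um**2),
                        (1, 0, cfg.pixel_dz_um**2),
                        (0, -1, cfg.pixel_dx_um**2),
                        (0, 1, cfg.pixel_dx_um**2),
                    ):
                        zz, xx = z + dz_, x + dx_
                        if 0 <= zz < nz and 0 <= xx < nx:
                            if domain[zz, xx]:
                                nb = C[zz, xx]
                            elif bed[zz, xx]:
                                nb = 0.0
                            else:
                                nb = C[z, x]
                        else:
                            nb = C[z, x]
                        lap += (nb - C[z, x]) / d2
                    new[z, x] = C[z, x] + D * h * lap
            new[~domain] = 0.0
            new[src] = strength[src]
            C = new
        assert np.max(np.abs(C - c_impl)) < 1e-8

    def test_mass_conserved_with_sources_off_and_closed_boundaries(self):
        cfg = PhantomConfig(diffusion_coefficient_um2_per_s=300.0)
        truth = build_static_phantom(cfg)
        c0 = np.zeros((cfg.grid_nz, cfg.grid_nx))
        zs = truth.surface_rows[96] + 20
        c0[zs : zs + 5, 90:100] = 1.0
        c0[~truth.plate_mask] = 0.0
        mass0 = c0.sum()
        fields = simulate_concentration(
            truth, cfg, [1.0, 3.0], sources_on=False, absorbing_bed=False,
            c_init=c0,
        )
        for f in fields:
            assert abs(f.sum() - mass0) < 1e-10 * mass0


class TestRendering:
    def test_static_noiseless_series_frames_identical(self):
        cfg = PhantomConfig(
            bulk_motion_sd_px=0.0, sensor_noise_sd=0.0,
            n_pre_frames=0, n_post_frames=5,
        )
        truth = build_static_phantom(cfg)
        conc = [np.zeros((cfg.grid_nz, cfg.grid_nx))] * 5
        series = render_series(truth, conc, cfg)
        ref = series.frames[0].intensity
        for f in series.frames[1:]:
            assert np.array_equal(f.intensity, ref)

    def test_maz_void_darker_than_plate_at_equal_depth(self):
        cfg = PhantomConfig(
            maz_list=(MAZSpec(96, 372.0, 203.0),),
            bulk_motion_sd_px=0.0, n_pre_frames=0, n_post_frames=1, seed=5,
        )
        truth = build_static_phantom(cfg)
        conc = [np.zeros((cfg.grid_nz, cfg.grid_nx))]
        img = render_series(truth, conc, cfg).frames[0].intensity
        rows = slice(truth.surface_rows[96] + 5, truth.surface_rows[96] + 25)
        void = img[rows, 90:103].mean()
        plate = img[rows, 10:40].mean()
        assert void < plate

    def test_deterministic_for_fixed_config_and_seed(self):
        a, _ = make_fixture("static", seed=3)
        b, _ = make_fixture("static", seed=3)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.intensity, fb.intensity)

    def test_frame_pair_correlation_matches_closed_form(self):
        # uniform reflectivity block, uniform concentration; the intensity
        # correlation between adjacent frames must equal exp(-gain*C*dt).
        # Row-wise correlation removes the deterministic depth structure.
        cfg = PhantomConfig(
            grid_nx=400, grid_nz=120, surface_row=5, plate_thickness_um=700.0,
            layer_reflectivities=(0.3, 0.3, 0.3, 0.3),
            bulk_motion_sd_px=0.0, sensor_noise_sd=0.0,
            attenuation_mu_per_um=0.0, decorrelation_gain=0.5,
            n_pre_frames=0, n_post_frames=10, seed=3,
        )
        truth = build_static_phantom(cfg)
        c_val = 0.8
        conc = [np.full((cfg.grid_nz, cfg.grid_nx), c_val)] * 10
        series = render_series(truth, conc, cfg)
        target = np.exp(-cfg.decorrelation_gain * c_val * cfg.frame_interval_s)
        rs = []
        for i in range(9):
            a = series.frames[i].intensity
            b = series.frames[i + 1].intensity
            for r in range(20, 90):
                rs.append(np.corrcoef(a[r], b[r])[0, 1])
        assert abs(np.mean(rs) - target) < 0.02

    def test_high_concentration_region_decorrelates_against_reference(self):
        # concentration confined to one MAZ wall: time-averaged |I_t - I_ref|
        # is strictly larger there than in a far-field plate block
        cfg = PhantomConfig(
            maz_list=(MAZSpec(96, 372.0, 203.0),),
            bulk_motion_sd_px=0.0, n_pre_frames=0, n_post_frames=20, seed=9,
        )
        truth = build_static_phantom(cfg)
        wall = np.zeros((cfg.grid_nz, cfg.grid_nx))
        src, _, _ = phantom._source_mask(truth)
        # only the crater wall (drop the surface row sources)
        wall_mask = src.copy()
        wall_mask[truth.surface_rows[0] : truth.surface_rows[0] + 1, :] = False
        wall[wall_mask] = 1.0
        conc = [wall] * 20
        series = render_series(truth, conc, cfg)
        ref = series.frames[0].intensity
        diffs = np.mean([np.abs(f.intensity - ref) for f in series.frames[1:]], axis=0)
        far = np.zeros_like(wall_mask)
        far[truth.surface_rows[20] + 10 : truth.surface_rows[20] + 40, 10:30] = True
        assert diffs[wall_mask].mean() > 2 * diffs[far].mean()


class TestFixtures:
    def test_static_preset_concentration_is_zero(self):
        _, truth = make_fixture("static", seed=0)
        assert all(c.max() == 0 for c in truth.concentration)

    def test_four_energies_ground_truth_depths(self):
        out = make_fixture("four_energies", seed=0)
        depths = [truth.maz_list[0].depth_um for _, truth in out]
        assert depths == [372.0, 321.0, 290.0, 255.0]

    def test_liquid_diffuses_faster_than_cream(self):
        liq = phantom.preset_config("liquid_like")
        crm = phantom.preset_config("cream_like")
        assert (
            liq.diffusion_coefficient_um2_per_s
            > crm.diffusion_coefficient_um2_per_s
        )
        assert liq.crater_fill_um_per_s > crm.crater_fill_um_per_s

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_fixture("gel_like")
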