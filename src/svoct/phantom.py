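"""Synthetic OCT nail phantom with dynamic speckle and drug diffusion.

The phantom emulates time-series B-scans of a layered human nail plate over
a nail bed, pierced by inverted-pyramid microthermal ablation zones (MAZs)
left by a fractional CO2 laser.  A diffusing particle-concentration field,
fed by constant-concentration sources on the MAZ walls and the exposed nail
surface, drives frame-to-frame speckle decorrelation and a shadowing factor
below high-concentration voxels — the two effects the downstream
speckle-variance pipeline is built to measure, here with known ground truth.

Speckle model: fully developed speckle as the intensity of a spatially
low-pass-filtered complex circular-Gaussian field (exponential marginal).
Temporal evolution mixes the underlying complex field AR(1)-style so that
the frame-to-frame *intensity* correlation is exactly
``rho = exp(-decorrelation_gain * C * dt)`` in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .oct_io import BScan, BScanSeries


@dataclass(frozen=True)
class MAZSpec:
    """One inverted-pyramid ablation zone: apex column, depth and top width."""

    apex_x_px: int
    depth_um: float
    top_width_um: float
    energy_mJ: float | None = None


# Per-energy geometry presets: (energy mJ, penetration depth um, aperture um).
ENERGY_PRESETS: tuple[tuple[float, float, float], ...] = (
    (50.0, 372.0, 203.0),
    (40.0, 321.0, 183.0),
    (30.0, 290.0, 171.0),
    (20.0, 255.0, 137.0),
)


@dataclass
class PhantomConfig:
    """Geometry, optics and dynamics of the synthetic nail experiment.

    Pixel spacings default to the system's transverse/axial resolutions of
    5 and 7 um.  ``decorrelation_gain`` maps local concentration to speckle
    decorrelation per second; ``shadow_gain`` attenuates signal below
    high-concentration voxels; ``diffusion_coefficient_um2_per_s`` is the
    scalar D of the particle field.
    """

    grid_nx: int = 192
    grid_nz: int = 150
    pixel_dx_um: float = 5.0
    pixel_dz_um: float = 7.0
    surface_row: int = 20
    surface_slope: float = 0.0  # rows per column (tilt)
    plate_thickness_um: float = 600.0
    # dorsal / intermediate / ventral plate sublayers, then nail bed
    layer_reflectivities: tuple[float, float, float, float] = (0.55, 0.45, 0.50, 0.35)
    background_reflectivity: float = 0.01
    maz_reflectivity: float = 0.02
    attenuation_mu_per_um: float = 0.0018
    transverse_resolution_um: float = 5.0
    axial_resolution_um: float = 7.0
    maz_list: tuple[MAZSpec, ...] = ()
    diffusion_coefficient_um2_per_s: float = 0.0
    source_strength: float = 1.0
    # drug fills an open crater top-down at this speed; a wall voxel becomes
    # a source once the fill front passes its depth (inf = instantly full)
    crater_fill_um_per_s: float = float("inf")
    # the intact dorsal surface is the nail's main permeation barrier, so
    # the exposed-surface source is weaker than the crater walls by this
    # factor (walls bypass the barrier entirely)
    surface_source_relative: float = 0.3
    decorrelation_gain: float = 0.35  # per unit concentration per second
    shadow_gain: float = 0.008  # per unit concentration per voxel above
    bulk_motion_sd_px: float = 0.3
    sensor_noise_sd: float = 0.002
    frame_interval_s: float = 0.5
    n_pre_frames: int = 5
    n_post_frames: int = 41
    seed: int = 0

    @property
    def plate_thickness_px(self) -> int:
        return int(round(self.plate_thickness_um / self.pixel_dz_um))

    def surface_rows(self) -> np.ndarray:
        x = np.arange(self.grid_nx)
        rows = np.round(self.surface_row + self.surface_slope * x).astype(int)
        return rows

    def validate(self) -> None:
        if self.grid_nx <= 0 or self.grid_nz <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_dx_um <= 0 or self.pixel_dz_um <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.plate_thickness_um <= 0:
            raise ValueError("plate thickness must be positive")
        rows = self.surface_rows()
        if rows.min() < 0 or rows.max() + self.plate_thickness_px >= self.grid_nz:
            raise ValueError("surface + plate thickness must fit inside the grid")
        if self.diffusion_coefficient_um2_per_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.decorrelation_gain < 0:
            raise ValueError("decorrelation gain must be >= 0")
        margin_um = 2 * self.pixel_dz_um
        intervals = []
        for maz in self.maz_list:
            if maz.depth_um <= 0 or maz.top_width_um <= 0:
                raise ValueError("MAZ depth and width must be positive")
            if maz.depth_um > self.plate_thickness_um + margin_um:
                raise ValueError("MAZ deeper than nail plate")
            half_w = maz.top_width_um / self.pixel_dx_um / 2.0
            lo, hi = maz.apex_x_px - half_w, maz.apex_x_px + half_w
            if lo < 0 or hi > self.grid_nx - 1:
                raise ValueError("MAZ aperture extends outside the grid")
            intervals.append((lo, hi))
        intervals.sort()
        for (a_lo, a_hi), (b_lo, b_hi) in zip(intervals, intervals[1:]):
            if b_lo <= a_hi:
                raise ValueError("overlapping MAZ apertures")


@dataclass
class GroundTruth:
    """Known phantom state against which every pipeline stage can be tested."""

    config: PhantomConfig
    reflectivity: np.ndarray  # [z][x] mean backscatter
    surface_rows: np.ndarray  # per-column surface row
    bed_rows: np.ndarray  # per-column plate/bed boundary row (first bed row)
    plate_mask: np.ndarray  # nail-plate tissue (MAZ interiors excluded)
    maz_mask: np.ndarray  # MAZ interiors (voids)
    maz_list: tuple[MAZSpec, ...] = ()
    concentration: list[np.ndarray] | None = None  # C(x,z,t) per frame time
    concentration_times_s: np.ndarray | None = None
    bulk_shifts_px: np.ndarray | None = None  # applied per-frame axial shift


def build_static_phantom(config: PhantomConfig) -> GroundTruth:
    """Lay out the reflectivity map, layer structure and MAZ voids.

    The plate band between the surface and the nail-bed boundary is split
    30/40/30 into dorsal/intermediate/ventral sublayers; each MAZ is a
    triangular (in cross-section) void whose aperture sits at the surface
    and whose apex lies ``depth_um`` below it.
    """
    config.validate()
    nz, nx = config.grid_nz, config.grid_nx
    surf = config.surface_rows()
    t_px = config.plate_thickness_px
    bed = surf + t_px

    z = np.arange(nz)[:, None]
    depth_px = z - surf[None, :]  # rows below local surface

    refl = np.full((nz, nx), config.background_reflectivity)
    d, m, v, b = config.layer_reflectivities
    frac = depth_px / t_px
    plate_band = (depth_px >= 0) & (depth_px < t_px)
    refl[plate_band & (frac < 0.3)] = d
    refl[plate_band & (frac >= 0.3) & (frac < 0.7)] = m
    refl[plate_band & (frac >= 0.7)] = v
    refl[depth_px >= t_px] = b

    maz_mask = np.zeros((nz, nx), dtype=bool)
    for maz in config.maz_list:
        depth = int(round(maz.depth_um / config.pixel_dz_um))
        half_w = maz.top_width_um / config.pixel_dx_um / 2.0
        s = surf[maz.apex_x_px]
        rows = np.arange(s, min(s + depth + 1, nz))
        for r in rows:
            hw = half_w * (1.0 - (r - s) / depth)
            cols = np.flatnonzero(np.abs(np.arange(nx) - maz.apex_x_px) <= hw)
            maz_mask[r, cols] = True
    refl[maz_mask] = config.maz_reflectivity

    plate_mask = plate_band & ~maz_mask
    return GroundTruth(
        config=config,
        reflectivity=refl,
        surface_rows=surf,
        bed_rows=bed,
        plate_mask=plate_mask,
        maz_mask=maz_mask,
        maz_list=tuple(config.maz_list),
    )


def _source_mask(truth: GroundTruth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drug-contact voxels, their activation times and their strengths.

    The exposed surface is wetted at t = 0 but holds only a fraction of the
    wall concentration (the intact dorsal layer is a barrier); a
    crater-wall voxel becomes a full-strength source once the top-down fill
    front (``crater_fill_um_per_s``) passes its depth below the local nail
    surface.  Returns ``(mask, t_active, strength)``.
    """
    cfg = truth.config
    src = np.zeros_like(truth.plate_mask)
    t_active = np.zeros(truth.plate_mask.shape)
    strength = np.zeros(truth.plate_mask.shape)
    # top plate row per column (exposed surface): active at t = 0.  Columns
    # inside an open aperture have their first plate voxel on the crater
    # wall instead — those are wall sources, gated by the fill front below.
    for x in range(cfg.grid_nx):
        col = np.flatnonzero(truth.plate_mask[:, x])
        if col.size and col[0] <= truth.surface_rows[x] + 2:
            src[col[0], x] = True
            strength[col[0], x] = cfg.surface_source_relative * cfg.source_strength
    # plate voxels 4-adjacent to a MAZ interior: active once filled
    if truth.maz_mask.any():
        wall = ndimage.binary_dilation(truth.maz_mask) & truth.plate_mask & ~src
        zz = np.arange(cfg.grid_nz)[:, None]
        depth_um = (zz - truth.surface_rows[None, :]) * cfg.pixel_dz_um
        fill = cfg.crater_fill_um_per_s
        t_wall = np.where(wall, np.maximum(depth_um, 0.0) / fill, 0.0)
        t_active = np.where(wall, t_wall, t_active)
        strength = np.where(wall, cfg.source_strength, strength)
        src |= wall
    return src, t_active, strength


def cfl_substep_s(config: PhantomConfig, safety: float = 0.9) -> float:
    """Largest stable explicit step for the 5-point diffusion stencil."""
    D = config.diffusion_coefficient_um2_per_s
    if D == 0:
        return np.inf
    dx2, dz2 = config.pixel_dx_um**2, config.pixel_dz_um**2
    return safety / (2.0 * D * (1.0 / dx2 + 1.0 / dz2))


def simulate_concentration(
    truth: GroundTruth,
    config: PhantomConfig,
    times: Sequence[float],
    sources_on: bool = True,
    absorbing_bed: bool = True,
    c_init: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Explicit finite-difference solution of dC/dt = D * laplacian(C).

    The domain is the nail-plate tissue; MAZ walls and the exposed surface
    hold constant concentration ``source_strength`` (Dirichlet), lateral
    and air-side boundaries are no-flux, and the nail-bed boundary absorbs
    (C = 0 below the plate).  For t <= 0 (pre-application) C is zero.  The
    solver internally sub-steps below the CFL limit; requested times need
    not be CFL-stable themselves.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be nondecreasing")
    cfg = config
    D = cfg.diffusion_coefficient_um2_per_s
    domain = truth.plate_mask
    if sources_on:
        src, t_active, src_strength = _source_mask(truth)
        src &= domain
    else:
        src = np.zeros_like(domain)
        t_active = np.zeros(domain.shape)
        src_strength = np.zeros(domain.shape)

    C = np.zeros(domain.shape) if c_init is None else np.array(c_init, dtype=float)
    dt_max = cfl_substep_s(cfg)

    # Per-direction neighbor handling: no-flux (mirror) everywhere except the
    # nail-bed side, which absorbs.  Precompute, for each shift direction,
    # which in-domain pixels have an out-of-domain neighbor and whether that
    # neighbor is bed (absorbing -> value 0) or not (no-flux -> value C).
    nz, nx = domain.shape
    bed_region = np.zeros_like(domain)
    cols = np.arange(nx)
    bed_region[(np.arange(nz)[:, None] >= truth.bed_rows[None, :])] = True
    bed_region &= ~domain

    shifts = {  # direction -> (axis, offset); neighbor at index + offset
        "up": (0, -1),
        "down": (0, +1),
        "left": (1, -1),
        "right": (1, +1),
    }
    inv_d2 = {"up": 1 / cfg.pixel_dz_um**2, "down": 1 / cfg.pixel_dz_um**2,
              "left": 1 / cfg.pixel_dx_um**2, "right": 1 / cfg.pixel_dx_um**2}

    def neighbor(arr: np.ndarray, axis: int, offset: int) -> np.ndarray:
        out = np.empty_like(arr)
        if axis == 0:
            if offset == -1:
                out[1:, :] = arr[:-1, :]
                out[0, :] = arr[0, :]
            else:
                out[:-1, :] = arr[1:, :]
                out[-1, :] = arr[-1, :]
        else:
            if offset == -1:
                out[:, 1:] = arr[:, :-1]
                out[:, 0] = arr[:, 0]
            else:
                out[:, :-1] = arr[:, 1:]
                out[:, -1] = arr[:, -1]
        return out

    neighbor_in = {}
    neighbor_bed = {}
    for name, (axis, off) in shifts.items():
        nb_dom = neighbor(domain.astype(float), axis, off) > 0.5
        nb_bed = neighbor(bed_region.astype(float), axis, off) > 0.5
        neighbor_in[name] = nb_dom
        neighbor_bed[name] = nb_bed & absorbing_bed

    results: list[np.ndarray] = []
    t_now = 0.0

    def apply_sources(t: float) -> None:
        active = src & (t_active <= t)
        C[active] = src_strength[active]

    apply_sources(0.0)
    for t_target in times:
        if t_target <= 0 or D == 0:
            if t_target <= 0:
                results.append(np.zeros_like(C))
            else:  # D == 0: concentration only at (active) source voxels
                out = np.zeros_like(C)
                active = src & (t_active <= t_target)
                out[active] = src_strength[active]
                results.append(out)
            continue
        span = t_target - max(t_now, 0.0)
        if span > 0:
            n_sub = max(1, int(np.ceil(span / dt_max)))
            dt = span / n_sub
            t_sub = max(t_now, 0.0)
            for _ in range(n_sub):
                lap = np.zeros_like(C)
                for name, (axis, off) in shifts.items():
                    nb = neighbor(C, axis, off)
                    # out-of-domain neighbors: bed -> 0 (absorbing), else mirror
                    nb = np.where(neighbor_in[name], nb,
                                  np.where(neighbor_bed[name], 0.0, C))
                    lap += (nb - C) * inv_d2[name]
                C = C + D * dt * lap
                C[~domain] = 0.0
                t_sub += dt
                apply_sources(t_sub)
            t_now = t_target
        results.append(C.copy())
    return results


def _speckle_kernel_norm(sigma_z: float, sigma_x: float, shape: tuple[int, int]) -> float:
    """L2 norm of the Gaussian PSF so filtered white noise keeps unit variance."""
    delta = np.zeros(shape)
    delta[shape[0] // 2, shape[1] // 2] = 1.0
    k = ndimage.gaussian_filter(delta, sigma=(sigma_z, sigma_x))
    return float(np.sqrt(np.sum(k**2)))


def render_series(
    truth: GroundTruth,
    concentrations: Sequence[np.ndarray],
    config: PhantomConfig,
    seed: int | None = None,
) -> BScanSeries:
    """Render intensity frames from structure, concentration and speckle.

    Per frame: intensity = reflectivity x exp(-mu * depth-below-surface)
    x cumulative shadow factor x speckle, plus additive sensor noise,
    clipped to [0, 1].  The complex speckle field is blended frame to frame
    so adjacent-frame intensity correlation is exp(-gain * C * dt); with
    C = 0 the speckle is frozen.  An integer bulk axial shift with sd
    ``bulk_motion_sd_px`` is applied per frame (0 for the reference frame).
    """
    cfg = config
    nz, nx = cfg.grid_nz, cfg.grid_nx
    n_total = cfg.n_pre_frames + cfg.n_post_frames
    if len(concentrations) != n_total:
        raise ValueError("one concentration field required per frame")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    sigma_z = cfg.axial_resolution_um / (2.355 * cfg.pixel_dz_um)
    sigma_x = cfg.transverse_resolution_um / (2.355 * cfg.pixel_dx_um)
    norm = _speckle_kernel_norm(sigma_z, sigma_x, (nz, nx))

    def fresh_field() -> np.ndarray:
        g = rng.normal(size=(nz, nx)) + 1j * rng.normal(size=(nz, nx))
        g *= np.sqrt(0.5)  # unit-power complex field
        re = ndimage.gaussian_filter(g.real, sigma=(sigma_z, sigma_x)) / norm
        im = ndimage.gaussian_filter(g.imag, sigma=(sigma_z, sigma_x)) / norm
        return re + 1j * im

    surf = truth.surface_rows
    depth_px = np.arange(nz)[:, None] - surf[None, :]
    atten = np.where(
        depth_px > 0,
        np.exp(-cfg.attenuation_mu_per_um * np.maximum(depth_px, 0) * cfg.pixel_dz_um),
        1.0,
    )
    structure = truth.reflectivity * atten

    dt = cfg.frame_interval_s
    timestamps = (np.arange(n_total) - cfg.n_pre_frames) * dt

    g = fresh_field()
    frames: list[BScan] = []
    shifts = np.zeros(n_total, dtype=int)
    for i in range(n_total):
        if i > 0:
            C = np.asarray(concentrations[i])
            rho_int = np.exp(-cfg.decorrelation_gain * C * dt)  # intensity corr
            a = np.sqrt(rho_int)  # field mixing coefficient
            if np.any(a < 1.0):
                g = a * g + np.sqrt(1.0 - a**2) * fresh_field()
            # a == 1 everywhere: frozen speckle, no new field drawn
        speckle = np.abs(g) ** 2

        # exclusive cumulative shadow below high-concentration voxels
        C = np.asarray(concentrations[i])
        csum_above = np.cumsum(C, axis=0) - C
        shadow = np.exp(-cfg.shadow_gain * csum_above)

        img = structure * shadow * speckle
        if cfg.sensor_noise_sd > 0:
            img = img + rng.normal(0.0, cfg.sensor_noise_sd, size=img.shape)

        if i != cfg.n_pre_frames and cfg.bulk_motion_sd_px > 0:
            k = int(round(rng.normal(0.0, cfg.bulk_motion_sd_px)))
        else:
            k = 0
        shifts[i] = k
        if k != 0:
            shifted = np.zeros_like(img)
            if k > 0:
                shifted[k:, :] = img[:-k, :]
            else:
                shifted[:k, :] = img[-k:, :]
            img = shifted

        img = np.clip(img, 0.0, 1.0)
        frames.append(BScan(img, cfg.pixel_dz_um, cfg.pixel_dx_um, float(timestamps[i])))

    truth.bulk_shifts_px = shifts
    truth.concentration = [np.asarray(c) for c in concentrations]
    truth.concentration_times_s = timestamps
    meta = {"seed": int(cfg.seed if seed is None else seed),
            "frame_interval_s": cfg.frame_interval_s,
            "source": "svoct phantom"}
    return BScanSeries(frames, reference_index=cfg.n_pre_frames, metadata=meta)


def _three_maz_config(**overrides) -> PhantomConfig:
    # 50 mJ craters at a 360 um pitch (aperture 203 um, ~155 um of intact
    # plate between neighbouring apertures)
    maz = tuple(
        MAZSpec(apex_x_px=x, depth_um=372.0, top_width_um=203.0, energy_mJ=50.0)
        for x in (60, 132, 204)
    )
    base = dict(grid_nx=264, maz_list=maz)
    base.update(overrides)
    return PhantomConfig(**base)


PRESETS = ("liquid_like", "cream_like", "static", "four_energies")

# Emulation dynamics chosen from diffusion-length arithmetic (see methods
# note): Region II sits ~85 um under the surface source and Region III
# ~160 um from the nearest MAZ wall, so t ~ L^2/4D puts liquid onsets near
# 1 s and cream onsets near 2-4 s — the phenomenology being emulated.  The
# crater fill velocities make the 372 um craters fill in ~1 s (liquid) vs
# ~2.5 s (cream), giving a descending SV front whose center of mass drops
# faster for the liquid.
D_LIQUID_UM2_S = 1800.0
D_CREAM_UM2_S = 900.0
FILL_LIQUID_UM_S = 400.0
FILL_CREAM_UM_S = 150.0


def make_fixture(preset_name: str, seed: int = 0):
    """Build a ready-made phantom experiment.

    ``liquid_like`` / ``cream_like``: three 50 mJ MAZs with a diffusing
    source field, liquid having the larger diffusion coefficient (earlier
    onset).  ``static``: identical geometry, no drug.  ``four_energies``:
    four single-MAZ scans with the per-energy depth/width presets; returns
    a list of (series, truth) pairs.
    """
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; choose from {PRESETS}")

    if preset_name == "four_energies":
        out = []
        for i, (energy, depth, width) in enumerate(ENERGY_PRESETS):
            cfg = PhantomConfig(
                maz_list=(MAZSpec(96, depth, width, energy),),
                diffusion_coefficient_um2_per_s=0.0,
                source_strength=0.0,
                n_pre_frames=2,
                n_post_frames=3,
                seed=seed + i,
            )
            truth = build_static_phantom(cfg)
            n = cfg.n_pre_frames + cfg.n_post_frames
            conc = [np.zeros((cfg.grid_nz, cfg.grid_nx))] * n
            out.append((render_series(truth, conc, cfg), truth))
        return out

    cfg = preset_config(preset_name, seed=seed)
    truth, conc = preset_concentration(cfg)
    series = render_series(truth, conc, cfg, seed=seed)
    return series, truth


def preset_concentration(cfg: PhantomConfig) -> tuple[GroundTruth, list[np.ndarray]]:
    """Geometry and concentration history for a config (seed-independent).

    The diffusion solution is deterministic, so multi-seed experiments can
    solve it once and re-render the speckle with different seeds.
    """
    truth = build_static_phantom(cfg)
    dt = cfg.frame_interval_s
    times = (np.arange(cfg.n_pre_frames + cfg.n_post_frames) - cfg.n_pre_frames) * dt
    if cfg.diffusion_coefficient_um2_per_s > 0 and cfg.source_strength > 0:
        conc = simulate_concentration(truth, cfg, times)
    else:
        conc = [np.zeros((cfg.grid_nz, cfg.grid_nx))] * len(times)
    return truth, conc


def preset_config(preset_name: str, seed: int = 0) -> PhantomConfig:
    """The PhantomConfig behind a dynamic preset (liquid/cream/static)."""
    if preset_name == "liquid_like":
        return _three_maz_config(
            diffusion_coefficient_um2_per_s=D_LIQUID_UM2_S,
            crater_fill_um_per_s=FILL_LIQUID_UM_S,
            seed=seed,
        )
    if preset_name == "cream_like":
        return _three_maz_config(
            diffusion_coefficient_um2_per_s=D_CREAM_UM2_S,
            crater_fill_um_per_s=FILL_CREAM_UM_S,
            seed=seed,
        )
    if preset_name == "static":
        return _three_maz_config(
            diffusion_coefficient_um2_per_s=0.0,
            source_strength=0.0,
            n_pre_frames=5,
            n_post_frames=21,
            seed=seed,
        )
    raise ValueError(f"no single config for preset {preset_name!r}")


def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Persist ground-truth arrays as a compressed npz + JSON-able config."""
    import json

    path = Path(path).with_suffix(".npz")
    np.savez_compressed(
        path,
        reflectivity=truth.reflectivity,
        surface_rows=truth.surface_rows,
        bed_rows=truth.bed_rows,
        plate_mask=truth.plate_mask,
        maz_mask=truth.maz_mask,
        bulk_shifts_px=truth.bulk_shifts_px if truth.bulk_shifts_px is not None else np.array([]),
    )
    meta = {
        "maz_list": [vars(m) for m in truth.maz_list],
        "config": {k: v for k, v in vars(truth.config).items() if k != "maz_list"},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
    return path
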