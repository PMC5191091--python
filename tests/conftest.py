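"""Shared fixtures: phantoms, rendered series and cached preset solutions."""

from __future__ import annotations

import numpy as np
import pytest

from svoct import phantom
from svoct.oct_io import BScan


def noise_free_bscan(truth, cfg) -> BScan:
    """Deterministic intensity image: structure and attenuation, no speckle."""
    depth_px = np.arange(cfg.grid_nz)[:, None] - truth.surface_rows[None, :]
    atten = np.where(
        depth_px > 0,
        np.exp(-cfg.attenuation_mu_per_um * np.maximum(depth_px, 0) * cfg.pixel_dz_um),
        1.0,
    )
    return BScan(
        np.clip(truth.reflectivity * atten, 0, 1),
        cfg.pixel_dz_um,
        cfg.pixel_dx_um,
        0.0,
    )


@pytest.fixture(scope="session")
def preset_cache():
    """Per-preset (config, truth, concentration) solved once for the session."""
    cache = {}

    def get(name: str):
        if name not in cache:
            cfg = phantom.preset_config(name)
            truth, conc = phantom.preset_concentration(cfg)
            cache[name] = (cfg, truth, conc)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def liquid_run(preset_cache):
    from svoct.pipeline import run_pipeline

    cfg, truth, conc = preset_cache("liquid_like")
    series = phantom.render_series(truth, conc, cfg, seed=11)
    return run_pipeline(series), truth


@pytest.fixture(scope="session")
def static_run(preset_cache):
    from svoct.pipeline import run_pipeline

    cfg, truth, conc = preset_cache("static")
    series = phantom.render_series(truth, conc, cfg, seed=11)
    return run_pipeline(series), truth


@pytest.fixture()
def flat_phantom():
    cfg = phantom.PhantomConfig(surface_row=40, grid_nz=160)
    return phantom.build_static_phantom(cfg), cfg


@pytest.fixture()
def single_maz_phantom():
    cfg = phantom.PhantomConfig(maz_list=(phantom.MAZSpec(96, 372.0, 203.0, 50.0),))
    return phantom.build_static_phantom(cfg), cfg
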