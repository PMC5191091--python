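"""Detection and measurement of laser microthermal ablation zones (MAZs).

An MAZ appears in a B-scan as a low-backscatter inverted-pyramid void open
to the nail surface.  Candidates are connected low-intensity regions (below
a fraction of the frame's Otsu threshold) touching the surface aperture;
each is measured for penetration depth (surface to apex, axial) and
aperture diameter (transverse extent at the surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .oct_io import BScan
from .segmentation import SurfaceProfile


@dataclass
class MAZCandidate:
    """A connected surface-open low-intensity region proposed as an MAZ."""

    mask: np.ndarray
    merged: bool = False  # True when touching candidates were fused


@dataclass
class MAZMeasurement:
    apex_x_px: int
    apex_z_px: int
    penetration_depth_um: float
    diameter_um: float
    energy_label_mJ: float | None = None

    def __post_init__(self) -> None:
        if self.penetration_depth_um < 0 or self.diameter_um < 0:
            raise ValueError("depth and diameter must be nonnegative")


def detect_mazs(
    bscan: BScan,
    surface: SurfaceProfile,
    min_depth_um: float = 50.0,
    min_width_um: float = 25.0,
    otsu_fraction: float = 0.5,
    max_search_depth_um: float = 500.0,
    smooth_sigma_px: float = 1.0,
    refine_sigma_px: float = 0.5,
) -> list[MAZCandidate]:
    """Find candidate MAZs open to the surface.

    The intensity is lightly smoothed, thresholded at
    ``otsu_fraction * Otsu``, restricted to a band below the surface, and
    connected components reaching the surface aperture with sufficient
    depth and width are kept.  Touching components are merged (and flagged).
    The threshold is relative, so detection is invariant to a global
    intensity rescale.
    """
    img = ndimage.gaussian_filter(
        bscan.intensity, sigma=(smooth_sigma_px, smooth_sigma_px)
    )
    thr = otsu_fraction * threshold_otsu(img)
    nz, nx = img.shape
    z = np.arange(nz)[:, None]
    surf = surface.surface_row[None, :]
    max_off = int(round(max_search_depth_um / bscan.pixel_dz_um))
    band = (z >= surf) & (z < surf + max_off)
    low = (img < thr) & band

    # close single-pixel gaps, then merge touching components
    low = ndimage.binary_closing(low, structure=np.ones((3, 3)))
    lab, n = ndimage.label(low, structure=np.ones((3, 3), dtype=int))
    min_depth_px = min_depth_um / bscan.pixel_dz_um
    min_width_px = min_width_um / bscan.pixel_dx_um

    candidates: list[MAZCandidate] = []
    for i in range(1, n + 1):
        mask = lab == i
        zs, xs = np.nonzero(mask)
        # must be open to the surface (reach within 2 px of the local surface)
        surf_rows = surface.surface_row[xs]
        if np.min(zs - surf_rows) > 2:
            continue
        depth_px = np.max(zs - surf_rows)
        width_px = xs.max() - xs.min() + 1
        if depth_px < min_depth_px or width_px < min_width_px:
            continue
        candidates.append(MAZCandidate(mask=mask))

    # refine boundaries on a lightly smoothed image: heavy smoothing is
    # robust for detection but erodes the 1-px apex and the aperture edges;
    # the refinement is bounded to a 3-px dilation of the candidate
    if refine_sigma_px is not None and refine_sigma_px < smooth_sigma_px:
        fine = ndimage.gaussian_filter(
            bscan.intensity, sigma=(refine_sigma_px, refine_sigma_px)
        )
        fine_low = (fine < otsu_fraction * threshold_otsu(fine)) & band
        for c in candidates:
            halo = ndimage.binary_dilation(c.mask, iterations=3)
            c.mask = c.mask | (halo & fine_low)

    # one candidate per aperture: fuse candidates whose transverse extents
    # come closer than the minimum credible aperture width, and flag them
    candidates.sort(key=lambda c: np.nonzero(c.mask)[1].min())
    merged: list[MAZCandidate] = []
    for c in candidates:
        xs = np.nonzero(c.mask)[1]
        if merged:
            prev_xs = np.nonzero(merged[-1].mask)[1]
            if xs.min() - prev_xs.max() < min_width_px:
                merged[-1] = MAZCandidate(
                    mask=merged[-1].mask | c.mask, merged=True
                )
                continue
        merged.append(c)
    return merged


def measure_maz(
    bscan: BScan,
    surface: SurfaceProfile,
    candidate: MAZCandidate,
    energy_label_mJ: float | None = None,
) -> MAZMeasurement:
    """Measure penetration depth and surface-aperture diameter of a candidate.

    Depth = (deepest candidate row - local surface row) * axial pitch;
    diameter = transverse extent of the candidate at the surface row *
    transverse pitch.  A degenerate one-pixel candidate reports one pixel
    pitch in each axis.
    """
    zs, xs = np.nonzero(candidate.mask)
    if zs.size == 0:
        raise ValueError("empty candidate")
    rel = zs - surface.surface_row[xs]
    if np.min(rel) > 2:
        raise ValueError("candidate detached from the surface")
    deepest = int(np.argmax(rel))
    apex_z = int(zs[deepest])
    apex_x = int(xs[deepest])
    depth_px = max(int(rel[deepest]), 1)

    at_surface = xs[rel <= 2]
    if at_surface.size == 0:
        at_surface = xs[rel == rel.min()]
    width_px = int(at_surface.max() - at_surface.min() + 1)

    return MAZMeasurement(
        apex_x_px=apex_x,
        apex_z_px=apex_z,
        penetration_depth_um=depth_px * bscan.pixel_dz_um,
        diameter_um=width_px * bscan.pixel_dx_um,
        energy_label_mJ=energy_label_mJ,
    )


def summarize_by_energy(measurements: list[MAZMeasurement]) -> pd.DataFrame:
    """Per-energy mean +/- sd of depth and diameter, sorted by energy.

    Single measurements report sd 0; an empty input yields an empty table.
    """
    cols = ["energy_mJ", "n", "mean_depth_um", "sd_depth_um",
            "mean_diameter_um", "sd_diameter_um"]
    if not measurements:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "energy_mJ": [m.energy_label_mJ for m in measurements],
            "depth_um": [m.penetration_depth_um for m in measurements],
            "diameter_um": [m.diameter_um for m in measurements],
        }
    )
    g = df.groupby("energy_mJ", dropna=False)
    out = pd.DataFrame(
        {
            "energy_mJ": g.size().index,
            "n": g.size().values,
            "mean_depth_um": g["depth_um"].mean().values,
            "sd_depth_um": g["depth_um"].std(ddof=1).fillna(0.0).values,
            "mean_diameter_um": g["diameter_um"].mean().values,
            "sd_diameter_um": g["diameter_um"].std(ddof=1).fillna(0.0).values,
        }
    )
    return out.sort_values("energy_mJ").reset_index(drop=True)
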