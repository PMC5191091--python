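"""Nail-surface segmentation, series realignment and plate masking.

The drug film on the nail adds a spurious optical path length, so before
speckle variance is computed every frame is realigned axially, per column,
to the surface of the reference frame.  The surface detector is an
Otsu-threshold first-crossing refined to the strongest local axial
gradient, then median-filtered across columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .oct_io import BScan, BScanSeries


@dataclass
class SurfaceProfile:
    """Per-column surface row (pixels) with per-column validity flags.

    Columns where no surface could be established are interpolated from
    valid neighbours and flagged invalid rather than guessed silently.
    """

    surface_row: np.ndarray  # int, per column
    valid: np.ndarray  # bool, per column

    def __post_init__(self) -> None:
        self.surface_row = np.asarray(self.surface_row, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.surface_row.shape != self.valid.shape:
            raise ValueError("surface_row and valid must have equal length")


@dataclass
class NailMask:
    """Nail-plate pixel mask with an MAZ-interior inclusion policy.

    ``exclude_maz`` (liquid experiment: the drug-filled craters are not part
    of the SV estimate) removes MAZ interiors from the plate mask;
    ``include_maz`` (cream experiment) retains them.
    """

    plate: np.ndarray
    maz_interior: np.ndarray
    policy: str

    POLICIES = ("exclude_maz", "include_maz")

    def __post_init__(self) -> None:
        if self.policy not in self.POLICIES:
            raise ValueError(f"unknown mask policy {self.policy!r}")

    @property
    def effective(self) -> np.ndarray:
        """The mask actually applied to SV images under the stated policy."""
        if self.policy == "include_maz":
            return self.plate | self.maz_interior
        return self.plate & ~self.maz_interior


def detect_surface(
    bscan: BScan,
    min_prominence: float = 0.05,
    smooth_window: int = 7,
    threshold: float | None = None,
) -> SurfaceProfile:
    """Detect the air/nail interface row in every A-scan.

    Per column: axially smooth the intensity, find the first row exceeding
    an adaptive threshold (Otsu over the frame, or a frozen ``threshold``
    so a whole series is detected consistently), refine to the strongest
    positive axial gradient within +/-2 px, and require that gradient to
    reach ``min_prominence``.  The profile is median-filtered across
    columns (window ``smooth_window``) and isolated failures interpolated.
    """
    img = bscan.intensity
    nz, nx = img.shape
    # axial + light lateral smoothing: the interface is transversely smooth
    smoothed = ndimage.gaussian_filter(img, sigma=(1.5, 1.5))
    if smoothed.max() <= 0:
        raise ValueError("no surface found: image has no positive signal")
    if threshold is not None:
        thr = threshold
    else:
        try:
            thr = threshold_otsu(smoothed)
        except ValueError as exc:  # constant image
            raise ValueError(
                "no surface found: degenerate intensity histogram"
            ) from exc

    grad = np.diff(smoothed, axis=0, prepend=smoothed[:1])
    rows = np.zeros(nx, dtype=int)
    valid = np.zeros(nx, dtype=bool)
    above = smoothed >= thr
    for x in range(nx):
        idx = np.flatnonzero(above[:, x])
        if idx.size == 0:
            continue
        r = idx[0]
        lo, hi = max(r - 2, 0), min(r + 3, nz)
        r_ref = lo + int(np.argmax(grad[lo:hi, x]))
        if grad[r_ref, x] >= min_prominence:
            rows[x] = r_ref
            valid[x] = True
    if not valid.any():
        raise ValueError("no surface found in any column")

    if not valid.all():
        xs = np.arange(nx)
        rows = np.round(
            np.interp(xs, xs[valid], rows[valid].astype(float))
        ).astype(int)
    if smooth_window > 1:
        rows = ndimage.median_filter(rows, size=smooth_window, mode="nearest")
    return SurfaceProfile(rows, valid)


def nail_envelope(
    surface: SurfaceProfile, max_aperture_px: int = 49
) -> SurfaceProfile:
    """The nail surface proper, with MAZ crater walls removed.

    The per-A-scan detector follows the true air/tissue interface, which
    dips into open ablation craters.  A grey-scale morphological opening of
    the row profile removes downward spikes narrower than
    ``max_aperture_px`` while preserving tilt, recovering the plate's
    dorsal surface across the apertures.
    """
    rows = ndimage.grey_opening(
        surface.surface_row, size=max_aperture_px, mode="nearest"
    )
    return SurfaceProfile(rows, surface.valid.copy())


def realign_series(
    series: BScanSeries,
    reference_surface: SurfaceProfile | None = None,
    max_shift_fraction: float = 0.25,
    global_shift: bool = False,
    shift_smooth_window: int = 31,
    detector_kwargs: dict | None = None,
) -> tuple[BScanSeries, np.ndarray]:
    """Shift every frame axially, per column, onto the reference surface.

    Integer-pixel shifts only (subpixel interpolation would itself change
    intensities and contaminate SV); vacated rows are zero-filled.  Frames
    whose required shift exceeds ``max_shift_fraction`` of the image depth
    in any column are flagged motion-corrupted (True in the returned flag
    array) and passed through unshifted.

    With ``global_shift`` a single median shift is applied to all columns.
    """
    kw = detector_kwargs or {}
    if "threshold" not in kw:
        # freeze the detection threshold on the reference frame so the
        # drug-induced histogram drift cannot move crossings coherently
        sm = ndimage.gaussian_filter(series.reference.intensity, sigma=(1.5, 1.5))
        kw = dict(kw, threshold=float(threshold_otsu(sm)))
    if reference_surface is None:
        reference_surface = detect_surface(series.reference, **kw)
    nz = series.shape[0]
    cap = int(max_shift_fraction * nz)
    ref_rows = reference_surface.surface_row

    # columns inside open craters have no stable nail surface; their shifts
    # are interpolated from the flanking intact-surface columns
    envelope = nail_envelope(reference_surface).surface_row
    crater_cols = ref_rows > envelope + 1
    # keep anchors clear of the steep crater walls, where detection jitters
    crater_cols = ndimage.binary_dilation(crater_cols, iterations=4)
    intact = ~crater_cols
    if not intact.any():
        crater_cols[:] = False
        intact = ~crater_cols
    xs = np.arange(ref_rows.size)

    new_frames = []
    flags = np.zeros(len(series), dtype=bool)
    for i, frame in enumerate(series.frames):
        surf = detect_surface(frame, **kw)
        shifts = ref_rows - surf.surface_row  # +ve: move content down
        if global_shift:
            shifts = np.full_like(shifts, int(np.median(shifts)))
        else:
            # bulk motion is global and the surface transversely smooth:
            # median-filter the intact-column shifts (removing per-column
            # detector jitter), then carry them across the craters
            v = shifts[intact].astype(float)
            if shift_smooth_window > 1 and v.size:
                v = ndimage.median_filter(
                    v, size=min(shift_smooth_window, v.size), mode="nearest"
                )
            shifts = np.round(np.interp(xs, xs[intact], v)).astype(int)
        if np.max(np.abs(shifts)) > cap:
            flags[i] = True
            new_frames.append(frame)
            continue
        if np.all(shifts == 0):
            new_frames.append(frame)
            continue
        img = frame.intensity
        out = np.zeros_like(img)
        for k in np.unique(shifts):
            cols = shifts == k
            if k == 0:
                out[:, cols] = img[:, cols]
            elif k > 0:
                out[k:, cols] = img[:-k, cols]
            else:
                out[:k, cols] = img[-k:, cols]
        new_frames.append(
            BScan(out, frame.pixel_dz_um, frame.pixel_dx_um, frame.timestamp_s)
        )
    realigned = BScanSeries(
        new_frames, series.reference_index, dict(series.metadata, realigned=True)
    )
    return realigned, flags


def detect_nail_bed(
    bscan: BScan,
    surface: SurfaceProfile,
    expected_thickness_um: float = 600.0,
    tolerance_um: float = 105.0,
    lateral_smooth_px: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the plate/bed boundary row per column.

    The boundary is the strongest negative axial intensity gradient within
    ``expected_thickness +/- tolerance`` below the local surface, median
    filtered across columns.  Columns with no negative extremum fall back
    to the expected thickness and are flagged.

    Returns ``(boundary_rows, fallback_flags)``.
    """
    img = ndimage.gaussian_filter(
        bscan.intensity, sigma=(1.5, max(lateral_smooth_px / 2, 0.5))
    )
    nz, nx = img.shape
    dz = bscan.pixel_dz_um
    lo_off = int(round((expected_thickness_um - tolerance_um) / dz))
    hi_off = int(round((expected_thickness_um + tolerance_um) / dz))
    exp_off = int(round(expected_thickness_um / dz))
    if lo_off >= nz:
        raise ValueError("expected-thickness window lies outside the image")

    grad = np.diff(img, axis=0, append=img[-1:])

    # stage 1: global boundary offset from the median surface-aligned
    # gradient profile (robust to per-column speckle)
    offsets = np.arange(lo_off, hi_off + 1)
    profiles = np.full((offsets.size, nx), np.nan)
    for x in range(nx):
        rows_x = surface.surface_row[x] + offsets
        ok = rows_x < nz
        profiles[ok, x] = grad[rows_x[ok], x]
    med_profile = np.nanmedian(profiles, axis=1)
    if np.all(np.isnan(med_profile)) or np.nanmin(med_profile) >= 0:
        global_off = exp_off
        global_found = False
    else:
        global_off = int(offsets[np.nanargmin(med_profile)])
        global_found = True

    # stage 2: per-column refinement within +/-3 px of the global boundary
    rows = np.zeros(nx, dtype=int)
    flagged = np.zeros(nx, dtype=bool)
    for x in range(nx):
        s = surface.surface_row[x]
        lo = max(s + global_off - 3, 0)
        hi = min(s + global_off + 4, nz)
        if not global_found or lo >= hi or lo >= nz:
            rows[x] = min(s + exp_off, nz - 1)
            flagged[x] = True
            continue
        window = grad[lo:hi, x]
        j = int(np.argmin(window))
        if window[j] >= 0:
            rows[x] = min(s + global_off, nz - 1)
            flagged[x] = True
        else:
            rows[x] = lo + j
    rows = ndimage.median_filter(rows, size=7, mode="nearest")
    return rows, flagged


def build_mask(
    surface: SurfaceProfile,
    bed_boundary: np.ndarray,
    maz_interior: np.ndarray,
    policy: str,
) -> NailMask:
    """Assemble the nail-plate mask between surface and bed under a policy."""
    if policy not in NailMask.POLICIES:
        raise ValueError(f"unknown mask policy {policy!r}")
    nz, nx = maz_interior.shape
    z = np.arange(nz)[:, None]
    band = (z >= surface.surface_row[None, :]) & (z < np.asarray(bed_boundary)[None, :])
    plate = band & ~maz_interior
    return NailMask(plate=plate, maz_interior=maz_interior & band, policy=policy)


def averaged_ascan_profile(
    bscan: BScan, x_center: int, n_adjacent: int = 11
) -> np.ndarray:
    """Mean depth profile over ``n_adjacent`` A-scans centred at a column.

    The default of 11 adjacent A-scans corresponds to a transverse range of
    about 50 um at 5 um pixel pitch.
    """
    half = n_adjacent // 2
    lo, hi = x_center - half, x_center + half + 1
    if n_adjacent < 1 or lo < 0 or hi > bscan.shape[1]:
        raise ValueError("A-scan averaging window out of bounds")
    return bscan.intensity[:, lo:hi].mean(axis=1)
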