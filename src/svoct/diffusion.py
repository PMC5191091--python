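"""ROI time courses, onset/saturation timing and SV center-of-mass descent.

Three depth ranges are monitored, mirroring the published region scheme:
Region I squares sit at the MAZ tips, Region II squares in the upper nail
away from the apertures, and Region III squares midway between MAZ pairs
at mid-plate depth.  Per region the summed SV over each square is averaged
(mean +/- sd across the three squares) at every time point; the SV-weighted
mean depth (center of mass) below the surface tracks the advancing drug
front, and its descent rate compares formulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .oct_io import BScanSeries
from .segmentation import NailMask, SurfaceProfile
from .speckle_variance import SVImage

REGION_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class Square:
    """An axis-aligned ROI square: half-open pixel ranges [z0:z1), [x0:x1)."""

    z0: int
    z1: int
    x0: int
    x1: int

    @property
    def area_px(self) -> int:
        return (self.z1 - self.z0) * (self.x1 - self.x0)


@dataclass
class ROISet:
    """Labeled ROI squares (up to three per region) inside the plate mask."""

    regions: dict[str, list[Square]]
    square_size_px: int

    def __post_init__(self) -> None:
        for label in self.regions:
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")


@dataclass
class TimeCourse:
    """Per-region averaged SV summations and COM depth vs time."""

    times_s: np.ndarray
    region_mean: dict[str, np.ndarray]
    region_sd: dict[str, np.ndarray]
    com_depth_um: np.ndarray
    total_sv: np.ndarray | None = None
    baseline_mean: dict[str, float] = field(default_factory=dict)
    baseline_sd: dict[str, float] = field(default_factory=dict)
    onset_s: dict[str, float | None] = field(default_factory=dict)
    saturation_s: dict[str, float | None] = field(default_factory=dict)

    @property
    def region_labels(self) -> list[str]:
        return list(self.region_mean)


def _clip_square(z0, z1, x0, x1, shape) -> Square:
    nz, nx = shape
    return Square(max(z0, 0), min(z1, nz), max(x0, 0), min(x1, nx))


def place_rois(
    mask: NailMask,
    surface: SurfaceProfile,
    maz_apices: list[tuple[int, int]],
    square_size_px: int = 10,
    upper_depth_px: int = 12,
    mid_depth_px: int | None = None,
) -> ROISet:
    """Place the three-region ROI scheme relative to MAZ apices.

    ``maz_apices`` are (x, z) apex pixel positions.  Region I squares are
    centred at the apices; Region II squares at a shallow depth below the
    surface between/flanking the apertures; Region III squares midway
    between MAZ pairs at mid-plate depth.  Fewer than two MAZs omit
    Region III.  All squares are clipped to the image and must intersect
    the plate mask.
    """
    if not maz_apices:
        raise ValueError("ROI placement needs at least one MAZ apex")
    shape = mask.plate.shape
    h = square_size_px // 2
    s = square_size_px

    def centered(x: int, z: int) -> Square:
        return _clip_square(z - h, z - h + s, x - h, x - h + s, shape)

    apices = sorted(maz_apices)
    regions: dict[str, list[Square]] = {"I": [], "II": []}
    for x, z in apices[:3]:
        regions["I"].append(centered(x, z))

    # Region II: upper nail, lateral midpoints between/outside apertures
    xs = [x for x, _ in apices]
    mids = [(a + b) // 2 for a, b in zip(xs, xs[1:])]
    span = max(xs) - min(xs) if len(xs) > 1 else shape[1] // 4
    candidates_x = ([min(xs) - span // len(xs)] + mids + [max(xs) + span // len(xs)])
    for x in candidates_x[:3]:
        x = int(np.clip(x, h, shape[1] - h - 1))
        z = int(surface.surface_row[x]) + upper_depth_px
        regions["II"].append(centered(x, z))

    if len(apices) >= 2:
        if mid_depth_px is None:
            plate_rows = np.nonzero(mask.plate.any(axis=1))[0]
            mid_depth_px = int((plate_rows.max() - surface.surface_row.mean()) // 2)
        pair_mids = mids + [(min(xs) + max(xs)) // 2]
        regions["III"] = []
        for x in pair_mids[:3]:
            z = int(surface.surface_row[int(x)]) + mid_depth_px
            regions["III"].append(centered(int(x), z))

    for label, squares in regions.items():
        for sq in squares:
            if not mask.plate[sq.z0 : sq.z1, sq.x0 : sq.x1].any():
                raise ValueError(f"Region {label} square falls outside the plate mask")
    return ROISet(regions=regions, square_size_px=square_size_px)


def _square_sums(sv: np.ndarray, squares: list[Square]) -> np.ndarray:
    return np.array([sv[s.z0 : s.z1, s.x0 : s.x1].sum() for s in squares])


def roi_timecourse(
    sv_series: list[SVImage],
    rois: ROISet,
    mask: NailMask | None = None,
    surface: SurfaceProfile | None = None,
    pixel_dz_um: float = 1.0,
    baseline_sv: list[SVImage] | None = None,
) -> TimeCourse:
    """Mean +/- sd of the per-square summed SV for each region and time.

    When ``mask``/``surface`` are given the SV center-of-mass depth (um
    below the local surface) is computed per frame; frames with zero total
    SV yield NaN.  ``baseline_sv`` (pre-application SV images processed
    identically) sets the onset baseline per region.
    """
    if not sv_series:
        raise ValueError("empty SV series")
    shape = sv_series[0].shape
    for label, squares in rois.regions.items():
        for sq in squares:
            if sq.z1 > shape[0] or sq.x1 > shape[1]:
                raise ValueError("ROI square outside the image")

    times = np.array([s.timestamp_s for s in sv_series])
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for label, squares in rois.regions.items():
        sums = np.stack([_square_sums(s.sv, squares) for s in sv_series])
        mean[label] = sums.mean(axis=1)
        sd[label] = sums.std(axis=1, ddof=0)

    com = np.full(len(sv_series), np.nan)
    total = None
    if mask is not None and surface is not None:
        com = np.array(
            [sv_center_of_mass_frame(s, mask, surface, pixel_dz_um) for s in sv_series]
        )
        m = mask.effective
        total = np.array([np.where(m, s.sv, 0.0).sum() for s in sv_series])

    tc = TimeCourse(
        times_s=times, region_mean=mean, region_sd=sd, com_depth_um=com,
        total_sv=total,
    )

    if baseline_sv is not None:
        for label, squares in rois.regions.items():
            base = np.stack([_square_sums(s.sv, squares) for s in baseline_sv]) if baseline_sv else np.zeros((1, len(squares)))
            per_time = base.mean(axis=1)
            tc.baseline_mean[label] = float(per_time.mean())
            tc.baseline_sd[label] = float(per_time.std(ddof=0))
    for label in tc.region_mean:
        b_mean = tc.baseline_mean.get(label, 0.0)
        b_sd = tc.baseline_sd.get(label, 0.0)
        curve = tc.region_mean[label]
        tc.onset_s[label] = (
            onset_time(times, curve, b_mean, b_sd) if curve.size >= 2 else None
        )
        tc.saturation_s[label] = (
            saturation_time(times, curve, baseline=b_mean)
            if curve.size >= 10
            else None
        )
    return tc


def onset_time(
    times: np.ndarray,
    curve: np.ndarray,
    baseline_mean: float = 0.0,
    baseline_sd: float = 0.0,
    n_consecutive: int = 2,
) -> float | None:
    """First time the curve exceeds baseline mean + 3 sd for >= 2 samples.

    Returns None when the curve never sustains an exceedance.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < n_consecutive:
        raise ValueError("curve shorter than the consecutive-sample requirement")
    thresh = baseline_mean + 3.0 * baseline_sd
    above = curve > thresh
    for i in range(curve.size - n_consecutive + 1):
        if above[i : i + n_consecutive].all():
            return float(times[i])
    return None


def saturation_time(
    times: np.ndarray,
    curve: np.ndarray,
    baseline: float = 0.0,
    plateau_fraction: float = 0.95,
    hold_fraction: float = 0.90,
    tail_fraction: float = 0.10,
) -> float | None:
    """Time the curve first reaches 95% of its plateau and holds >= 90%.

    The plateau is the mean of the final 10% of samples; undefined (None)
    when the plateau does not rise above the baseline.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 10:
        raise ValueError("saturation estimation needs >= 10 samples")
    n_tail = max(1, int(np.ceil(tail_fraction * curve.size)))
    plateau = float(curve[-n_tail:].mean())
    if plateau <= baseline:
        return None
    hold = hold_fraction * plateau
    target = plateau_fraction * plateau
    for i in range(curve.size):
        if curve[i] >= target and np.all(curve[i:] >= hold):
            return float(times[i])
    return None


def sv_center_of_mass_frame(
    sv: SVImage,
    mask: NailMask,
    surface: SurfaceProfile,
    pixel_dz_um: float,
) -> float:
    """SV-weighted mean depth (um below the local surface) of one frame."""
    m = mask.effective
    w = np.where(m, sv.sv, 0.0)
    total = w.sum()
    if total == 0:
        return np.nan
    z = np.arange(sv.shape[0])[:, None]
    depth_px = z - surface.surface_row[None, :]
    return float((w * depth_px).sum() / total * pixel_dz_um)


def sv_center_of_mass(
    sv_series: list[SVImage],
    mask: NailMask,
    surface: SurfaceProfile,
    pixel_dz_um: float,
) -> np.ndarray:
    """COM depth trajectory over a thresholded SV series (NaN when SV sums to 0)."""
    return np.array(
        [sv_center_of_mass_frame(s, mask, surface, pixel_dz_um) for s in sv_series]
    )


def com_descent_rate(
    times: np.ndarray,
    com_depth_um: np.ndarray,
    onset_s: float | None = None,
    window_s: float = 10.0,
    weights: np.ndarray | None = None,
    anchor_origin: bool = False,
) -> float:
    """Slope (um/s) of the COM depth over the post-onset descent window.

    The fit covers ``window_s`` seconds after onset — beyond that the
    process saturates (cumulative decorrelation is irreversible) and a
    longer window measures the plateau, not the front velocity.  With
    ``weights`` (typically the frame's total SV) the fit is weighted least
    squares, since the COM of a frame with little suprathreshold SV is
    correspondingly unreliable.  ``anchor_origin`` constrains the line
    through (onset, depth 0): before any SV has accumulated the COM sits at
    the surface by definition, and the anchored slope is the mean descent
    velocity rather than a free local tangent.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(com_depth_um, dtype=float)
    keep = np.isfinite(c)
    if onset_s is not None:
        keep &= t >= onset_s
        if np.isfinite(window_s):
            keep &= t <= onset_s + window_s
    if keep.sum() < 2:
        return np.nan
    w = np.ones(keep.sum()) if weights is None else np.asarray(weights, float)[keep]
    sw = np.sqrt(np.maximum(w, 0.0))
    tt = t[keep] - (onset_s or 0.0)
    if anchor_origin:
        num = float(np.sum(sw**2 * tt * c[keep]))
        den = float(np.sum(sw**2 * tt**2))
        return num / den if den > 0 else np.nan
    A = np.vstack([tt, np.ones(keep.sum())]).T * sw[:, None]
    slope, _ = np.linalg.lstsq(A, c[keep] * sw, rcond=None)[0]
    return float(slope)


@dataclass
class FormulationComparison:
    onset_diff_s: dict[str, float | None]
    saturation_diff_s: dict[str, float | None]
    com_rate_a_um_s: float
    com_rate_b_um_s: float

    @property
    def com_rate_ratio(self) -> float:
        return self.com_rate_a_um_s / self.com_rate_b_um_s


def compare_formulations(tc_a: TimeCourse, tc_b: TimeCourse) -> FormulationComparison:
    """Compare two formulations' time courses on a common time grid.

    Onset/saturation differences are a - b per region; the COM descent
    rates are least-squares slopes over each course's post-onset window and
    reported as the a/b ratio (> 1 means a penetrates faster).
    """
    t_lo = max(tc_a.times_s.min(), tc_b.times_s.min())
    t_hi = min(tc_a.times_s.max(), tc_b.times_s.max())
    if t_hi <= t_lo:
        raise ValueError("time courses do not overlap in time")

    def diff(da: dict, db: dict) -> dict[str, float | None]:
        out = {}
        for label in set(da) & set(db):
            a, b = da.get(label), db.get(label)
            out[label] = None if a is None or b is None else float(a - b)
        return out

    horizon = min(10.0, t_hi)
    rate_a = com_descent_rate(
        tc_a.times_s, tc_a.com_depth_um, onset_s=0.0, window_s=horizon,
        weights=tc_a.total_sv, anchor_origin=True,
    )
    rate_b = com_descent_rate(
        tc_b.times_s, tc_b.com_depth_um, onset_s=0.0, window_s=horizon,
        weights=tc_b.total_sv, anchor_origin=True,
    )
    return FormulationComparison(
        onset_diff_s=diff(tc_a.onset_s, tc_b.onset_s),
        saturation_diff_s=diff(tc_a.saturation_s, tc_b.saturation_s),
        com_rate_a_um_s=rate_a,
        com_rate_b_um_s=rate_b,
    )
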