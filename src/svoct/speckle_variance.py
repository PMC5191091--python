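"""Two-frame speckle variance with shadow correction and noise thresholding.

Each post-application frame I_tn is compared against the reference frame
I_t0 acquired at drug application.  With m = (I_t0 + I_tn)/2 the per-pixel
speckle variance is

    SV(x,z) = sqrt( ((I_t0 - m)^2 + (I_tn - m)^2) / 2 )  =  |I_t0 - I_tn| / 2.

Shadowing under strong scatterers (aggregated drug particles) suppresses SV
at depth; the correction rescales each pixel by an exponential of the
depth-cumulative SV of the same frame,

    SVR(x,z) = SV(x,z) * exp( sign * (1/gamma) * sum_{i=1..z} SV(x,i) ),

with attenuation coefficient gamma.  The printed form uses a positive
exponent; because the stated purpose is to *reduce* the shadowing effect
the sign is configurable, the positive print being the default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .oct_io import BScan, BScanSeries
from .segmentation import NailMask

STAGES = ("raw", "shadow_corrected", "thresholded")


@dataclass
class SVImage:
    """A speckle-variance map with its processing provenance."""

    sv: np.ndarray
    stage: str
    timestamp_s: float
    reference_timestamp_s: float
    gamma: float | None = None
    exponent_sign: int | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"unknown SV stage {self.stage!r}")
        if np.any(self.sv < 0):
            raise ValueError("speckle variance must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sv.shape


@dataclass
class ShadowCorrectionParams:
    """Shadow-correction settings: gamma, exponent sign and an amplification cap.

    ``gamma=None`` selects the per-frame automatic value: 10x the median
    (over columns) of the depth-integrated raw SV, keeping the correction
    factor of order e^0.1.  The cap bounds the multiplicative factor to
    avoid runaway amplification deep in shadowed columns.
    """

    gamma: float | None = None
    exponent_sign: int = +1
    amplification_cap: float = float(np.exp(3.0))

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.exponent_sign not in (+1, -1):
            raise ValueError("exponent_sign must be +1 or -1")
        if self.amplification_cap < 1:
            raise ValueError("amplification cap must be >= 1")


def compute_sv(reference: BScan, frame: BScan) -> SVImage:
    """Two-frame speckle variance of a frame against the reference."""
    if frame.shape != reference.shape:
        raise ValueError("frame and reference shapes differ")
    a = reference.intensity
    b = frame.intensity
    m = 0.5 * (a + b)
    sv = np.sqrt(0.5 * ((a - m) ** 2 + (b - m) ** 2))
    return SVImage(
        sv=sv,
        stage="raw",
        timestamp_s=frame.timestamp_s,
        reference_timestamp_s=reference.timestamp_s,
    )


def auto_gamma(sv: np.ndarray) -> float | None:
    """Per-frame gamma: 10x median column-wise depth-integrated raw SV.

    Returns None when the frame carries no SV at all (no correction
    meaningful, factor collapses to 1).
    """
    col_integral = sv.sum(axis=0)
    med = float(np.median(col_integral))
    return 10.0 * med if med > 0 else None


def shadow_correct(sv: SVImage, params: ShadowCorrectionParams | None = None) -> SVImage:
    """Apply the depth-cumulative shadow correction to a raw SV image."""
    if params is None:
        params = ShadowCorrectionParams()
    if sv.stage != "raw":
        raise ValueError("shadow correction expects a raw SV image")
    gamma = params.gamma if params.gamma is not None else auto_gamma(sv.sv)
    if gamma is None:
        # zero-SV frame: correction factor is identically exp(0) = 1
        return replace(sv, stage="shadow_corrected", gamma=np.inf,
                       exponent_sign=params.exponent_sign)
    csum = np.cumsum(sv.sv, axis=0)  # inclusive of row z
    factor = np.exp(params.exponent_sign * csum / gamma)
    factor = np.minimum(factor, params.amplification_cap)
    return replace(
        sv,
        sv=sv.sv * factor,
        stage="shadow_corrected",
        gamma=float(gamma),
        exponent_sign=params.exponent_sign,
    )


def estimate_noise_threshold(
    pre_series: BScanSeries, policy: str = "paper_fixed", percentile: float = 99.0
) -> float:
    """Noise-floor SV threshold from pre-application frames.

    ``paper_fixed`` returns the published constant 0.05 (valid for
    normalized linear intensity in [0, 1]); ``percentile`` returns the
    given percentile of raw SV pooled over every pre-application frame
    compared against the reference.
    """
    if policy == "paper_fixed":
        return 0.05
    if policy != "percentile":
        raise ValueError(f"unknown threshold policy {policy!r}")
    pre = pre_series.pre_application()
    if len(pre) < 2:
        raise ValueError("percentile policy needs >= 2 pre-application frames")
    ref = pre_series.reference
    vals = np.concatenate([compute_sv(ref, f).sv.ravel() for f in pre])
    return float(np.percentile(vals, percentile))


def apply_threshold(
    sv: SVImage, threshold: float, mask: NailMask | np.ndarray | None = None
) -> SVImage:
    """Zero SV below the noise floor and outside the nail mask."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = sv.sv.copy()
    out[out < threshold] = 0.0
    if mask is not None:
        m = mask.effective if isinstance(mask, NailMask) else np.asarray(mask, bool)
        if m.shape != out.shape:
            raise ValueError("mask shape differs from SV image")
        out[~m] = 0.0
    return replace(sv, sv=out, stage="thresholded", threshold=float(threshold))


def sv_series(
    series: BScanSeries,
    params: ShadowCorrectionParams | None = None,
    mask: NailMask | np.ndarray | None = None,
    threshold: float | str = "paper_fixed",
) -> list[SVImage]:
    """Full SV pipeline over the post-application frames of a realigned series.

    For each frame strictly after the reference: raw SV vs the reference,
    shadow correction, then thresholding.  ``threshold`` may be a number or
    a policy name for :func:`estimate_noise_threshold`.
    """
    if isinstance(threshold, str):
        threshold = estimate_noise_threshold(series, policy=threshold)
    ref = series.reference
    out = []
    for frame in series.post_application():
        sv = compute_sv(ref, frame)
        sv = shadow_correct(sv, params)
        sv = apply_threshold(sv, threshold, mask)
        out.append(sv)
    return out
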