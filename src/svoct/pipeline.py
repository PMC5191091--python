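"""End-to-end analysis: realign -> segment -> SV -> morphometry -> diffusion.

This is the programmatic equivalent of the command-line ``run`` command and
the canonical wiring used by the analysis drivers: everything is computed
from a B-scan series alone (ground truth, when available, is only for
validation in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import diffusion as dq
from . import morphometry as maz
from . import segmentation as seg
from . import speckle_variance as svm
from .oct_io import BScanSeries


@dataclass
class PipelineResult:
    series: BScanSeries  # realigned
    surface: seg.SurfaceProfile
    bed_rows: np.ndarray
    mask: seg.NailMask
    maz_measurements: list[maz.MAZMeasurement]
    sv_images: list[svm.SVImage]
    baseline_sv: list[svm.SVImage]
    threshold: float
    timecourse: dq.TimeCourse | None
    motion_flags: np.ndarray
    params: dict = field(default_factory=dict)


def run_pipeline(
    series: BScanSeries,
    mask_policy: str = "exclude_maz",
    threshold_policy: str | float = "paper_fixed",
    shadow_params: svm.ShadowCorrectionParams | None = None,
    expected_thickness_um: float = 600.0,
    square_size_px: int = 10,
    quantify: bool = True,
) -> PipelineResult:
    """Run the full trans-nail diffusion analysis on one B-scan series."""
    realigned, flags = seg.realign_series(series)
    ref = realigned.reference
    interface = seg.detect_surface(ref)  # true air/tissue interface
    surface = seg.nail_envelope(interface)  # nail surface across craters
    bed_rows, _ = seg.detect_nail_bed(
        ref, surface, expected_thickness_um=expected_thickness_um
    )

    candidates = maz.detect_mazs(ref, surface)
    measurements = [maz.measure_maz(ref, surface, c) for c in candidates]
    maz_interior = np.zeros(ref.shape, dtype=bool)
    for c in candidates:
        maz_interior |= c.mask
    mask = seg.build_mask(surface, bed_rows, maz_interior, mask_policy)

    if isinstance(threshold_policy, str):
        threshold = svm.estimate_noise_threshold(realigned, policy=threshold_policy)
    else:
        threshold = float(threshold_policy)

    sv_images = svm.sv_series(realigned, shadow_params, mask, threshold)
    baseline_sv = [
        svm.apply_threshold(
            svm.shadow_correct(svm.compute_sv(ref, f), shadow_params), threshold, mask
        )
        for f in realigned.pre_application()
    ]

    timecourse = None
    if quantify and measurements and sv_images:
        apices = [(m.apex_x_px, m.apex_z_px) for m in measurements]
        rois = dq.place_rois(mask, surface, apices, square_size_px=square_size_px)
        timecourse = dq.roi_timecourse(
            sv_images,
            rois,
            mask=mask,
            surface=surface,
            pixel_dz_um=series.pixel_dz_um,
            baseline_sv=baseline_sv,
        )

    return PipelineResult(
        series=realigned,
        surface=surface,
        bed_rows=bed_rows,
        mask=mask,
        maz_measurements=measurements,
        sv_images=sv_images,
        baseline_sv=baseline_sv,
        threshold=threshold,
        timecourse=timecourse,
        motion_flags=flags,
        params={
            "mask_policy": mask_policy,
            "threshold_policy": threshold_policy,
            "threshold": threshold,
            "square_size_px": square_size_px,
            "expected_thickness_um": expected_thickness_um,
        },
    )
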