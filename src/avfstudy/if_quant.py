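"""Immunofluorescence intensity quantification (FIU, mean gray value).

Marker expression is read out as fluorescence intensity units: the arithmetic
mean gray value of the pixels inside an ROI on the max-projected image,
corrected by subtracting the mean gray measured on the same specimen's
primary-antibody control with the same ROIs.  Subtraction (rather than a
ratio) is the default correction; ``ratio=True`` is available since the
underlying protocol statement admits either reading.  Negative corrected
values are retained, not clamped, so that group means stay unbiased; they are
flagged in the output.

ROIs come from the same geometric engine as the PLA analysis (endothelial
bands plus media circles), keeping the two assays' compartment definitions
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pla_quant import ImageStack, ROI, max_project
from .stats import timecourse_summary

__all__ = [
    "IntensityMeasurement",
    "mean_gray",
    "correct_fiu",
    "measure_if_specimen",
    "marker_timecourse",
]


@dataclass(frozen=True)
class IntensityMeasurement:
    """One corrected intensity readout for a specimen compartment."""

    rat_id: str
    day: int
    marker: str
    compartment: str
    fiu_raw: float
    fiu_control: float
    fiu_corrected: float
    negative_flag: bool = False


def mean_gray(image, roi: ROI) -> float:
    """Arithmetic mean gray value inside an ROI.

    ``image`` may be a 2-D array, a ``(z, rows, cols)`` array or an
    :class:`ImageStack`; stacks are max-projected first.
    """
    img = max_project(image)
    if img.shape != roi.mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    if not roi.mask.any():
        raise ValueError(f"ROI {roi.roi_id!r} mask is empty")
    return float(img[roi.mask].mean())


def correct_fiu(fiu_raw: float, fiu_control: float, ratio: bool = False) -> float:
    """Control-corrected FIU: raw minus primary-antibody-control mean gray.

    With ``ratio=True`` returns raw / control instead (control must then be
    positive).  Negative differences are returned as-is.
    """
    if ratio:
        if not fiu_control > 0:
            raise ValueError("ratio correction needs a positive control FIU")
        return float(fiu_raw) / float(fiu_control)
    return float(fiu_raw) - float(fiu_control)


def measure_if_specimen(
    marker_stack: ImageStack,
    control_stack: ImageStack,
    rois,
    keys: dict | None = None,
    ratio: bool = False,
) -> pd.DataFrame:
    """Quantify one immunofluorescence specimen against its control.

    Per compartment, the raw FIU is the mean of the per-ROI mean gray values
    on the marker image; the control FIU is measured identically on the
    primary-antibody control.  Returns one row per compartment with
    ``fiu_raw, fiu_control, fiu_corrected, negative_flag`` plus the ``keys``.
    """
    if control_stack is None:
        raise ValueError(f"missing primary-antibody control for {keys or '<unnamed>'}")
    marker_img = max_project(marker_stack)
    control_img = max_project(control_stack)
    rows = []
    for compartment in ("endothelium", "media"):
        comp_rois = [r for r in rois if r.compartment == compartment]
        if not comp_rois:
            continue
        raw = float(np.mean([mean_gray(marker_img, r) for r in comp_rois]))
        ctrl = float(np.mean([mean_gray(control_img, r) for r in comp_rois]))
        corrected = correct_fiu(raw, ctrl, ratio=ratio)
        row = dict(keys or {})
        row.update(
            compartment=compartment,
            fiu_raw=raw,
            fiu_control=ctrl,
            fiu_corrected=corrected,
            negative_flag=corrected < 0,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def marker_timecourse(
    measurements: pd.DataFrame,
    baseline_day: int = -1,
    value: str = "fiu_corrected",
) -> pd.DataFrame:
    """Per-marker, per-compartment, per-day mean +/- SE of corrected FIU with
    percent change versus the baseline-day group mean.

    ``measurements`` is long-format with at least ``marker, compartment, day``
    and the value column (one row per specimen and compartment); the baseline
    day must be present.
    """
    return timecourse_summary(
        measurements, value=value, by=["marker", "compartment"],
        baseline_day=baseline_day,
    )
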