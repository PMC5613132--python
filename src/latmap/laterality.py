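"""Adaptive-threshold laterality index and hemispheric extent statistics.

The laterality index (LI) quantifies hemispheric dominance of task activity
from suprathreshold voxel counts in paired left/right ROIs::

    LI = 100 * (L - R) / (L + R)

where the per-subject threshold adapts to the individual's activation level:
it is 50% of the mean of the top 5% of Z values in the ROI pair.  +100 means
complete left dominance, -100 complete right dominance, and -33 <= LI <= 33
is read as bilateral organization.

The same adaptive thresholding applied to whole-hemisphere masks yields the
spatial *extent* of activation (total suprathreshold voxel count), used to
test whether bilateral language organization entails more diffuse processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import RoiMask, RoiPair, StatMap

#: |LI| <= band is classified bilateral (band inclusive on both ends)
BILATERAL_BAND = 33.0
#: fraction of ROI voxels entering the "top activation" mean
TOP_FRACTION = 0.05
#: the threshold is this fraction of the top-activation mean
THRESHOLD_FRACTION = 0.5
#: Edinburgh handedness cutoffs: >= +40 right-handed, <= -40 left-handed
EHI_CUTOFF = 40.0

LABELS = ("left_typical", "bilateral", "right_atypical")
THRESHOLD_SOURCES = ("max", "left", "right", "union")


class LateralityError(ValueError):
    """Raised when a laterality quantity is undefined for the input."""


@dataclass(frozen=True)
class AdaptiveThreshold:
    mean_top5: float
    value: float
    source_side: str


@dataclass(frozen=True)
class LateralityResult:
    subject_id: str
    n_left: int
    n_right: int
    threshold: AdaptiveThreshold
    li: float
    label: str


@dataclass(frozen=True)
class ExtentResult:
    n_voxels: int
    roi_label: str
    threshold: float


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    ehi_score: float
    sex: str
    age: float

    @property
    def handedness(self) -> str:
        return classify_handedness(self.ehi_score)


def _top_mean(values: np.ndarray, top_fraction: float) -> float:
    """Mean of the top ceil(fraction * n) values (never fewer than one)."""
    n = values.size
    k = max(1, math.ceil(top_fraction * n))
    top = np.partition(values, n - k)[n - k:]
    return float(top.mean())


def adaptive_threshold(
    statmap: StatMap,
    rois: RoiPair,
    top_fraction: float = TOP_FRACTION,
    threshold_fraction: float = THRESHOLD_FRACTION,
    source: str = "max",
) -> AdaptiveThreshold:
    """Per-subject activation threshold from the ROI pair.

    For each side the top ``top_fraction`` of Z values (at least one voxel)
    are averaged; ``source`` selects which side's mean anchors the threshold:

    * ``"max"`` (default) — the larger of the two side means, i.e. the
      dominant side sets the threshold; mirror-symmetric and deterministic;
    * ``"left"`` / ``"right"`` — that side's mean regardless of dominance;
    * ``"union"`` — the top fraction of the pooled left+right voxels.

    The threshold itself is ``threshold_fraction`` times that mean.  Raises
    :class:`LateralityError` when the anchoring mean is not positive (no
    positive activation in the ROI pair).
    """
    if source not in THRESHOLD_SOURCES:
        raise ValueError(f"source must be one of {THRESHOLD_SOURCES}")
    if statmap.shape != rois.left.data.shape:
        raise LateralityError("ROI masks are not on the map grid")
    left_mean = _top_mean(statmap.data[rois.left.data], top_fraction)
    right_mean = _top_mean(statmap.data[rois.right.data], top_fraction)
    if source == "left":
        mean_top, side = left_mean, "left"
    elif source == "right":
        mean_top, side = right_mean, "right"
    elif source == "union":
        pooled = statmap.data[rois.left.data | rois.right.data]
        mean_top = _top_mean(pooled, top_fraction)
        side = "left" if left_mean >= right_mean else "right"
    else:  # max of sides
        if left_mean >= right_mean:
            mean_top, side = left_mean, "left"
        else:
            mean_top, side = right_mean, "right"
    if mean_top <= 0:
        raise LateralityError("no positive activation in ROI pair")
    return AdaptiveThreshold(mean_top5=mean_top, value=threshold_fraction * mean_top,
                             source_side=side)


def count_suprathreshold(statmap: StatMap, mask: RoiMask, thr: float) -> int:
    """Number of mask voxels with Z strictly above ``thr``."""
    if statmap.shape != mask.data.shape:
        raise LateralityError("mask is not on the map grid")
    return int(np.count_nonzero(statmap.data[mask.data] > thr))


def laterality_index(n_left: int, n_right: int) -> float:
    """LI = 100 (L - R) / (L + R); undefined (raises) when L + R = 0."""
    if n_left < 0 or n_right < 0:
        raise ValueError("voxel counts must be non-negative")
    total = n_left + n_right
    if total == 0:
        raise LateralityError("no suprathreshold voxels in either ROI")
    return 100.0 * (n_left - n_right) / total


def classify_laterality(li: float, band: float = BILATERAL_BAND) -> str:
    """left_typical if LI > band, right_atypical if LI < -band, else bilateral."""
    if not -100.0 <= li <= 100.0:
        raise ValueError(f"LI {li} outside [-100, 100]")
    if li > band:
        return "left_typical"
    if li < -band:
        return "right_atypical"
    return "bilateral"


def classify_handedness(ehi_score: float) -> str:
    """Edinburgh quotient to handedness class (cutoffs at +/-40 inclusive)."""
    if not -100.0 <= ehi_score <= 100.0:
        raise ValueError(f"EHI score {ehi_score} outside [-100, 100]")
    if ehi_score >= EHI_CUTOFF:
        return "right"
    if ehi_score <= -EHI_CUTOFF:
        return "left"
    return "ambidextrous"


def compute_laterality(
    statmap: StatMap,
    rois: RoiPair,
    top_fraction: float = TOP_FRACTION,
    threshold_fraction: float = THRESHOLD_FRACTION,
    source: str = "max",
    band: float = BILATERAL_BAND,
) -> LateralityResult:
    """Full adaptive-threshold LI pipeline for one subject map."""
    thr = adaptive_threshold(statmap, rois, top_fraction, threshold_fraction, source)
    n_left = count_suprathreshold(statmap, rois.left, thr.value)
    n_right = count_suprathreshold(statmap, rois.right, thr.value)
    li = laterality_index(n_left, n_right)
    return LateralityResult(
        subject_id=statmap.subject_id,
        n_left=n_left,
        n_right=n_right,
        threshold=thr,
        li=li,
        label=classify_laterality(li, band),
    )


def hemispheric_extent(
    statmap: StatMap,
    hemispheres: RoiPair,
    top_fraction: float = TOP_FRACTION,
    threshold_fraction: float = THRESHOLD_FRACTION,
    source: str = "max",
) -> tuple[ExtentResult, ExtentResult, int]:
    """Suprathreshold extent per hemisphere, with the threshold recomputed
    on the hemisphere pair in the same adaptive manner as the ROI LI."""
    thr = adaptive_threshold(statmap, hemispheres, top_fraction, threshold_fraction, source)
    n_l = count_suprathreshold(statmap, hemispheres.left, thr.value)
    n_r = count_suprathreshold(statmap, hemispheres.right, thr.value)
    left = ExtentResult(n_voxels=n_l, roi_label=hemispheres.left.label, threshold=thr.value)
    right = ExtentResult(n_voxels=n_r, roi_label=hemispheres.right.label, threshold=thr.value)
    return left, right, n_l + n_r


def cohort_laterality_table(
    maps: list[StatMap],
    rois: RoiPair,
    metas: list[SubjectMeta] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-cohort laterality table (one row per subject).

    Columns: subject_id, n_left, n_right, threshold, li, label, and — when
    metadata is supplied — ehi_score, handedness, sex, age.
    """
    if metas is not None and len(metas) != len(maps):
        raise ValueError("metadata length does not match number of maps")
    rows = []
    for i, m in enumerate(maps):
        res = compute_laterality(m, rois, **kwargs)
        row = {
            "subject_id": res.subject_id,
            "n_left": res.n_left,
            "n_right": res.n_right,
            "threshold": res.threshold.value,
            "li": res.li,
            "label": res.label,
        }
        if metas is not None:
            meta = metas[i]
            row.update(
                ehi_score=meta.ehi_score,
                handedness=meta.handedness,
                sex=meta.sex,
                age=meta.age,
            )
        rows.append(row)
    return pd.DataFrame(rows)
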