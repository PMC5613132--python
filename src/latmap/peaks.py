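"""Peak-of-activity localization within an ROI and axis-wise group contrasts.

The peak is simply the ROI voxel with the highest Z value (ties resolved to
the smallest row-major linear index, so results are deterministic).  Peak
coordinates are reported in world mm, and groups are compared along the
y (anterior-posterior) or z (inferior-superior) axis with Welch's t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import WelchResult, welch_t_from_samples
from .volumes import RoiMask, StatMap, voxel_to_mm


@dataclass(frozen=True)
class PeakResult:
    index: tuple[int, int, int]
    mm: tuple[float, float, float]
    z_value: float
    roi_label: str
    subject_id: str


AXES = {"x": 0, "y": 1, "z": 2}


def find_peak(statmap: StatMap, mask: RoiMask) -> PeakResult:
    """ROI voxel with maximal Z; ties break to the smallest linear index."""
    if statmap.shape != mask.data.shape:
        raise ValueError("mask is not on the map grid")
    masked = np.where(mask.data, statmap.data, -np.inf)
    flat = int(np.argmax(masked))  # argmax returns the first (smallest) index on ties
    idx = np.unravel_index(flat, statmap.shape)
    mm = voxel_to_mm(idx, statmap.affine, statmap.shape)
    return PeakResult(
        index=tuple(int(i) for i in idx),
        mm=tuple(float(c) for c in mm),
        z_value=float(statmap.data[idx]),
        roi_label=mask.label,
        subject_id=statmap.subject_id,
    )


def hemisphere_of_peak(peak: PeakResult) -> str:
    """left / right / midline by the sign of the peak's world x coordinate."""
    x = peak.mm[0]
    if x < 0:
        return "left"
    if x > 0:
        return "right"
    return "midline"


def compare_peak_axis(group_a: list[PeakResult], group_b: list[PeakResult],
                      axis: str) -> WelchResult:
    """Welch t comparing peak mm coordinates of two groups along y or z.

    Statistic direction is (group_b - group_a).
    """
    if axis not in ("y", "z"):
        raise ValueError("axis must be 'y' or 'z'")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 peaks")
    ax = AXES[axis]
    xs = [p.mm[ax] for p in group_a]
    ys = [p.mm[ax] for p in group_b]
    return welch_t_from_samples(xs, ys)


def peaks_table(peaks: list[PeakResult]) -> pd.DataFrame:
    """Peaks as a table: subject, voxel index, mm coordinates, Z, hemisphere."""
    rows = [
        {
            "subject_id": p.subject_id,
            "i": p.index[0],
            "j": p.index[1],
            "k": p.index[2],
            "x_mm": p.mm[0],
            "y_mm": p.mm[1],
            "z_mm": p.mm[2],
            "z_value": p.z_value,
            "hemisphere": hemisphere_of_peak(p),
        }
        for p in peaks
    ]
    return pd.DataFrame(rows)


def flag_discordant_peaks(peaks: list[PeakResult], expected_side: list[str]) -> list[bool]:
    """Flag subjects whose peak hemisphere contradicts their group's side.

    Mirrors the exclusion of subjects whose individual peak falls in the
    hemisphere opposite to their classification before axis comparisons.
    """
    if len(peaks) != len(expected_side):
        raise ValueError("peaks and expected sides differ in length")
    return [hemisphere_of_peak(p) != side for p, side in zip(peaks, expected_side)]
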