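"""Inferential primitives applied to derived quantities.

Welch's unequal-variance t test (from raw samples or from printed group
summaries), Pearson correlation reported with its n-2 degrees of freedom,
and a voxelwise two-sample Welch t map for group contrasts.

Sign convention: two-group statistics are computed as (second - first), so
``welch_t_from_samples(typical, atypical)`` is the "atypical minus typical"
direction.  Swapping the groups flips the sign of t and leaves p unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .volumes import GridMismatchError, StatMap


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    n1: int
    n2: int

    def as_record(self, test: str = "welch_t") -> dict:
        return {"test": test, "t": self.t, "df": self.df, "p": self.p,
                "n1": self.n1, "n2": self.n2}


@dataclass(frozen=True)
class CorrResult:
    r: float
    df: int
    p: float


def welch_t_from_summary(m1: float, sd1: float, n1: int,
                         m2: float, sd2: float, n2: int) -> WelchResult:
    """Welch t test from group means, standard deviations, and sizes.

    t = (m2 - m1) / sqrt(sd1^2/n1 + sd2^2/n2), with Welch-Satterthwaite
    degrees of freedom and a two-tailed p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        # both groups constant: no variability to test against
        if m1 == m2:
            return WelchResult(t=0.0, df=float(n1 + n2 - 2), p=1.0, n1=n1, n2=n2)
        raise ValueError("zero variance in both groups with unequal means")
    t = (m2 - m1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0), n1=n1, n2=n2)


def welch_t_from_samples(xs, ys) -> WelchResult:
    """Welch t test from raw samples; equals the summary path on the
    samples' moments (ddof = 1).  Identical constant samples give t=0, p=1."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("each sample needs n >= 2")
    return welch_t_from_summary(
        float(xs.mean()), float(xs.std(ddof=1)), xs.size,
        float(ys.mean()), float(ys.std(ddof=1)), ys.size,
    )


def pearson_with_df(xs, ys) -> CorrResult:
    """Pearson r with df = n - 2 and a two-tailed p via t = r sqrt(df/(1-r^2))."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("samples must have equal length")
    n = xs.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation with df >= 1")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance: correlation undefined for a constant vector")
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrResult(r=r, df=df, p=p)


def two_sample_t_map(group_a: list[StatMap], group_b: list[StatMap]) -> StatMap:
    """Voxelwise Welch t map for a group contrast (computed as A - B).

    Voxels with zero variance in both groups are set to t = 0.  This is an
    ordinary per-voxel two-sample test; no mixed-effects modelling and no
    multiple-comparison correction is applied.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 maps")
    ref = group_a[0]
    for m in group_a[1:] + group_b:
        if not ref.same_grid(m):
            raise GridMismatchError("all maps must share one grid")
    a = np.stack([m.data for m in group_a])
    b = np.stack([m.data for m in group_b])
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return ref.with_data(t, subject_id="", map_kind="contrast")
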