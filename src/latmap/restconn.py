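"""Resting-state seed and hemispheric-global-signal connectivity.

Pipeline for 4-D resting runs:

1. band-pass every voxel time series to 0.01-0.1 Hz with a hard DFT window
   (DC removed; motion parameters are filtered identically);
2. regress out a 28-column nuisance design — the Friston-24 motion expansion
   (parameters, squares, one-volume lags, lagged squares) plus mean CSF and
   white-matter signals each with its backward difference;
3. extract mean series from 5 mm spherical seed masks and the per-hemisphere
   gray-matter means (the hemispheric *global signals*, kept as predictors
   of interest rather than removed);
4. fit a per-voxel multiple regression on [intercept | seeds | global_left |
   global_right], yielding beta and t maps per predictor and the
   left-minus-right global-signal contrast (and its negation).

Whole-brain global signal is deliberately not regressed out: its removal
alters group comparisons qualitatively and it carries the lateralization
signal this stage is built to measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .stats import two_sample_t_map
from .volumes import (FormatError, GridMismatchError, RoiMask, RoiPair,
                      StatMap, ValidationError, _check_affine, mm_to_voxel,
                      voxel_to_mm)

logger = logging.getLogger(__name__)

F_LO_HZ = 0.01
F_HI_HZ = 0.1
SEED_RADIUS_MM = 5.0


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed mask: center in world mm, radius in mm."""

    center_mm: tuple[float, float, float]
    radius_mm: float = SEED_RADIUS_MM
    name: str = "seed"

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("seed radius must be positive")


@dataclass
class RestingRun:
    """4-D resting time series with motion parameters and tissue masks."""

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray
    tr_s: float
    motion: np.ndarray  # (t, 6)
    gray: RoiMask
    white: RoiMask
    csf: RoiMask
    hemispheres: RoiPair
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValidationError("RestingRun data must be 4-D (x, y, z, t)")
        if self.n_volumes < 20:
            raise ValidationError("need at least 20 volumes")
        self.affine = _check_affine(self.affine)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.shape != (self.n_volumes, 6):
            raise ValidationError(
                f"motion must be (T, 6) = ({self.n_volumes}, 6), got {self.motion.shape}"
            )
        for mask in (self.gray, self.white, self.csf,
                     self.hemispheres.left, self.hemispheres.right):
            if mask.data.shape != self.shape3d:
                raise GridMismatchError("mask is not on the run grid")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "RestingRun":
        return RestingRun(data=data, affine=self.affine, tr_s=self.tr_s,
                          motion=self.motion, gray=self.gray, white=self.white,
                          csf=self.csf, hemispheres=self.hemispheres,
                          subject_id=self.subject_id)


@dataclass(frozen=True)
class NuisanceDesign:
    """T x 28 nuisance matrix: Friston-24 motion + CSF/WM with differences."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.names):
            raise ValueError("design matrix does not match column names")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class ConnectivityResult:
    """Per-predictor beta and t maps plus hemispheric-global contrasts."""

    betas: dict[str, StatMap]
    tstats: dict[str, StatMap]
    contrast_left_gt_right: StatMap | None
    contrast_right_gt_left: StatMap | None
    predictor_names: list[str]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_run_data(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D NIfTI run, returning (data, affine)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI run {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path} is {data.ndim}-D, expected a 4-D run")
    return data, np.asarray(img.affine, dtype=float)


def write_run_data(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_motion(path) -> np.ndarray:
    """Read a whitespace-delimited 6-column motion parameter file."""
    motion = np.loadtxt(str(path), ndmin=2)
    if motion.shape[1] != 6:
        raise FormatError(f"{path} has {motion.shape[1]} columns, expected 6")
    return motion


def write_motion(motion: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(motion, dtype=float), fmt="%.10g")


# ---------------------------------------------------------------------------
# Temporal filtering and nuisance design
# ---------------------------------------------------------------------------

def bandpass(series: np.ndarray, tr_s: float,
             f_lo: float = F_LO_HZ, f_hi: float = F_HI_HZ) -> np.ndarray:
    """Hard DFT-window band-pass along the last axis.

    Frequency bins with f_lo < f < f_hi are retained; everything else,
    including the DC component, is zeroed, so the output is (numerically)
    zero-mean.  No tapering is applied.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 20:
        raise ValueError("need at least 20 time points")
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 <= f_lo < f_hi:
        raise ValueError("require 0 <= f_lo < f_hi")
    if f_hi >= nyquist:
        raise ValueError(f"f_hi = {f_hi} Hz must be below Nyquist = {nyquist} Hz")
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs > f_lo) & (freqs < f_hi)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def bandpass_run(run: RestingRun, f_lo: float = F_LO_HZ,
                 f_hi: float = F_HI_HZ) -> RestingRun:
    """Band-pass every voxel series and the motion parameters of a run."""
    out = run.with_data(bandpass(run.data, run.tr_s, f_lo, f_hi))
    out.motion = bandpass(run.motion.T, run.tr_s, f_lo, f_hi).T
    return out


def backward_difference(series: np.ndarray) -> np.ndarray:
    """d_t = s_t - s_{t-1} with d_0 = 0, along the last axis."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("need at least 2 time points")
    out = np.zeros_like(series)
    out[..., 1:] = series[..., 1:] - series[..., :-1]
    return out


def expand_motion_regressors(motion: np.ndarray) -> np.ndarray:
    """Friston-24 expansion of 6 rigid-body motion parameters.

    Per parameter, in order: [m, m^2, m lagged by one volume, lagged m^2];
    the lagged rows are zero-padded at t = 0.  Output is T x 24.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (T, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    cols = []
    for p in range(6):
        m = motion[:, p]
        lag = np.zeros_like(m)
        lag[1:] = m[:-1]
        cols.extend([m, m ** 2, lag, lag ** 2])
    return np.column_stack(cols)


def motion_column_names() -> list[str]:
    return [f"m{p}{suffix}" for p in range(1, 7)
            for suffix in ("", "_sq", "_lag1", "_lag1_sq")]


def mean_mask_series(data4d: np.ndarray, mask: RoiMask) -> np.ndarray:
    """Per-volume mean over the masked voxels."""
    return data4d[mask.data].mean(axis=0)


def build_nuisance_design(run: RestingRun) -> NuisanceDesign:
    """28-column design: Friston-24 motion + CSF, WM, and their backward
    differences, extracted from the run's tissue masks."""
    motion24 = expand_motion_regressors(run.motion)
    csf = mean_mask_series(run.data, run.csf)
    wm = mean_mask_series(run.data, run.white)
    matrix = np.column_stack(
        [motion24, csf, backward_difference(csf), wm, backward_difference(wm)]
    )
    names = motion_column_names() + ["csf", "csf_backdiff", "wm", "wm_backdiff"]
    return NuisanceDesign(matrix=matrix, names=names)


# ---------------------------------------------------------------------------
# Regression stages
# ---------------------------------------------------------------------------

def _drop_zero_columns(matrix: np.ndarray, names: list[str]):
    keep = np.ptp(matrix, axis=0) > 0
    return matrix[:, keep], [n for n, k in zip(names, keep) if k]


def nuisance_regress(run: RestingRun, design: NuisanceDesign) -> RestingRun:
    """Per-voxel OLS removal of nuisance variance; residuals returned.

    Constant (zero-range) design columns are dropped; an intercept is always
    included, so the residuals are demeaned.  Raises on rank deficiency,
    naming the collinear columns.
    """
    t = run.n_volumes
    if design.matrix.shape[0] != t:
        raise ValueError("design rows do not match run length")
    x, names = _drop_zero_columns(design.matrix, list(design.names))
    x = np.column_stack([np.ones(t), x])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x[:, 1:], names)
        raise ValueError(
            f"nuisance design is rank deficient; collinear columns: {bad} "
            f"(a band-passed design needs roughly 2*T*tr*(f_hi-f_lo) >= "
            f"{x.shape[1]} effective time points)"
        )
    y = run.data.reshape(-1, t).T  # T x V
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return run.with_data(resid.T.reshape(run.data.shape))


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Best-effort identification of columns involved in collinearity."""
    bad = []
    if x.shape[1] < 2:
        return names
    c = np.corrcoef(x.T)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(c[i, j]) > 0.999:
                bad.extend([names[i], names[j]])
    return sorted(set(bad)) or names


def sphere_mask(center_mm, radius_mm: float, shape, affine: np.ndarray,
                name: str = "seed") -> RoiMask:
    """Voxels whose centers lie within ``radius_mm`` (Euclidean) of a point."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    xyz = idx @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((xyz - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
    data = (d2 <= radius_mm ** 2).reshape(shape)
    if not data.any():
        raise ValueError(f"sphere at {tuple(center_mm)} r={radius_mm} mm is empty")
    return RoiMask(data=data, side="none", label=name)


def extract_seed(run: RestingRun, seed: SeedSpec) -> np.ndarray:
    """Mean time series over the seed's spherical mask."""
    mask = sphere_mask(seed.center_mm, seed.radius_mm, run.shape3d, run.affine,
                       name=seed.name)
    return mean_mask_series(run.data, mask)


def hemispheric_global_signal(run: RestingRun) -> tuple[np.ndarray, np.ndarray]:
    """Per-volume mean over each hemisphere's gray-matter voxels.

    Returns (left, right).  Voxels outside the gray mask are excluded.
    """
    out = []
    for hemi in (run.hemispheres.left, run.hemispheres.right):
        combined = hemi.data & run.gray.data
        if not combined.any():
            raise ValueError(f"no gray-matter voxels in {hemi.side} hemisphere")
        out.append(run.data[combined].mean(axis=0))
    return out[0], out[1]


def seed_connectivity(run: RestingRun, seeds: list[SeedSpec],
                      f_lo: float = F_LO_HZ, f_hi: float = F_HI_HZ,
                      include_globals: bool = True) -> ConnectivityResult:
    """Subject-level multiple regression connectivity model.

    The run should already be nuisance-regressed and band-passed; seed and
    hemispheric global predictors are extracted from it and band-passed with
    the same window before entering the design
    [intercept | seed_1..seed_k | global_left | global_right].

    Returns per-predictor beta and t maps and the beta contrast between the
    left and right hemispheric global signals (both directions).  With
    ``include_globals=False`` the model is seed-only and the hemispheric
    contrasts are ``None``.
    """
    t = run.n_volumes
    predictors = [extract_seed(run, s) for s in seeds]
    names = [s.name for s in seeds]
    if include_globals:
        gl, gr = hemispheric_global_signal(run)
        predictors += [gl, gr]
        names += ["global_left", "global_right"]
    if not predictors:
        raise ValueError("no predictors: supply seeds or include_globals=True")
    predictors = [bandpass(p, run.tr_s, f_lo, f_hi) for p in predictors]
    p = np.column_stack(predictors)
    # pairwise collinearity guard
    std = p.std(axis=0)
    if np.any(std == 0):
        dead = [n for n, s in zip(names, std) if s == 0]
        raise ValueError(f"constant predictor(s): {dead}")
    c = np.corrcoef(p.T) if p.shape[1] > 1 else np.ones((1, 1))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(c[i, j]) > 0.99:
                raise ValueError(
                    f"collinear predictors {names[i]!r} and {names[j]!r} "
                    f"(|r| = {abs(c[i, j]):.3f})"
                )
    x = np.column_stack([np.ones(t), p])
    y = run.data.reshape(-1, t).T
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (K+1) x V
    resid = y - x @ beta
    dof = t - x.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    shape = run.shape3d

    def as_map(vec: np.ndarray, kind: str) -> StatMap:
        return StatMap(data=vec.reshape(shape), affine=run.affine,
                       subject_id=run.subject_id, map_kind=kind)

    betas = {n: as_map(beta[i + 1], "beta") for i, n in enumerate(names)}
    tstats = {n: as_map(tval[i + 1], "zstat") for i, n in enumerate(names)}
    if include_globals:
        lr = betas["global_left"].data - betas["global_right"].data
        c_lr = as_map(lr.ravel(), "contrast")
        c_rl = as_map(-lr.ravel(), "contrast")
    else:
        c_lr = c_rl = None
    return ConnectivityResult(
        betas=betas,
        tstats=tstats,
        contrast_left_gt_right=c_lr,
        contrast_right_gt_left=c_rl,
        predictor_names=names,
    )


def preprocess_run(run: RestingRun, f_lo: float = F_LO_HZ,
                   f_hi: float = F_HI_HZ) -> RestingRun:
    """Band-pass, then nuisance-regress with identically filtered regressors.

    Filtering the regressors with the same window prevents the classic
    artifact where regression reintroduces frequencies outside the passband.
    """
    filtered = bandpass_run(run, f_lo, f_hi)
    design = build_nuisance_design(filtered)
    design = NuisanceDesign(
        matrix=bandpass(design.matrix.T, run.tr_s, f_lo, f_hi).T,
        names=design.names,
    )
    x, names = _drop_zero_columns(design.matrix, list(design.names))
    if x.shape[1] < len(design.names):
        logger.info("dropped %d constant nuisance columns",
                    len(design.names) - x.shape[1])
    return nuisance_regress(filtered, NuisanceDesign(matrix=x, names=names))


def group_connectivity_contrast(group_a: list[ConnectivityResult],
                                group_b: list[ConnectivityResult],
                                which: str = "left_gt_right") -> StatMap:
    """Voxelwise Welch t map (A - B) over subject-level connectivity maps.

    ``which`` is a predictor name (beta maps) or one of ``left_gt_right`` /
    ``right_gt_left`` (hemispheric global-signal contrast maps).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 subjects")

    def pick(res: ConnectivityResult) -> StatMap:
        if which == "left_gt_right":
            return res.contrast_left_gt_right
        if which == "right_gt_left":
            return res.contrast_right_gt_left
        if which in res.betas:
            return res.betas[which]
        raise KeyError(f"unknown contrast/predictor {which!r}")

    return two_sample_t_map([pick(r) for r in group_a], [pick(r) for r in group_b])
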