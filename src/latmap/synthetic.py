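"""Synthetic cohorts with planted ground truth.

Generates the two kinds of data the analysis stages consume:

* per-subject 3-D Z-maps on a 64 x 64 x 35 grid (2 mm isotropic, midline
  bisecting the first axis) containing Gaussian activation blobs centred in
  mirror-symmetric left/right "Broca" boxes.  Blob geometry is solved so
  that the *noiseless* map realizes a requested laterality index through the
  adaptive-threshold pipeline itself: the dominant blob's width is chosen to
  hit a target suprathreshold count, and the non-dominant amplitude is
  solved in closed form from the sorted kernel values to hit the count ratio
  (100 - |LI|) / (100 + |LI|).  Counts are integers, so the generator plants
  the closest achievable LI and records it; requests it cannot realize raise
  rather than silently clipping.

* 4-D resting-state runs (TR = 2 s) containing seed-coupled signals with
  known betas, hemisphere-wide global components whose asymmetry is switched
  by a group flag, motion/CSF/WM-like nuisance, and white noise.

The *extent-bilaterality coupling*: each subject's total planted
suprathreshold count is ``base_count * jitter * (1 + kappa * (1 - |LI|/100))``,
split between hemispheres by the LI.  With kappa > 0 bilateral subjects
activate more voxels (the diffuseness effect); with kappa = 0 the planted
extent is independent of the LI (up to the jitter).

Every generator takes an explicit seed and is reproducible bit for bit.
Truth tables accompany all generated data; no analysis stage reads them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import laterality as lat
from .restconn import RestingRun, bandpass, sphere_mask
from .volumes import RoiMask, RoiPair, StatMap


class SimulationError(ValueError):
    """Raised when a requested ground truth cannot be realized."""


# ---------------------------------------------------------------------------
# Grids and masks
# ---------------------------------------------------------------------------

def default_affine(shape=(64, 64, 35), voxel_mm: float = 2.0) -> np.ndarray:
    """RAS affine with isotropic voxels, centred so world x = 0 bisects the
    grid (no voxel centre sits on the midline when the first dim is even)."""
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = voxel_mm
        affine[ax, 3] = -voxel_mm * (shape[ax] - 1) / 2.0
    return affine


def make_roi_pair(shape=(64, 64, 35), label: str = "broca") -> RoiPair:
    """Mirror-symmetric left/right box ROIs (toy BA44/45 analogue).

    Boxes sit in the inferior-frontal octant of each hemisphere and are exact
    mirror images under reversal of the first grid axis.
    """
    nx, ny, nz = shape
    if nx % 2:
        raise SimulationError("first grid dimension must be even so the midline bisects it")
    wi = max(2, round(0.16 * nx))
    wj = max(2, round(0.16 * ny))
    wk = max(2, min(round(0.29 * nz), nz - 2))
    i0 = max(1, round(0.0625 * nx))
    j0 = min(ny - wj - 1, round(0.53 * ny))
    k0 = min(nz - wk - 1, round(0.63 * nz))
    if 2 * (i0 + wi) > nx:
        raise SimulationError("grid too small for disjoint mirror ROIs")
    left = np.zeros(shape, dtype=bool)
    left[i0:i0 + wi, j0:j0 + wj, k0:k0 + wk] = True
    right = left[::-1, :, :].copy()
    return RoiPair(
        left=RoiMask(data=left, side="left", label=f"{label}_left"),
        right=RoiMask(data=right, side="right", label=f"{label}_right"),
    )


def make_hemisphere_masks(shape=(64, 64, 35)) -> RoiPair:
    """Left/right hemisphere masks splitting the grid at the midline."""
    nx = shape[0]
    if nx % 2:
        raise SimulationError("first grid dimension must be even so the midline bisects it")
    left = np.zeros(shape, dtype=bool)
    left[: nx // 2] = True
    right = np.zeros(shape, dtype=bool)
    right[nx // 2:] = True
    return RoiPair(
        left=RoiMask(data=left, side="left", label="hemisphere_left"),
        right=RoiMask(data=right, side="right", label="hemisphere_right"),
    )


def make_cortex_masks(shape=(64, 64, 35), margin: int = 2,
                      label: str = "cortex") -> RoiPair:
    """Per-hemisphere simulated-cortex masks: the ROI boxes dilated by
    ``margin`` voxels.

    The synthetic brain only carries activation in and around the paired
    ROIs — everything else is empty space plus noise — so the "hemispheric
    gray matter" of this toy brain is the peri-ROI region.  These masks are
    the hemispheric ROI for extent measurements; :func:`make_hemisphere_masks`
    still provides the full half-grid partition.
    """
    rois = make_roi_pair(shape, label=label)
    nx = shape[0]

    def dilate(mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + margin + 1, shape)
        out = np.zeros(shape, dtype=bool)
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return out

    left = dilate(rois.left.data)
    left[nx // 2:] = False  # never cross the midline
    right = left[::-1, :, :].copy()
    return RoiPair(
        left=RoiMask(data=left, side="left", label=f"{label}_left"),
        right=RoiMask(data=right, side="right", label=f"{label}_right"),
    )


def _box_center(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return (idx.min(axis=0) + idx.max(axis=0)) / 2.0


# ---------------------------------------------------------------------------
# Task-map cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic task-map cohort.

    Defaults emulate a 63-subject verbal-fluency sample: 83% left-typical,
    9% bilateral, 8% right-atypical, blob peak Z = 8 against unit white
    noise in Z units, 2 mm group grid, and an extent-bilaterality coupling
    of kappa = 1.5 (more bilateral subjects activate more voxels).
    """

    n_subjects: int = 63
    shape: tuple[int, int, int] = (64, 64, 35)
    voxel_mm: float = 2.0
    proportions: tuple[float, float, float] = (0.83, 0.09, 0.08)
    li_ranges: dict = field(default_factory=lambda: {
        "left_typical": (50.0, 100.0),
        "bilateral": (-33.0, 33.0),
        "right_atypical": (-100.0, -50.0),
    })
    amplitude: float = 8.0
    base_count: int = 400
    extent_kappa: float = 1.5
    extent_jitter: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise SimulationError("group proportions must sum to 1")
        if self.amplitude <= 0 or self.noise_sd < 0:
            raise SimulationError("amplitude must be > 0 and noise_sd >= 0")
        if self.extent_kappa < 0:
            raise SimulationError("extent coupling kappa must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.shape, self.voxel_mm)


#: mild per-axis width factors: lattice-symmetric shells around the blob
#: centre would otherwise tie many kernel values, making achievable
#: suprathreshold counts sparse and the planted-LI quantization coarse.
#: The x factor stays 1.0 so blobs remain exact mirror images under flip_x.
_ANISO = (1.0, 1.0731, 0.9273)


#: blob profile exponent: 1 is Gaussian, 2 a flat-top super-Gaussian.  Real
#: activation clusters have plateaus of near-maximal Z rather than a single
#: spike; a flat top also keeps the adaptive threshold pinned near half the
#: peak amplitude instead of drifting with blob size.
_BLOB_EXPONENT = 2.0


def _kernel(shape, center_vox, sigma_vox: float) -> np.ndarray:
    """Unit-peak super-Gaussian blob on the voxel lattice (mildly
    anisotropic in y/z)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / f) ** 2 for g, c, f in zip(grids, center_vox, _ANISO))
    return np.exp(-((d2 / (2.0 * sigma_vox ** 2)) ** _BLOB_EXPONENT))


def _kernel_at(points: np.ndarray, center_vox, sigma_vox: float) -> np.ndarray:
    """Kernel values at an (N, 3) array of voxel indices (cheap for a ROI)."""
    d2 = (((points - np.asarray(center_vox)) / np.asarray(_ANISO)) ** 2).sum(axis=1)
    return np.exp(-((d2 / (2.0 * sigma_vox ** 2)) ** _BLOB_EXPONENT))


def _roi_threshold_stats(kernel_roi: np.ndarray, top_fraction: float,
                         threshold_fraction: float):
    """(tau, count) for a unit-peak kernel restricted to the ROI: tau is the
    adaptive threshold per unit amplitude, count the voxels above it.
    Amplitude cancels, so the dominant-side count depends only on geometry."""
    n = kernel_roi.size
    k = max(1, math.ceil(top_fraction * n))
    top = np.partition(kernel_roi, n - k)[n - k:]
    tau = threshold_fraction * float(top.mean())
    return tau, int(np.count_nonzero(kernel_roi > tau))


def _solve_sigma(kernel_fn, target_count: int, sigma_lo: float = 0.6,
                 sigma_hi: float = 9.0, n_grid: int = 240):
    """Blob width (in voxels) whose noiseless suprathreshold ROI count is
    closest to the target.  Counts are step functions of sigma, so this is a
    grid search over widths rather than a root find."""
    best = None
    for sigma in np.linspace(sigma_lo, sigma_hi, n_grid):
        tau, count = kernel_fn(sigma)
        err = abs(count - target_count)
        if best is None or err < best[0]:
            best = (err, sigma, tau, count)
        if err == 0:
            break
    _, sigma, tau, count = best
    return sigma, tau, count


def _amplitude_for_count(vals_desc: np.ndarray, thr: float, n_target: int,
                         a_max: float):
    """Smallest-|error| achievable count and the amplitude realizing it.

    ``vals_desc`` are the non-dominant kernel values in its ROI, sorted
    descending.  Count c is achievable iff vals[c-1] > vals[c] strictly
    (lattice symmetry creates ties); the amplitude is placed midway between
    the bracketing reciprocals so the strict-> rule lands exactly on c.
    """
    if n_target <= 0:
        return 0.0, 0
    n = vals_desc.size
    n_target = min(n_target, n)
    for delta in range(n + 1):
        for c in (n_target - delta, n_target + delta):
            if not 1 <= c <= n:
                continue
            upper = vals_desc[c - 1]
            lower = vals_desc[c] if c < n else 0.0
            if upper <= lower or upper <= 0:
                continue
            if c < n:
                a = 2.0 * thr / (upper + lower)
            else:
                a = 1.01 * thr / upper
            if a <= a_max * (1 + 1e-12):
                return min(a, a_max), c
    raise SimulationError("no feasible amplitude for requested count")


def simulate_zmap(spec: CohortSpec, planted_li: float, planted_extent: int,
                  seed: int) -> tuple[StatMap, dict]:
    """One synthetic Z-map realizing a laterality index and extent budget.

    ``planted_extent`` is the target total noiseless suprathreshold count in
    the ROI pair; it is split (100+|LI|)/200 : (100-|LI|)/200 between the
    dominant and non-dominant side.  Returns the map and a truth record with
    the realized (count-quantized) LI.
    """
    if not -100.0 <= planted_li <= 100.0:
        raise SimulationError(f"planted LI {planted_li} outside [-100, 100]")
    if planted_extent < 2:
        raise SimulationError("planted extent must be at least 2 voxels")
    rois = make_roi_pair(spec.shape)
    dom_mask = rois.left if planted_li >= 0 else rois.right
    nd_mask = rois.right if planted_li >= 0 else rois.left
    dom_center = _box_center(dom_mask.data)
    nd_center = _box_center(nd_mask.data)
    abs_li = abs(planted_li)

    dom_target = max(1, round(planted_extent * (100.0 + abs_li) / 200.0))
    dom_points = np.argwhere(dom_mask.data).astype(float)

    def kernel_fn(sigma):
        return _roi_threshold_stats(_kernel_at(dom_points, dom_center, sigma),
                                    lat.TOP_FRACTION, lat.THRESHOLD_FRACTION)

    sigma_vox, tau, dom_count = _solve_sigma(kernel_fn, dom_target)
    thr = spec.amplitude * tau  # the analysis-time adaptive threshold (noiseless)

    dom_kernel = _kernel(spec.shape, dom_center, sigma_vox)
    nd_kernel = _kernel(spec.shape, nd_center, sigma_vox)

    nd_target = round(dom_count * (100.0 - abs_li) / (100.0 + abs_li))
    if abs_li == 0:
        # mirror kernels: equal amplitude gives exactly equal counts
        a_nd, nd_count = spec.amplitude, dom_count
    else:
        vals = np.sort(nd_kernel[nd_mask.data])[::-1]
        a_nd, nd_count = _amplitude_for_count(vals, thr, nd_target, spec.amplitude)

    data = spec.amplitude * dom_kernel + a_nd * nd_kernel
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, spec.shape)

    realized_li = 100.0 * (dom_count - nd_count) / (dom_count + nd_count)
    if planted_li < 0:
        realized_li = -realized_li
    n_left = dom_count if planted_li >= 0 else nd_count
    n_right = nd_count if planted_li >= 0 else dom_count
    truth = {
        "planted_li": float(planted_li),
        "realized_li": float(realized_li),
        "planted_extent": int(planted_extent),
        "realized_extent": int(dom_count + nd_count),
        "n_left_true": int(n_left),
        "n_right_true": int(n_right),
        "sigma_mm": float(sigma_vox * spec.voxel_mm),
        "amplitude_dominant": float(spec.amplitude),
        "amplitude_nondominant": float(a_nd),
        "threshold_noiseless": float(thr),
    }
    return StatMap(data=data, affine=spec.affine, subject_id="", map_kind="zstat"), truth


GROUPS = ("left_typical", "bilateral", "right_atypical")

#: P(handedness class | laterality group); atypical groups are enriched in
#: left-handers and ambidextrals, as in real samples.
_HANDEDNESS_PROBS = {
    "left_typical": (0.60, 0.25, 0.15),  # right, left, ambidextrous
    "bilateral": (0.20, 0.50, 0.30),
    "right_atypical": (0.20, 0.50, 0.30),
}
_EHI_RANGES = {"right": (40.0, 100.0), "left": (-100.0, -40.0),
               "ambidextrous": (-39.0, 39.0)}


def simulate_cohort(spec: CohortSpec) -> tuple[list[StatMap], list[lat.SubjectMeta], pd.DataFrame]:
    """A full cohort of maps, metadata, and the accompanying truth table."""
    rng = np.random.default_rng(spec.seed)
    groups = rng.choice(len(GROUPS), size=spec.n_subjects, p=list(spec.proportions))
    maps: list[StatMap] = []
    metas: list[lat.SubjectMeta] = []
    rows = []
    for s in range(spec.n_subjects):
        group = GROUPS[int(groups[s])]
        lo, hi = spec.li_ranges[group]
        planted_li = float(rng.uniform(lo, hi))
        jitter = float(rng.uniform(1.0 - spec.extent_jitter, 1.0 + spec.extent_jitter))
        multiplier = 1.0 + spec.extent_kappa * (1.0 - abs(planted_li) / 100.0)
        planted_extent = max(2, round(spec.base_count * jitter * multiplier))
        subject_id = f"sub-{s + 1:03d}"
        map_seed = int(rng.integers(0, 2 ** 31 - 1))
        zmap, truth = simulate_zmap(spec, planted_li, planted_extent, map_seed)
        zmap = zmap.with_data(zmap.data, subject_id=subject_id)

        hand = rng.choice(("right", "left", "ambidextrous"),
                          p=_HANDEDNESS_PROBS[group])
        ehi = float(np.round(rng.uniform(*_EHI_RANGES[hand]), 1))
        sex = str(rng.choice(("F", "M")))
        age = float(np.round(np.clip(rng.normal(22.5, 3.4), 19, 39), 1))
        meta = lat.SubjectMeta(subject_id=subject_id, ehi_score=ehi, sex=sex, age=age)

        maps.append(zmap)
        metas.append(meta)
        rows.append({"subject_id": subject_id, "group": group,
                     "extent_multiplier": multiplier, "extent_jitter": jitter,
                     **truth,
                     "ehi_score": ehi, "handedness": meta.handedness,
                     "sex": sex, "age": age, "map_seed": map_seed})
    return maps, metas, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Resting-state runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSeed:
    """A seed-coupled signal: unit coupling in a source sphere, ``beta``
    coupling in a target sphere elsewhere."""

    center_mm: tuple[float, float, float]
    target_mm: tuple[float, float, float]
    beta: float
    name: str = "seed"
    source_radius_mm: float = 6.0
    target_radius_mm: float = 6.0


@dataclass(frozen=True)
class RestingSpec:
    """Study conditions for synthetic resting runs: 6 min at TR = 2 s."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_mm: float = 2.0
    n_volumes: int = 180
    tr_s: float = 2.0
    seeds: tuple[PlantedSeed, ...] = (
        PlantedSeed(center_mm=(-12.0, 8.0, 2.0), target_mm=(12.0, 8.0, 2.0),
                    beta=0.8, name="seed_lh"),
    )
    global_amp_dominant: float = 1.0
    global_amp_other: float = 0.5
    #: mirrored "default-mode-like" regions where the dominant hemisphere's
    #: global component couples with extra gain.  A uniform amplitude
    #: asymmetry alone is invisible to regression betas (the predictor is the
    #: hemisphere mean, so scaling cancels); the group difference must live
    #: in the spatial distribution of the coupling, as it does in real data.
    asym_center_left_mm: tuple[float, float, float] = (-12.0, -18.0, 6.0)
    asym_radius_mm: float = 8.0
    asym_gain: float = 0.75
    motion_amp: float = 0.05
    csf_amp: float = 0.5
    wm_amp: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_volumes < 20:
            raise SimulationError("need at least 20 volumes")
        if self.tr_s <= 0:
            raise SimulationError("TR must be positive")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.shape, self.voxel_mm)


def make_tissue_masks(shape=(32, 32, 16)) -> dict[str, RoiMask]:
    """Toy tissue segmentation: interior gray-matter shell with small central
    CSF and white-matter boxes carved out."""
    nx, ny, nz = shape
    interior = np.zeros(shape, dtype=bool)
    interior[2:nx - 2, 2:ny - 2, 1:nz - 1] = True
    csf = np.zeros(shape, dtype=bool)
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    csf[cx - 2:cx + 2, cy - 2:cy + 2, cz - 1:cz + 1] = True
    wm = np.zeros(shape, dtype=bool)
    wm[cx - 4:cx + 4, cy - 6:cy - 3, cz - 2:cz + 2] = True
    wm &= ~csf
    gray = interior & ~csf & ~wm
    return {
        "gray": RoiMask(data=gray, side="none", label="gray"),
        "white": RoiMask(data=wm, side="none", label="white"),
        "csf": RoiMask(data=csf, side="none", label="csf"),
    }


def _band_limited(rng: np.random.Generator, t: int, tr_s: float) -> np.ndarray:
    """Unit-variance signal confined to the 0.01-0.1 Hz analysis band."""
    sig = bandpass(rng.normal(size=t), tr_s)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def simulate_resting(spec: RestingSpec, group_flag: str, seed: int,
                     subject_id: str = "") -> tuple[RestingRun, dict]:
    """One synthetic resting run with planted connectivity ground truth.

    ``group_flag`` is ``"typical"`` (left hemisphere carries the larger
    global component) or ``"atypical"`` (right carries it).  Returns the run
    and a truth record (planted betas, global amplitudes, component series).
    """
    if group_flag not in ("typical", "atypical"):
        raise ValueError("group_flag must be 'typical' or 'atypical'")
    rng = np.random.default_rng(seed)
    t = spec.n_volumes
    shape = spec.shape
    affine = spec.affine
    tissues = make_tissue_masks(shape)
    hemis = make_hemisphere_masks(shape)

    data = np.zeros(shape + (t,), dtype=np.float64)

    # seed-coupled signals
    seed_series = {}
    for planted in spec.seeds:
        s = _band_limited(rng, t, spec.tr_s)
        seed_series[planted.name] = s
        src = sphere_mask(planted.center_mm, planted.source_radius_mm, shape, affine)
        tgt = sphere_mask(planted.target_mm, planted.target_radius_mm, shape, affine)
        data[src.data] += s
        data[tgt.data] += planted.beta * s

    # hemisphere-wide global components over gray matter
    amp_left = spec.global_amp_dominant if group_flag == "typical" else spec.global_amp_other
    amp_right = spec.global_amp_other if group_flag == "typical" else spec.global_amp_dominant
    g_left = _band_limited(rng, t, spec.tr_s)
    g_right = _band_limited(rng, t, spec.tr_s)
    data[tissues["gray"].data & hemis.left.data] += amp_left * g_left
    data[tissues["gray"].data & hemis.right.data] += amp_right * g_right

    # dominant hemisphere's global component couples extra in its DMN-like
    # region; which side carries it is what distinguishes the groups
    if spec.asym_gain != 0 and (amp_left or amp_right):
        cl = spec.asym_center_left_mm
        if group_flag == "typical":
            region = sphere_mask(cl, spec.asym_radius_mm, shape, affine)
            data[region.data & tissues["gray"].data] += spec.asym_gain * g_left
        else:
            region = sphere_mask((-cl[0], cl[1], cl[2]), spec.asym_radius_mm,
                                 shape, affine)
            data[region.data & tissues["gray"].data] += spec.asym_gain * g_right

    # motion-correlated nuisance: random-walk parameters coupled through
    # random spatial maps (linear and squared terms)
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(t, 6)), axis=0)
    if spec.motion_amp > 0:
        for p in range(6):
            m = motion[:, p] - motion[:, p].mean()
            coupling = rng.normal(0.0, 1.0, size=shape)
            data += spec.motion_amp * coupling[..., None] * m[None, None, None, :]

    # CSF / WM compartment signals (slow drifts plus noise)
    csf_sig = _band_limited(rng, t, spec.tr_s)
    wm_sig = _band_limited(rng, t, spec.tr_s)
    if spec.csf_amp > 0:
        data[tissues["csf"].data] += spec.csf_amp * csf_sig
    if spec.wm_amp > 0:
        data[tissues["white"].data] += spec.wm_amp * wm_sig

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    run = RestingRun(data=data, affine=affine, tr_s=spec.tr_s, motion=motion,
                     gray=tissues["gray"], white=tissues["white"],
                     csf=tissues["csf"], hemispheres=hemis,
                     subject_id=subject_id)
    truth = {
        "group_flag": group_flag,
        "betas": {p.name: p.beta for p in spec.seeds},
        "global_amp_left": amp_left,
        "global_amp_right": amp_right,
        "asym_side": "left" if group_flag == "typical" else "right",
        "asym_gain": spec.asym_gain,
        "global_left_series": g_left,
        "global_right_series": g_right,
        "seed_series": seed_series,
    }
    return run, truth
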