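# Methods

This note documents the models and procedures `latmap` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show about real recordings.

## Coordinate and thresholding conventions

Voxel indices are 0-based; world space is RAS millimetres via the NIfTI
affine; the left hemisphere is world x < 0. "Suprathreshold" is strictly
`Z > threshold` everywhere. `flip_x` reverses the first grid axis and leaves
the affine untouched; this equals a world-space sagittal mirror exactly when
the x = 0 plane bisects the grid, and the synthetic group grid (64 × 64 × 35
voxels, 2 mm isotropic, centred) is built so that it does — no voxel centre
sits on the midline, so mirror symmetry is exact rather than resampled.
Cluster labelling uses 26-connectivity, a common volumetric default. The
extent filter in `label_clusters` is plain connected-component bookkeeping,
not a random-field cluster correction: critical cluster sizes from Gaussian
random field theory depend on the smoothness of real data and are out of
scope.

## Adaptive-threshold laterality index

For a pair of mirror ROIs, the top ⌈0.05·n⌉ Z values of each side (never
fewer than one voxel) are averaged; the subject's threshold is 0.5 × the
larger of the two side means. Counting suprathreshold voxels per side gives
LI = 100 (L − R)/(L + R), classified left-typical (LI > 33), bilateral
(−33 ≤ LI ≤ 33, boundaries inclusive — the conservative reading), or
right-atypical (LI < −33).

Which ROI anchors the top-5% mean is genuinely ambiguous ("one of the paired
ROIs" admits several readings), so the anchor is a config switch
(`source = "max" | "left" | "right" | "union"`). The default `"max"` — the
dominant side sets the threshold — is mirror-symmetric and deterministic,
which makes the mirror antisymmetry of the whole pipeline exact: flipping
the map negates the LI to machine precision. Whether negative-Z voxels are
excluded before the top-5% mean is immaterial under the error contract: a
non-positive anchoring mean raises instead of producing a threshold.

An LI with L + R = 0 is an error, never a silent NaN. LIs are reported to
one decimal in tables; full precision is kept internally.

Hemispheric *extent* applies the identical adaptive thresholding to a
hemispheric ROI pair and reports per-hemisphere and total suprathreshold
counts — the diffuseness statistic whose negative correlation with |LI|
operationalizes "bilateral organization uses more cortical tissue".

Handedness bookkeeping follows the Edinburgh inventory cutoffs: laterality
quotient ≥ +40 right-handed, ≤ −40 left-handed, ambidextrous between.

## Pattern-similarity graph

Subject similarity is the Pearson correlation of unthresholded Z values over
the masked ROI voxels. The matrix becomes a complete weighted graph; because
Newman–Girvan modularity is defined for non-negative weights, negative
correlations are truncated to zero (edge dropped) by default, with a
config option to shift all weights by +1 instead — how negative similarities
entered the original graph analysis is unstated, so both behaviours are
available. Communities are found by two-phase greedy (Louvain) modularity
maximization at resolution 1.0 with a seeded, deterministic node order
(networkx's implementation). Partitions are compared to reference labels by
Hungarian-matched accuracy, which is invariant to label permutation; the
reference "atypical" class pools bilateral and right-dominant subjects into
one group.

## Peaks

The peak is the ROI voxel with the maximal Z; ties break to the smallest
row-major linear index so results are deterministic. Axis comparisons are
performed on world-mm coordinates (not voxel indices) with Welch's t.
Subjects whose peak hemisphere contradicts their group's dominant side can
be flagged and excluded before the comparison, mirroring the exclusion of
discordant individuals in practice. No correction is attempted for
smoothing-induced peak displacement.

## Inferential primitives

Welch's unequal-variance t is computed from raw samples or from printed
group summaries (means, SDs, ns); the two paths agree to 1e-10 whenever the
sample moments match. Degrees of freedom are Welch–Satterthwaite; two-group
statistics are signed (second − first). The voxelwise two-sample t map
applies the same formulas per voxel with the contrast direction A − B;
voxels with zero variance in both groups are set to t = 0. No
multiple-testing correction is applied across the map by default — the
cluster-extent filter is the provided surrogate. Pearson correlations are
reported with df = n − 2 and a two-tailed p from t = r√(df/(1 − r²)).

## Resting-state connectivity

Runs are band-passed with a hard DFT window: frequency bins with
0.01 Hz < f < 0.1 Hz are kept, everything else including DC is zeroed, with
no tapering — exactly testable bin arithmetic. Motion parameters are
filtered identically. The nuisance design has 28 columns: the Friston-24
motion expansion ([m, m², one-volume lag, lagged²] per parameter, lag rows
zero-padded at t = 0) plus mean CSF and white-matter series each with its
backward difference (d₀ = 0). Nuisance removal is per-voxel OLS with an
intercept; residuals are orthogonal to every design column by construction,
and regressors are band-passed with the same window as the data so
regression cannot reintroduce out-of-band variance. A band-passed design
needs roughly 2·T·TR·(f_hi − f_lo) effective time points for its columns; at
the default T = 180, TR = 2 s there are ~42 pass-band dimensions for 28
columns, and shorter runs that cannot support the design raise a rank error
rather than fitting silently.

Seeds are 5 mm-radius spheres (voxels whose centres lie within the Euclidean
radius of the seed centre; on a 2 mm grid centred on a voxel this is 81
voxels). The hemispheric global signals — per-volume means over each
hemisphere's gray matter, split at world x = 0 with x = 0 voxels excluded —
enter the subject-level multiple regression as predictors of interest
alongside the seed series; the whole-brain global signal is deliberately
*not* regressed out, since its removal qualitatively alters group analyses
and it carries the lateralization signal of interest. Subject-level fits are
OLS (no prewhitening). The left > right hemispheric contrast is the beta
difference (and its negation); group comparisons are voxelwise Welch t maps
over subject contrast or beta images. Optional spatial smoothing is a plain
Gaussian at FWHM 6.2 mm (σ = FWHM/(2√(2 ln 2))), an approximation of
iterative smooth-to-target-FWHM procedures.

## Synthetic data: what it emulates

`CohortSpec` defaults encode the study conditions: 63 subjects in
83% / 9% / 8% proportions of left-typical, bilateral, and right-dominant
organization; a 64 × 64 × 35 grid at 2 mm; blob peak Z = 8 against unit
white Gaussian noise (the maps are already "statistical", so noise is in Z
units with no spatial autocorrelation by default); planted LIs drawn
uniformly within each class band (typical 50–100, bilateral −33–33,
right-dominant −100 to −50). Amplitude and noise defaults are calibration
choices — the real distribution of within-subject Z magnitudes is unknown.

Activation blobs are mirror-placed, mildly anisotropic super-Gaussian
(flat-top) profiles. Two generator-internal choices matter:

- *flat tops*: real activation clusters plateau near their maximal Z; a
  flat top also pins the adaptive threshold near half the peak amplitude,
  so the threshold does not drift with blob size;
- *mild y/z anisotropy* (x untouched, preserving exact mirror symmetry):
  lattice-symmetric shells around the blob centre would otherwise tie many
  kernel values and make achievable suprathreshold counts sparse.

The generator realizes a requested LI through the analysis pipeline itself:
the dominant blob width is solved (grid search over widths; counts are step
functions) so its noiseless suprathreshold count hits the target, and the
non-dominant amplitude is then solved in closed form from the sorted kernel
values to hit the count ratio (100 − |LI|)/(100 + |LI|). Counts are
integers, so the planted LI is quantized (within ~3 LI units at the default
extent); the realized value is recorded in the truth table, and infeasible
requests raise rather than clip. Each subject's total planted count is
`base_count · jitter · (1 + κ(1 − |LI|/100))` with κ = 1.5 by default — the
simplest monotone mechanism producing the diffuseness effect — and a ±20%
uniform jitter so that at κ = 0 the planted extent varies but is independent
of the LI. Extent is measured on per-hemisphere *simulated-cortex* masks
(the ROI boxes dilated by 2 voxels): the toy brain's only gray matter is the
peri-ROI region, and an adaptive top-5% pool much larger than the activation
would be dominated by noise order statistics rather than signal. Metadata
(Edinburgh scores, sex, age) are sampled with left-handers and ambidextrals
enriched in the atypical groups.

Resting runs (default 32 × 32 × 16 at 2 mm, 180 volumes, TR 2 s) sum: a
band-limited seed signal with unit coupling in a source sphere and a known
beta in a target sphere; hemisphere-wide global components over gray matter
whose amplitudes (1.0 dominant / 0.5 other) switch sides with the group
flag; an extra-gain (0.75) coupling of the dominant hemisphere's global
component in a mirrored "default-mode-like" region — a uniform amplitude
asymmetry alone is invisible to regression betas, since scaling the
hemisphere-mean predictor cancels, so the group difference must live in the
spatial distribution of the coupling, as it does in real data; random-walk
motion parameters coupled through random spatial maps; CSF/WM compartment
signals; and white noise. Every generator takes an explicit seed and is
bit-for-bit reproducible; truth tables accompany all outputs and no analysis
stage reads them.

What passing tests do **not** show about real data: the generator has no
spatial autocorrelation, no physiological or scanner noise structure, no
registration error, no inter-subject anatomical variability, and blob
geometry far simpler than real activation topographies. Recovery statistics
(LI correlation > 0.9, seed-beta RMSE ≤ 0.1) certify the estimators against
their own generative model, not field performance.

## Pipeline and problem sizes

`run_pipeline` chains simulate → laterality table → graph classification →
peaks → extent correlation → resting connectivity → group contrast, derives
all stage seeds from one config seed, and emits a JSON + Markdown report that
is byte-identical across reruns; estimates are joined to generator truth only
in a clearly labelled evaluation section. Default problem sizes are chosen so
a full run completes in seconds on one core: 63 task maps on the full group
grid, and 3 resting subjects per group at 120 volumes on the 32 × 32 × 16
grid (the single-subject default remains 180 volumes). Degenerate configs
(n = 2 cohorts, too few handers for a comparison) produce warnings in the
report rather than failures.

## Known limitations

- The LI is the voxel-count variant only; bootstrap/histogram LI estimators
  are deliberately out of scope.
- No GLM fitting from raw task time series: synthetic Z-maps stand in for
  first-level outputs.
- No mixed-effects group models, prewhitening, motion scrubbing, slice
  timing, registration, or surface-based analysis.
- The hemispheric split at x = 0 assumes spatially normalized, midline-
  aligned volumes.
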