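# Methods

`lnmap` implements literature-based lesion network mapping (LNM) for
dyskinetic cerebral palsy (DCP): given binary lesion tracings and a
normative resting-state connectome on a shared voxel grid, it derives the
functional network common to the lesions, tests its statistical
robustness, specificity and stability, parcellates the thalamus by
cortical connectivity, and tabulates the systematic-review lesion
patterns. This note describes the models, the parameters that matter, the
synthetic study designs the tests run on, and the numerical conventions.

## Seed connectivity and T-maps

Each case's lesion mask (possibly multi-focal; all foci of one case form
one seed) is averaged over voxels to a seed BOLD series per connectome
subject, and Pearson-correlated with every brain-mask voxel's series.
The per-subject r values are summarised voxel-wise with a one-sample
t-test across the `n` subjects,

    t(v) = mean_j r_j(v) / ( sd_j r_j(v) / sqrt(n) ),   df = n - 1,

with the sample standard deviation (n−1 denominator). By default the
test runs on raw r values; `use_fisher_z=True` applies the arctanh
variance-stabilising transform first (a conventional alternative; it is
monotone and odd, so on realistic connectivity data the t-score signs
agree between the two choices, though this is not an algebraic identity
for arbitrary inputs).

Two degenerate situations are handled explicitly rather than silently:

* a voxel whose time series has zero variance in any subject is flagged
  *undefined* and excluded from all downstream stages (binarisation,
  overlap, permutation pools), so absent signal can never read as
  connectivity;
* zero sample variance of the r values with nonzero mean yields a
  saturation sentinel t = ±1e9 instead of ±inf; it binarises correctly
  and is never interpreted as a finite statistic.

Per-subject series may differ in length; r is computed on each subject's
full series. fMRI preprocessing is out of scope; inputs must already
share one grid (mismatches are errors, never implicit resampling).

## Binary-overlap LNM

Case T-maps are thresholded strictly at `t > t_threshold` (default 7; at
df = 99 this corresponds to an uncorrected two-sided p ≈ 3e-10, far
below 0.001), binarised and summed. The lesion network map keeps voxels
connected to at least `frac` of the cases with

    min_count = ceil(frac * n_cases)

(default frac 0.95: 22 of 23 cases). The product is computed with a
1e-9 slack so that exact products (0.95 × 20 = 19) are not bumped up by
floating-point representation. Raising the threshold can only shrink
overlap counts, and raising frac can only shrink the map (tested
invariants).

## Permutation inference

Both permutation tests control family-wise error with the max-statistic
method: each voxel's observed statistic is compared against the
permutation distribution of the image-wide maximum (over the jointly
defined voxels only).

* **Sign-flip one-sample test** (default 5000 permutations, α 0.05):
  the observed statistic is the voxel-wise one-sample t over case T-map
  values; each permutation independently negates whole case maps. Valid
  under symmetric, independent case maps.
* **Two-sample contrast** (specificity): voxel-wise pooled-variance
  two-sample t (Welch available via `equal_var=False`); the null
  relabels cases into groups of the original sizes.

Monte-Carlo p-values use add-one counting, p = (1 + b)/(1 + B), so p is
never 0. Whenever the full group (2^n sign patterns, or C(n, n_a)
relabelings) fits within the permutation budget the null is enumerated
exhaustively and p-values are exact, with the identity permutation
included (smallest attainable p = 1/2^n or 1/C(n, n_a)). The observed
statistic is computed through the same arithmetic path as the permuted
statistics so the identity permutation ties with it exactly. The default
tail is one-sided positive — the analysis targets connected, not
anti-connected, voxels — with a two-sided option.

## Specificity and stability

Specificity contrasts the disease cohort's T-maps against a control
cohort (grey-matter spheres of 12 mm radius, 100 masks by default, with
centers drawn uniformly over grey-matter voxels without replacement so
all masks are distinct).

Stability repeats the overlap analysis over `n_subsets` (default 100)
distinct random subsets leaving k cases out (defaults k ∈ {5, 7, 9}) and
correlates each subset's overlap-*fraction* map (count / subset size)
with the full-cohort fraction map by spatial Pearson correlation over
in-mask voxels. Continuous fraction maps are correlated rather than the
binary thresholded maps, whose near-degenerate variance makes Pearson r
unstable; this interpretation is a deliberate design choice.

## Winner-takes-all thalamic parcellation

Per subject, each cortical ROI group's mean series (groups
motor/associative/limbic/other, supplied as an integer label volume) is
correlated with every target-structure voxel; correlations are averaged
across subjects (optionally Fisher z first) and each voxel takes the
argmax label. Exact ties go to the lowest-index label and are flagged.
The average is symmetric in subjects, so subject order cannot change the
atlas. Per-lesion parcel strength is the mean case T-map value over the
parcel's usable voxels (peak available via `reduction="peak"`; mean is
the default for robustness). Parcels are compared with a
repeated-measures ANOVA (within-case factor = parcel) followed by all
pairwise paired t-tests, Bonferroni-corrected by the number of pairs (6
for four parcels) and capped at 1. The repeated-measures flavour matches
the paired post-hoc structure of the data. A control variant removes a
region (e.g. the thalamus) from every seed, dropping cases left empty
with a logged notice.

## Review tabulation

Study findings follow a controlled vocabulary (the MRICS general
categories, the grey-matter sub-patterns and specific subcortical
sites). After dropping studies excluded for reporting bias, each
finding is pooled over the studies reporting it: number of studies,
total patients, affected patients, and the percentage rounded half-up to
an integer (the convention that reproduces every published pooled pair,
e.g. 451/893 → 51 and 296/597 → 50). The bundled
`data/dcp_review_counts.tsv` fixture carries the pooled count pairs of
the DCP review, not the ~40 underlying per-study rows.

## Synthetic data: what it emulates, and what it does not

The generator plants latent-network structure in Gaussian noise: each
*node region* (an arbitrary voxel set) has its own i.i.d. standard-normal
latent signal per subject and timepoint, and a member voxel's series is
`coupling · latent + N(0, noise_sd)`; voxels in several regions sum the
contributions; voxels in none are pure noise. There is no temporal
autocorrelation, haemodynamics, head motion or age structure — the
estimators consume only spatial correlation, and this is the simplest
process that exercises them. Passing tests therefore demonstrate correct
statistics and recovery under the assumed covariance structure, not
performance on real paediatric fMRI.

**Planted-network study** (defaults; used by the recovery, replication,
stability and specificity checks): a 24×28×24 grid at 2 mm isotropic
with an ellipsoidal brain mask (~6200 voxels); a central hub sphere of
8 mm radius (pseudo-thalamus, 257 voxels) and eight peripheral 3 mm
foci on the corner diagonals. Each focus carries its own latent, and
every focus's region also includes the hub, so the hub fluctuates with
all foci while the foci stay mutually independent — heterogeneous
lesions converging on a single network node, which is precisely the
structure lesion network mapping is designed to detect. (A single latent
shared by the whole network would make all case maps near-identical and
smear permutation significance over the whole brain.) The 23 lesions are
3 mm blobs centred on randomly chosen focus voxels, so the hub itself
stays lesion-free and hub recovery can be scored by Dice. Study
conditions follow the analysis being emulated: 100 subjects × 150
timepoints, coupling 0.8, noise sd 1.

**Null calibration**: the family-wise error rate of the sign-flip test
is measured on a global-null connectome (no regions) with 12
single-voxel seeds at distinct centers — pairwise disjoint, because
overlapping seeds share signal and violate the independence the
sign-flip exchangeability argument needs (shared-focus seed cohorts
empirically inflate the family-wise rate several-fold even under the
global null; this is a property of the test, not of the
implementation). Scale: 14×14×14 grid, 20 subjects × 60 timepoints,
200 runs × 200 permutations, chosen as a desk-scale design whose
binomial tolerance (α + 1.96·√(α(1−α)/200) ≈ 0.08) is still
informative.

**Specificity study**: control spheres are placed on grey matter
*outside* the planted network, emulating a control lesion cohort that
does not sit on the disease network (a sphere landing on the network
would itself become a network seed and erase the very contrast under
test). The label-shuffle null reuses the pooled cohort, so repeated
shuffles are dependent; the empirical rate is checked over 100 shuffles
against the binomial bound.

**Winner-takes-all recovery**: four cortical ROI blobs with their own
latents; every target voxel is planted to carry exactly one ROI's
latent with near-zero noise (1e-6), so the parcellation must recover
the assignment exactly.

## Numerical conventions and edge cases

* Voxel indexing is 0-based; in-mask vectors follow row-major (C) order
  over the brain mask; written statistic maps put 0 outside the mask and
  the mask is written alongside.
* NIfTI-1 (.nii/.nii.gz) throughout, via nibabel; binary masks round-trip
  bit-exactly (uint8), statistics as float32 (round-trip within 1e-6).
* Permutation draws, connectome noise, lesion placement and subset
  sampling all use `numpy.random.default_rng` seeded explicitly; every
  pipeline output embeds the config and seed in a JSON manifest, and a
  rerun with the same seed is byte-identical.
* Leave-k-out subsets are drawn without duplicate combinations, and
  requesting more distinct subsets than exist is an error; k = 0 is
  allowed (degenerate, correlation 1) for testing.
* Degenerate inputs fail loudly: zero-variance seeds, empty ROI groups,
  all-zero case maps (warned, p = 1), lesions emptied by masking
  (dropped with notice; error if all are), grid mismatches.

## Known limitations

* No spatial smoothing, cluster-extent or TFCE inference; voxel-wise
  max-statistic FWE only.
* The sign-flip test assumes independent case maps; heavily overlapping
  lesions violate this (the real analysis shares the limitation).
* The synthetic connectome's white noise makes recovery easier than real
  fMRI with autocorrelated, motion-contaminated signals; reported Dice
  values characterise the implementation, not expected clinical
  performance.
* Registration/normalisation, surface rendering, atlas-based anatomy and
  the retrieval of real cohorts are out of scope; all inputs must share
  one voxel grid.
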