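# Methods

`fcmanifold` implements an analysis pipeline for tracking large-scale
reorganization of task-based functional connectivity (FC) across the epochs of
a two-day motor-adaptation experiment, together with a synthetic-data
generator that emulates the statistical structure of such a study so that
every stage can be validated against known ground truth.

## Covariance estimation

Parcellated BOLD time series (regions × volumes) are z-scored per region using
the population (n) denominator — the choice of denominator is immaterial after
standardization — and spliced into five equal-length task epochs of 96 volumes
(48 trials at 2 volumes/trial) per day: Baseline, Early Learning, Late
Learning, Early Washout, Late Washout. Equal epoch lengths avoid biasing the
covariance estimates. The first 6 volumes of each scan are discarded. The
Baseline epoch is the first post-discard window of the task scan and the
Early/Late Washout epochs are the first/last windows of the washout scan;
where the experiment offers more trials than one window, the first-window
choice matches the "early" semantics and is configurable.

Each epoch's FC matrix is the Ledoit–Wolf shrinkage covariance (scikit-learn),
which is symmetric positive-definite (SPD) even when regions outnumber
volumes, as they do at 464 regions × 96 volumes.

## Riemannian subject centering

Stable subject-specific covariance signatures dominate raw FC similarity and
mask task structure. Centering removes them on the SPD manifold under the
affine-invariant metric. With per-subject geometric (Karcher) means S̄ᵢ over
all 10 epochs and the grand geometric mean S̄ over every subject and epoch,
each epoch matrix S is

1. projected to the tangent space at its subject mean,
   T = S̄ᵢ^{1/2} log(S̄ᵢ^{-1/2} S S̄ᵢ^{-1/2}) S̄ᵢ^{1/2};
2. parallel-transported to the grand mean, T′ = G T Gᵀ with
   G = S̄^{1/2} S̄ᵢ^{-1/2};
3. retracted, S′ = S̄^{1/2} exp(S̄^{-1/2} T′ S̄^{-1/2}) S̄^{1/2}.

Because the transport is linear and the subject mean satisfies the Karcher
first-order condition, the geometric mean of each subject's centered matrices
equals the grand mean exactly (to solver tolerance); this fixed point is
asserted in the tests at 1e-6 affine distance.

Numerical choices: the Karcher mean is initialized at the log-Euclidean mean
and iterated with the unit-step fixed point M ← M^{1/2} exp(mean log)
M^{1/2}, tolerance 1e-8 on the Frobenius norm of the mean tangent, at most 50
iterations (non-convergence raises, carrying the residual). All
eigendecompositions use symmetric solvers; every output is re-symmetrized;
eigenvalues below 1e-10 × λmax are floored (with a warning) before logs and
inverse powers. The module is deterministic.

## Manifold embedding and eccentricity

Each centered matrix is row-thresholded (top 10% of off-diagonal entries per
row, k = ⌈0.10 (n−1)⌉, ties broken toward the lower region index, diagonal
excluded, surviving values retained), converted to a cosine-similarity
affinity matrix between rows (negative affinities are kept — clipping would be
an undocumented transform), and embedded by column-centered PCA. The top 3
components are retained. Component signs follow a fixed convention (largest
|score| entry made positive).

A template Baseline manifold is built from the geometric mean of each
subject's two Baseline matrices, then the geometric mean across subjects, then
the same threshold→affinity→PCA chain. Every per-subject, per-epoch embedding
is aligned to the template by orthogonal Procrustes (translation + rotation /
reflection, **no scaling** — scaling would distort eccentricity magnitudes
across epochs). Eccentricity of a region is its Euclidean distance from the
template centroid (the origin after centering), fixed for all epochs:
per-epoch centroids would absorb the very shifts being measured. Low
eccentricity = integrated (brain-wide, diverse connectivity profile); high =
segregated (network-specific profile).

## Statistics

* Region-wise 2 (Day) × 5 (Epoch) repeated-measures ANOVA on eccentricity,
  vectorized across regions; each main effect is tested against its
  effect-by-subject interaction, the interaction against the three-way
  residual. No sphericity correction is applied, so the Epoch effect carries
  df (4, 4(n−1)) and the 7-level profile omnibus df (6, 6(n−1)). The
  implementation is cross-checked against pingouin in the test-suite.
* Benjamini–Hochberg FDR (statsmodels) at q = 0.05.
* Post-hoc paired t contrasts on day-averaged epoch values.
* Functional ensembles: k-means (k = 4, 50 restarts, seeded) on the template
  coordinates of significant regions; cluster ids are relabeled by descending
  size (ties by lowest member index) and annotated with the modal network.
* Reinstatement RSA: per subject, the Pearson (or Spearman) spatial
  correlation between the Day-1 Early Learning eccentricity pattern and each
  of the 7 subsequent epochs, restricted to an ensemble's regions; an omnibus
  one-way rmANOVA over the 7 similarity values, then six one-tailed paired
  t-tests of Day-2 Early Learning similarity against each other epoch
  (uncorrected, following common reporting practice for planned contrasts).
* Network–behavior correlations: Pearson r across subjects between
  network-mean eccentricity change and the Learning Score; significance by a
  spin permutation test: a uniform random 3-D rotation (mirrored across
  hemispheres) is applied to the regions' spherical centroids, regions are
  reassigned one-to-one to their nearest rotated neighbour (greedy by
  distance) within each hemisphere, and the network correlations are
  recomputed; p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm) (add-one, so p is
  never 0), BH-corrected across the 7 networks. Without spherical
  coordinates the test falls back to a plain region-label permutation and
  flags it.

## Behavior

Trials with reaction time < 100 ms, > 2000 ms, or missing (movement never
initiated) are flagged, not deleted. Signed angular errors are averaged into
8-trial bins (excluded trials ignored; fully-excluded bins linearly
interpolated). Initial error is the median of the first 16 learning trials;
savings = Day-1 initial error − Day-2 initial error. The adaptation proxy is
A = 45° − |error|; the Recall Ratio is RR = A(Day-2 early) / A(Day-1 late)
over the same 48-trial windows used for the imaging epochs, undefined when
the denominator is below a 5° stability threshold (the subject is then
excluded from RR correlations only; flooring the denominator instead is
available by option). The window choice and the exclusion-versus-floor
reading of the threshold were open details; both are configurable.

The Learning Score is the first functional principal component loading of the
smoothed two-day binned error curve, sign-fixed so that higher scores mean
lower error. Smoothing uses a cubic B-spline basis with 17 basis functions
and a second-derivative roughness penalty whose single weight is selected by
generalized cross-validation over a log-spaced grid (1e-4…1e4) and recorded.
Seventeen basis functions cannot have one knot per bin center on a 140-bin
curve, so the knots are spaced evenly over the curve domain. fPCA is a
trapezoid-weighted PCA of the smoothed curves on the bin grid. Fast/slow
learner groups come from a strict greater-than-median split of the scores
(equal halves at even n).

## Synthetic data

The generator emulates the study design — N subjects × 2 days × 5 epochs × 96
Gaussian volumes plus two-day trial tables — with known ground truth, not the
biophysics of BOLD (no hemodynamics, no motion, temporal autocorrelation only
via an optional AR(1) switch; the pipeline does not model autocorrelation
either).

Connectivity: every region has a latent 3-D "functional geometry" position;
network centroids sit at staggered radii and regions scatter around them
(τ = 0.8, except the association/DMN-analogue network Net1: a tight τ = 0.35
module at the largest radius — functionally segregated, highest baseline
eccentricity, mirroring transmodal cortex at the apex of the connectivity
gradient). The base covariance Σ₀ is a Gaussian kernel of latent distance
(amplitude 0.35, length 1.0, floor 0.03, edge jitter 0.02, unit diagonal, a
diagonal ridge guarantees SPD). Subject-epoch covariances are composed
additively in the tangent space at Σ₀ — stable subject signature Dᵢ (entry SD
0.10), shared epoch effect Eⱼ, subject-by-epoch noise (entry SD 0.01) — and
retracted with the exponential map, which keeps every covariance SPD at any
effect scale. Shared epoch effects are covariance deltas induced by random
latent displacement fields (SD 0.5); Baseline epochs carry no effect; with
the reinstatement flag the Day-2 Early Learning effect equals the Day-1 one
exactly.

The planted contraction mixes each target region's coupling row toward the
brain-average coupling row (default fraction 0.6, graded 0.4–1.6× across
targets so the effect has a spatial pattern for the RSA to detect): the
targets' within-network couplings weaken, their between-network couplings
strengthen, and their eccentricity drops. Expansion sharpens the rows away
from the average instead. This construction was selected because, among
several geometrically plausible alternatives, it is the one whose
eccentricity imprint through the full pipeline is reliably confined to the
targets; non-target thresholded profiles are essentially untouched, so
false-discovery accounting against the planted targets is meaningful.

Behavior: learning errors decay as 45·exp(−ρᵢt) + ε (ε SD 4°), ρᵢ log-normal
(median 0.045/trial, log-SD 0.5), Day-2 rates × 1.8 (savings), washout a
mirrored aftereffect of 0.6 amplitude decaying twice as fast, baseline pure
noise; 1% of reaction times fall outside the QC bounds.

Effect scales are deliberately larger than real task-fMRI effects: at
desk-scale problem sizes (≈16–24 subjects, 70–100 regions, 96 volumes) the
sampling noise of a 96-volume covariance is substantial, and the generator's
purpose is a testable ground truth, not realism of effect size. Passing tests
therefore demonstrate correctness and calibration of the machinery, not the
detectability of subtle real-world effects; conversely the Gaussian,
autocorrelation-free volumes make the Ledoit–Wolf estimates slightly cleaner
than real denoised BOLD.

## Simulation experiments and problem sizes

The `experiments` module fixes the validation conditions: subject-structure
removal at 24 subjects × 100 regions (subject scale raised to 0.25 with epoch
scale 0.05 — the σ_D ≫ σ_E regime the comparison probes); contraction
detection at 16 subjects × 70 regions × 50 replicates with the shared epoch
effects off, so non-targets are genuinely null and a realized false-discovery
proportion against the planted targets is well defined; reinstatement at 20
subjects × 70 regions × 50 replicates. Because epoch effects are shared
across subjects, epochs genuinely differ within any single dataset; the null
for the profile omnibus therefore shuffles each subject's 7-epoch similarity
profile independently, which enforces exchangeability while preserving the
values. Spin-test calibration uses 200 unstructured maps against one set of
1000 spins (the spin null is conditional on the parcellation). These sizes
keep each experiment in the minutes range on one core.

## Known limitations

* A symmetric covariance effect planted on 10 target rows necessarily also
  changes every other region's couplings *to* those targets. Regions strongly
  coupled to the targets therefore carry genuine secondary epoch effects, and
  the region-wise ANOVA correctly flags some of them; when false discoveries
  are scored against the planted-target labels alone, the realized
  false-discovery proportion is inflated to ≈ 0.12 (the pure-null BH
  contribution would be ≈ 0.04). This is a property of covariance geometry,
  not of the inference machinery.

* The affinity spectrum of a clustered connectome is only moderately gapped
  after the third component, so per-epoch embeddings rotate slightly within
  the top-3 subspace before Procrustes alignment; this is the dominant noise
  source in eccentricity and is inherent to the 3-component choice.
* The greedy spin reassignment is one member of the rotation-permutation
  family; exact per-network rejection rates are mildly conservative
  (observed ≈ 0.03–0.07 at α = 0.05).
* The fPCA smoothing penalty is selected once for all subjects (mean GCV),
  not per subject.
* `center_dataset` estimates one grand mean over all matrices; very large
  cohorts would want a streaming/chunked variant.
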