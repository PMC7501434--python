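# Methods

`strokefc` re-implements, as a tested and reusable pipeline, a
functional-connectome group analysis comparing sub-acute stroke patients
with healthy controls at rest and under two loads of an attentive
multiple-object-tracking (MOT) task. This note documents the models, the
estimators, the defaults and the choices made where the design was open.

## Generative model (synthetic cohorts)

Real node time series for this design are not publicly deposited, so the
package ships a generator whose output carries exactly the statistical
structure the downstream stages estimate.

Ground truth is specified per (group, condition) cell directly in partial
correlations — the quantity the network stage estimates. A target matrix
P with unit diagonal and the requested edge values off-diagonal is
converted to a precision matrix

    Θ = c · (I − P_off),

where P_off holds the off-diagonal targets. Because −Θij/√(ΘiiΘjj) is
invariant to the uniform scale c, the implied partial correlations equal
the targets exactly for any c; c is chosen so the smallest eigenvalue of
Θ is at least 0.1. Background (non-effect) edges are drawn on a random
graph (edge probability = `sparsity`, default 0.1; magnitudes uniform in
[0.1, 0.3] with random sign) and, if positive definiteness fails, are
shrunk by a single factor shared by every cell — shared so that shrinking
can never masquerade as a group or condition effect. Requested effect
edges are never altered; an unrealizable request raises an error naming
the offending edge.

Frames are i.i.d. Gaussian draws from the implied covariance. Nodal
standard deviations (the SDSA ground truth) enter as an outer diagonal
scaling of the correlation matrix, which leaves partial correlations
untouched; SDSA effects and edge effects are therefore orthogonal by
construction. An optional AR(1) coefficient (variance-preserving) adds
temporal smoothness as a realism knob; it is off by default because the
edge definition uses only contemporaneous correlation.

Default study conditions mirror the cohort being emulated: 44 patients
and 100 controls; 30 nodes (435 edges); 200 resting frames and 152 frames
per task load; three conditions per subject. Default effects: ~20
condition-modulated edges with |Δρ| between 0.1 and 0.3 (monotone in
load), one patient–control offset edge with Δρ = 0.1 constant across
conditions (the temporal–sensorimotor analog, nodes 23–27 when K = 30),
and a 20% task-related decrease of signal SD on 4 "task-negative" nodes.
The magnitudes are calibration choices — no empirical edge-strength
distribution is published for this cohort — picked so the qualitative
result pattern (near-ceiling condition classification, chance-level group
classification, a single recoverable group edge, a clear SDSA condition
effect) is reproduced at desk scale. On small graphs the default builder
caps the number of condition edges at a fifth of the available pairs so
the model stays positive definite.

What the generator does **not** emulate: hemodynamics, realistic fMRI
noise spectra, head motion, scanner drift, spatially correlated ICA maps,
or lesion heterogeneity. Passing tests therefore demonstrate correctness
of the estimators and the statistical pipeline under the assumed Gaussian
graphical model — not robustness to the full physics of fMRI.

## Dual regression

Stage 1 regresses the demeaned group spatial maps (plus, optionally, a
binary lesion mask as an extra column) into each frame of the subject's
voxel×time dataset, giving one time series per map; stage 2 regresses
those (demeaned) time series back into the dataset, giving
subject-specific maps. The lesion time series is estimated jointly — so
variance shared with the lesion is assigned to the lesion column — and
then discarded before network modeling. Regressors are demeaned, not
variance-normalized (the standard convention; normalization is exposed as
an option). Rank-deficient designs fail loudly, naming the collinear
columns.

Head motion is summarized as the mean frame-to-frame RMS displacement of
a sphere of radius R (default 80 mm, the convention of the tool family
used for motion correction): for consecutive frames,
√(R²/5 · tr(MᵀM) + tᵀt), with M the difference of the two rotation
matrices and t the difference of the two translations. Rotations are
interpreted as extrinsic x, y, z Euler angles about the volume center;
the source convention is not documented, so this choice is recorded here
and in output metadata. Optional confound regression residualizes node
time series on a T×6 motion trace (no derivatives or squares, which are
likewise undocumented at the source).

## Network estimation

Each run's time series are standardized to zero mean and unit variance,
so the empirical second-moment matrix is a correlation matrix and the
penalty is comparable across runs; SDSA is computed upstream of this
standardization, which would otherwise erase it. Edges are partial
correlations −Θij/√(ΘiiΘjj) from an L1-penalized precision estimate
(graphical lasso, diagonal unpenalized; solver:
`sklearn.covariance.graphical_lasso`). λ = 0 returns the unpenalized MLE
(inverse sample correlation, requiring T > K). A ridge-penalized
alternative ((S + λI)⁻¹) sits behind the same interface for sensitivity
checks.

The penalty is selected per run by 5-fold cross-validation on contiguous
frame blocks (blocks, not random frames, to respect possible temporal
autocorrelation), scoring the held-out Gaussian log-likelihood
log det Θ − tr(S_test Θ) over a default grid of 20 log-spaced values in
[0.01, 1]; exact ties go to the larger (more parsimonious) penalty.
Whether the original analysis selected one penalty per run, per subject
or globally is unstated; per run is the default here. Edge vectors use
row-major upper-triangle order, `edge_1_2 … edge_{K−1}_{K}`, recorded in
table headers so downstream stages agree on the ordering.

Non-convergence of the lasso solver within the iteration cap is flagged
on the returned estimate rather than raised, and the partial result is
returned.

## Classification

The classifier is linear discriminant analysis with the pooled
within-class covariance shrunk toward its diagonal,
Σ* = (1 − γ)Σ + γ·diag(Σ). γ is the analytic (variance-of-entries)
optimal intensity: the summed sampling variances of the off-diagonal
entries of Σ divided by their summed squares, clipped to [0, 1]. With
γ > 0, Σ* is positive definite for any sample size, which is what makes
the 435-edge feature space usable with at most a few hundred runs. Priors
are uniform by default (designs are balanced after subsampling). Fitting
requires at least two samples per class.

Cross-validation always leaves out whole subjects ("leave-one-out" at
subject granularity): a subject's three runs are dependent, and row-level
folds would leak identity. Reported accuracy is the mean of per-class
accuracies (balanced accuracy); the analytic chance level 1/L is reported
alongside the permutation null.

Group classification removes the 44-vs-100 imbalance by repeatedly
(default 25 iterations at desk scale, 100 at paper scale) subsampling
controls without replacement to the patient count, running
leave-one-subject-out on each balanced subset and averaging per-class
accuracies. Equal group sizes degenerate to plain leave-one-subject-out.

Permutation tests rebuild the null of the accuracy statistic: group
labels are permuted across subjects (group task) or condition labels
within each subject (condition task), and p = (1 + #{null ≥ observed}) /
(n_perm + 1) — the add-one convention, a valid finite-sample p that is
never exactly 0. For the group task the null runner uses a single
balanced subsample per permutation; the observed statistic uses the full
iteration count. Desk-scale default is 100 permutations; the paper-scale
preset restores 10,000.

## Group statistics

Edgewise and nodewise inference uses a mixed-design (split-plot) ANOVA:
one between-subject factor (group) and one within-subject factor
(condition). Effect sums of squares are Type III (sum-to-zero contrasts),
the appropriate convention for the unbalanced two-group design; the group
effect is tested against the subject-within-group mean square, condition
and interaction against the condition×subject-within-group mean square.
The implementation is vectorized across edges (QR projections shared by
all response columns), which is what makes 10⁴-edge calibration runs
cheap. Constant (zero-variance) responses are flagged degenerate and
reported as F = 0 rather than 0/0. No sphericity correction is applied by
default — plain F tests are reported — with a Greenhouse–Geisser option
available. Multiplicity is controlled by Benjamini–Hochberg FDR at
q = 0.05, applied separately per effect.

SDSA is the sample standard deviation (denominator T − 1) of each node's
raw time series. Cohort-level summary comparisons use Welch's
unequal-variance t (which reproduces the published cohort table; a pooled
t does not) with the Welch–Satterthwaite df, and Pearson's chi-square
without continuity correction for 2×2 tables. Zero variance in both
groups with equal means returns t = 0 by convention.

## Numerical and testing choices

- All randomness flows from explicit integer seeds; cohort generation
  spawns per-run seeds from a single seed sequence, so outputs are
  byte-identical across reruns of the same config.
- Acceptance-style simulation tests run at desk scale: 10-node graphs
  (45 edges), 20–144 subjects, 25 subsampling iterations, 100
  permutations, and the unpenalized (λ = 0) estimator where many
  replicate cohorts are needed; the cross-validated graphical lasso is
  used where estimation quality is itself under test (condition
  classification, parameter recovery at K = 30).
- The lesion-decontamination checks orthogonalize the true node series
  against the lesion signal in-sample, so the measured correlation
  isolates method-induced contamination instead of the O(1/√T) chance
  correlation of independent signals.
- The published cohort table's response-time rows print summary SDs to
  one decimal; recomputed t statistics are not meaningful at ±0.02 there,
  so the recomputation checks cover the rows whose inputs carry two
  significant decimals (age, education, MoCA, MOT accuracy at both
  loads). The handedness chi-square row is internally inconsistent at
  df = 1 and is not reproduced.
- The 3-class condition task reports the analytic chance level 1/3; a
  "30%" chance figure circulates for this design without derivation, and
  the package reports both the analytic level and the permutation null
  rather than guessing its origin.

## Known limitations

- Group ICA is out of scope: ground-truth or user-supplied maps play the
  role of the estimated components.
- No motion correction, smoothing, temporal filtering, registration, or
  ICA-based denoising; inputs are assumed to be clean node time series or
  toy volumes.
- The Gaussian generator cannot probe robustness to non-Gaussian noise,
  autocorrelated confounds (beyond the AR(1) knob), or lesion-induced
  spatial distortion of the maps.
- The balanced-accuracy permutation null for the group task is built from
  single-subsample runs; with very small cohorts its variance exceeds
  that of the observed statistic, making the test mildly conservative.
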