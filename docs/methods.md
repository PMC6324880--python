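# Methods

## Overview

`wmconn` implements a normative connectome-based prediction of working-memory
ability (WMA) and its decomposition across psychiatric diagnoses. The chain
is:

1. **Behavioural target.** WMA is the learning plateau `a` of an inverse
   curve `y = a - b/x` fitted to per-session n-back sensitivity d' =
   z(hit rate) - z(false-alarm rate), after a five-session moving average.
2. **Connectivity features.** Resting-state voxel time series are reduced to
   171 network-level features on an 18-network parcellation: 18
   within-network values (mean pairwise voxel correlation) and 153
   between-network values (Pearson correlation of voxel-mean courses).
   Raw correlations are used as features; no Fisher z-transform.
3. **Normative model.** A sparse Bayesian (ARD) linear regression maps the
   171 features to WMA in healthy subjects; irrelevant connections are
   pruned automatically.
4. **Generalization.** The fixed model is applied to independent cohorts;
   predictions are evaluated with confound-partialled (Pearson/Spearman)
   correlations whose permutation null preserves subject-confound links,
   and with group contrasts (pooled-variance t, Bonferroni; Hedges g with
   95% CI; one-way ANOVA with Holm post-hocs and a Bartlett report).
5. **Decomposition.** Because the prediction is a weighted sum, a patient's
   predicted deviation from the control mean decomposes exactly into
   per-connection D-scores, standardized to Z-scores by the control SD of
   weighted FC; diagnosis and connection effects are tested by permutation
   two-way ANOVA, per-connection Kruskal-Wallis with Benjamini-Hochberg
   FDR, a KS comparison of selected vs excluded connections, and
   cluster-level summed D-scores over between-cluster connections.

All results in this repository are computed on cohorts from the package's
own synthetic generator, which plants known ground truth.

## Preprocessing choices

- **Framewise displacement** uses the Power formulation: the sum of absolute
  backward differences of the six realignment parameters, rotations
  converted to arc length at a 50 mm head radius. Frames with FD > 0.5 mm
  are scrubbed; neighbours are retained. Subjects losing more than 40% of
  frames are flagged for exclusion.
- **Order of operations**: (optional band-pass) -> nuisance regression of
  the six motion parameters plus gray-matter/white-matter/CSF mean signals
  (with intercept) on the full series -> scrubbing -> correlation. The
  0.009-0.08 Hz zero-phase Butterworth band-pass (order 4, applied
  forward-backward) belongs to the HCP-style profile only.
- Constant nuisance regressors are dropped (redundant with the intercept);
  genuinely collinear regressors raise an error naming the columns.
- Zero-variance voxels are dropped with a warning before correlation; a
  zero-variance network mean series is an error naming the network.

## The sparse Bayesian regression

Weights carry independent Gaussian priors N(0, 1/alpha_i) with
Gamma(a0, b0) hyperpriors on each precision alpha_i and on the noise
precision; a0 = b0 = 1e-10 by default (essentially non-informative).
Inference is mean-field variational Bayes with conjugate coordinate
updates; features and target are z-scored internally and results returned
on the original scale. The evidence lower bound (free energy) is computed
every sweep, is non-decreasing (asserted by the test suite), and iteration
stops when its relative change falls below 1e-8 (at most 5000 sweeps). The
fit is deterministic; no restarts are used.

A feature is pruned when its posterior mean precision exceeds
`prune_precision` (default 1e4, bounding the standardized posterior weight
SD by 1e-2). With these monotone VB updates, the precision of an irrelevant
feature grows roughly linearly at rate E[beta]·x_i'x_i per sweep, so a much
larger threshold would never be reached before the free-energy tolerance
stops iteration; 1e4 matches the convention of widely used ARD
implementations and cleanly separates planted weights (standardized
precisions of order 1-100) from noise. Raising the hyperprior shape
`alpha_shape` strengthens the sparsity pressure; support size is monotone
non-increasing across order-of-magnitude increases (adjacent near-identical
weak priors can differ by a few features because VB converges to local
optima).

In the p > n regime ARD retains a tail of small noise-fitting weights
alongside the planted ones (as other standard ARD implementations do on the
same data); the planted support is recovered at about 95% at the default
study size n = 100 while held-out R^2 varies substantially across
ground-truth draws. The number of selected connections is whatever the data
support — it is never forced to a target count.

**Contribution ratios.** For selected connection i, the contribution is the
training-cohort mean of w_i·x_i divided by the sum of those means over the
support, times 100. Percentages are signed and sum to 100 up to rounding;
when the summed mean weighted FC is near zero, individual percentages can
exceed 100 in magnitude.

**LOOCV.** Each subject is predicted by a model refitted without it;
R^2 = 1 - SSE/SST over held-out predictions and may be negative.

## Statistics

- **Partial correlation**: residualize both variables on the confounds plus
  intercept (Spearman: rank-transform everything first). A variable fully
  explained by the confounds has partial correlation 0.
- **Permutation p-values** are two-sided and add-one,
  p = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_perm), shuffling only the
  predicted score so confounds stay attached to their subjects. When n! <=
  n_perm the null is enumerated exhaustively (p = count/n!, identity
  included). The sampled branch is vectorized through the projection
  identity rho(a_perm) = a_perm·(M b) / (||M a_perm|| ||M b||) with M the
  residual-maker of the confounds.
- **Hedges g** = J·(m1-m2)/s_pooled, J = 1 - 3/(4(n1+n2)-9); 95% CI via the
  large-sample variance (n1+n2)/(n1·n2) + g^2/(2(n1+n2-2)).
- **Group t-tests** are pooled-variance (Student), matching the df
  convention of equal-variance contrasts; Bonferroni adjustment is
  min(1, p·m).
- **Two-way mixed ANOVA** (diagnosis between-, connection
  within-participant) uses classical sums of squares with group-size
  weights — exact for the balanced-by-design synthetic layout; for
  unbalanced layouts the permutation null provides the calibration. Main
  effect: diagnosis labels are permuted across subjects with rows intact
  (vectorized over permutations via subject means; exhaustive for <= 8
  subjects when feasible). Interaction: rows are permuted and connection
  labels additionally shuffled independently within each subject (a
  `global` scheme shuffling one shared connection relabelling is available
  behind a flag). Post-hoc pairs permute labels within each diagnosis pair.
- **Kruskal-Wallis** per connection is tie-corrected; all-tied columns
  report H = 0, p = 1 with a warning. FDR control is Benjamini-Hochberg at
  Q = 0.05.
- **Distribution alignment** before pooling sites: each control group's FC
  is mapped per connection onto the reference (training) cohort's mean/SD
  by the linear transform derived from the controls; the same map is
  applied to that site's patients. D-score conservation (row sums equal
  predicted-WMA deviation) holds exactly under any such per-connection
  affine map.
- **ICC** is one-way random effects, (MS_b - MS_w)/(MS_b + (k-1)·MS_w)
  with k sessions; negative values are clamped to 0.

## The synthetic-data generator

The generator defines the study conditions; everything downstream is tested
against its planted truth.

- **FC -> WMA relation**: 16 of 171 connections carry nonzero weight;
  magnitudes are uniform on [0.75, 1.5] with a roughly 3:13
  positive:negative sign split. Population-mean FC is ~0.5 for
  within-network and ~0.2 for between-network features (with feature-level
  heterogeneity), subject-level feature SD 0.1, WMA residual SD 0.2, and
  the control population mean WMA anchored at 2.5 d' units. These defaults
  make every planted connection individually detectable at the default
  study size (per-connection t about 3.8 at n = 100) and put the planted
  explainable variance at about 0.84 — the regime of a high-precision
  behavioural target estimated from ~1500 trials per subject.
- **Diagnosis effects**: for each diagnosis a per-connection FC mean shift
  is spread over the true support proportionally to the weights so that
  the induced shift of true WMA equals g control-SDs exactly; defaults
  g = -0.68 (SCZ), -0.29 (MDD), -0.16 (OCD), 0.09 (ASD) at case/control
  sizes 58/60, 77/63, 46/47, 69/71, with each patient group site-matched
  to its own controls. Control groups share one population FC mean (no
  site effects by default).
- **Confounds** are generated from the subject's standardized true WMA
  with couplings 0.46 (fluid intelligence), 0.61 (composite cognition),
  -0.36 (age), -0.24 (head motion) — magnitudes typical of
  cognition/motion/age couplings in resting-state cohort studies. Measured
  scores are noisy linear transforms of true WMA.
- **Time series**: per network a unit-variance latent factor; voxels add
  iid noise with variance (1-w)/w so the population within-network FC is
  exactly w; factor correlations are inflated to undo the attenuation of
  voxel-mean courses, so empirical FC converges to the target as frames
  grow. Targets implying an indefinite network covariance are repaired by
  eigenvalue clipping (with renormalization and a warning) up to a
  tolerance, beyond which an error names the offending eigenvalue. Motion
  is a small random walk; injected spikes produce FD exceedances exactly at
  the requested frames plus a transient signal artifact, so scrubbing is
  exercised end-to-end.
- **Learning curves**: y_x = a - b/x plus Gaussian session noise;
  optionally realized at trial level as binomial hit/false-alarm counts
  (targets are a quarter of trials), clipping d' to the range attainable
  under the 1/(2N) correction with a warning.

**What the generator does not emulate**: hemodynamics, spatial structure,
scanner drift or site effects, non-Gaussian score distributions, floor and
ceiling effects, and medication or symptom structure. Passing tests
therefore validate the statistical machinery and its implementation on the
assumed generative family, not claims about real clinical data. Under these
clean conditions the test-retest ICC of the FC features (~0.5-0.6 at 150
frames in the acceptance report) is higher than is typical of short
real-world scans.

## Numerical and degenerate-input conventions

- d' extreme rates are clipped to [1/(2N), 1 - 1/(2N)].
- Moving-average windows shrink symmetrically at series edges (linear
  trends are preserved everywhere).
- The inverse-curve fit is the closed-form regression of y on 1/x —
  deterministic, no iterative optimizer; degenerate (constant) session
  indices are an error.
- Constant target y yields an empty support with intercept mean(y);
  zero-variance features are dropped with a warning.
- Alignment requires nonzero control SD at every connection (error names
  the connection); Z-scores require nonzero control SD of weighted FC.
- Correlation-scale quantities are reported to their natural [-1, 1] range;
  permutation p-values are never 0 by construction.

## Known limitations

- Per-seed recovery of the full severity ordering across four diagnoses is
  limited by the sampling noise of Hedges g at the default group sizes
  (SD ~0.2 versus a 0.13 gap between the two closest planted effects), so
  ordering is reliable in the mean across cohorts but not per cohort.
- ARD in the p > n regime keeps small spurious weights; support is to be
  read as "planted support plus a noise tail", and held-out R^2 varies
  widely across ground-truth draws.
- The two-way ANOVA's classical sums of squares are exact only for layouts
  balanced over the within-participant factor (always true here); strongly
  unbalanced between-participant designs rely on the permutation
  calibration.
- The comparison of two dependent correlations is a subject-level
  bootstrap — a declared convention, as is the within-subject
  connection-shuffle for the interaction null (the `global` alternative is
  exposed behind a flag).
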