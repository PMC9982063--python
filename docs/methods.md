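# Methods

## The model

`ectnct` analyzes how structural brain network organization shapes the
response to electroconvulsive therapy (ECT). The dynamical substrate is the
noise-free, discrete-time, linear time-invariant network model standard in
network control theory:

    x(t+1) = A x(t) + B u(t)

`x(t)` is the vector of regional activities, `A` the structural adjacency
matrix normalized to Schur stability, and `B u(t)` a control input — here,
the electric charge applied during ECT. The adjacency (binary, from
streamline counts; undirected, zero diagonal) is normalized as

    A = W / (c + lambda_max(W)),   c = 1,

which maps the top eigenvalue to `lambda_max/(1+lambda_max) < 1` so the
free dynamics decay. The unit scaling constant is the conventional choice
in the brain-controllability literature; it is exposed as a parameter.

Two regional controllability metrics are computed with input matrix
`B = e_i` (one input region at a time):

* **Average controllability** `ac[i] = trace(W_i)`, the trace of the
  infinite-horizon controllability Gramian
  `W_i = sum_tau A^tau e_i e_i' (A')^tau`. It equals the cumulative output
  power `sum_t ||x(t)||^2` after the impulse `x(0) = e_i` — the identity the
  dynamics module verifies by simulation, and the mechanical core of the
  claim that average controllability tracks seizure EEG power. Computed by
  solving the discrete Lyapunov equation; for symmetric `A` all nodes come
  from one solve `W = A W A' + I` whose diagonal holds every `trace(W_i)`
  (rows and columns of `A^tau` coincide). The solver uses the bilinear
  transform (`O(N^3)`), avoiding the Kronecker direct method whose memory is
  quartic in `N`; agreement with a horizon-10^4 brute-force sum is 1e-8
  relative or better for spectral radius <= 0.95.
* **Modal controllability** `mc[i] = sum_j (1 - lambda_j^2) v_ij^2` over the
  eigenpairs of `A` — the leverage of region *i* on fast-decaying modes.
  Asymmetric matrices are refused rather than evaluated in a non-orthonormal
  eigenbasis. The exchange-of-summation identity
  `sum_i mc[i] = N - sum_j lambda_j^2` is exact and used as an oracle.

Whole-brain values AC̄ and MC̄ are arithmetic means over regions. Note that
for a binary network this makes MC̄ an exact function of edge count and top
eigenvalue, `MC̄ = 1 - 2m/(N (1+lambda_max)^2)`: across networks that differ
mainly in density, MC̄ *co-moves* with density and with stimulus power. The
opposed AC̄-up/MC̄-down pattern against cumulative power appears across
systems that differ in bulk spectral spread at a fixed top eigenvalue, which
is the family the association check uses.

## Postictal Suppression Index

The PSI quantifies post-seizure EEG flattening:

    PSI = 1 - P_termination / P_seizure

with each power the mean over three 1.28 s windows (256 samples at the
clinical 200 Hz rate). 3.84 s around the tonic-clonic seizure endpoint are
excluded; the exclusion is read as symmetric (1.92 s each side) and the
seizure windows are taken immediately before the gap, the termination
windows immediately after. Both placements are configurable: the device
convention is proprietary, and the contiguous-window reading is the most
conservative artifact-avoiding interpretation. Window power is the mean
squared demeaned amplitude; no spectral filtering is applied because none is
specified by the device convention. Computation is single-channel.

## Synthetic study

Patient data are access-restricted, so the package ships a generator whose
defaults are the reference study conditions: 50 subjects, 100-node binary
connectomes, PSI missing for 5 subjects, a 29/50 female split, age 45.1
(SD 10.8) years, and HDRS response defined as post minus pre (improvement
negative).

Connectomes are connected Watts-Strogatz small-world graphs with an exact
density-derived edge count (density uniform on 0.10-0.35 across subjects)
plus a hub-concentration step: a per-subject fraction (uniform on 0-0.5) of
hub-free edges is moved onto 5 hub regions. The hub step matters: it varies
the top eigenvalue — hence MC̄ — at fixed edge count, so whole-brain
controllability is not a deterministic function of the edge-count covariate
and the planted effects remain identifiable after covariate adjustment.
Inter-individual variation in hub organization is also a genuine feature of
structural brain networks.

The planted causal chain is

    PSI      = 0.70 - 0.06 z(MC̄) + e1,    e1 ~ N(0, 0.15^2)
    response = -12 - 18 PSI + 2 z(MC̄) + 0.08 (age - 45.1) + 1.0 sex
               - 0.15 (hdrs_pre - 25) + e2,   e2 ~ N(0, 7^2)

PSI is clipped to [0, 1). These effect sizes put the partial eta-squared of
the main contrasts in the 0.05-0.15 band at n = 50. Only the MC̄ chain is
planted; in this synthetic world AC̄ inherits MC̄'s direction through their
positive correlation (both rise with density), so the AC̄ contrasts are
exercised structurally but their synthetic signs are not the hypothesized
real-data ones. EEG traces are three sinusoids (integer cycles per analysis
window, so window power is phase-exact) plus 1.5 µV Gaussian noise, with the
termination phase scaled by `sqrt(1 - PSI)`; the noise level is calibrated
so the windowed PSI recovers the target within 0.01 across 1000 draws.
What the generator does *not* emulate: real tractography weight
distributions, multi-channel EEG, non-stationary ictal morphology, item-level
HDRS structure. Passing tests therefore certify the machinery and its
calibration under the planted model, not clinical effect sizes.

`hdrs_post` is kept continuous (`hdrs_pre + response`) rather than rounded
to integer scale points, preserving the exact `response = post - pre`
invariant.

## Inference

ANCOVAs are OLS fits of the dependent variable on one predictor plus
covariates (age, sex, baseline HDRS, and edge count, the latter guarding
against effects driven by raw graph size). Reported per contrast: the
predictor's F (= t^2, df1 = 1, df2 = N - 2 - #covariates), the one-sided p
in the a-priori direction, and partial eta-squared
`F/(F + df2)`. The five directions are fixed centrally in one map; analyses
involving PSI use exactly the PSI-available subset.

Mediation (X -> PSI -> response, covariates in both sub-models) reports OLS
paths a, b, c, c' with `c = c' + ab` exact to 1e-10 (inputs are mean-centered
before fitting to keep the identity tight at raw scales). The ab confidence
interval is a bias-corrected (BC, no acceleration) nonparametric bootstrap
over row resamples. Significance of ab uses a permutation test by joint
significance: the mediator column is permuted to build the null of the
a-coefficient, its covariate-residualized version (Freedman-Lane style) to
build the null of the b-coefficient, and `p_ab = max(p_a, p_b)`. Permuting
the raw mediator inside the product ab directly was evaluated and rejected:
with one large path and one null path it is badly anticonservative (the
observed `a*b_hat` is scaled by the large `a` while permuted products are
doubly null), whereas joint significance stays calibrated under either
partial null — verified by a 100-replicate planted-null simulation. The
scheme is recorded in the result metadata.

## ML benchmark

The multivariate comparison runs 35 pipelines — {identity, PCA keeping 95%
variance, PCA with 20 components, univariate selection top 5%, top 10%} x
{OLS, ridge (alpha 1), linear SVR (C = 1, 10), RBF SVR (C = 1, 10), random
forest (100 trees)} — per feature modality (vectorized upper triangles of
the per-subject matrices), under leave-one-out CV with all preprocessing
(including standardization) refit inside each training fold; specs with
tunable settings run an inner leave-one-out grid search on the training
fold (the 35 default specs have fixed hyperparameters). Performance is
percent variance explained by Spearman rank correlation between true and
out-of-fold predicted response, with negative correlations clamped to 0%
(squaring alone would reward anti-prediction; the clamping convention is
declared, not inherited). Univariate selection scores features with
f_regression, monotone in |Pearson r|. The comparators are plain LOO linear
regressions on AC̄ or MC̄ alone and on {age, sex, baseline HDRS}. No
significance testing of pipeline differences is performed; the comparison
is descriptive.

## Problem sizes and numerical choices

* Lyapunov solves: bilinear method everywhere; equivalence to the truncated
  (10^4-step) Gramian sum is an acceptance property at 1e-8 relative.
* Simulation horizon default 10^4 steps — adequate to 1e-8 for spectral
  radius <= 0.95.
* Calibration suites use scaled-down replicate counts chosen once: 100
  replicates at n = 200 for null calibration and sign recovery; 20 seeds at
  n = 40, P = 100 with two representative pipelines for the pure-noise CV
  check; the benchmark's integrity checks run at n = 5-16 where the
  properties (leakage, counting) are size-independent.
* The acceptance script's benchmark section uses 40-node connectomes so the
  full 35-pipeline grid stays light; all other sections run at the reference
  conditions.
* Degenerate inputs are refused loudly: asymmetric matrices (unless an
  explicit symmetrize flag is set), unstable systems, constant predictors or
  mediators, perfectly collinear designs, traces too short for the window
  layout.

## Known limitations

* The linear noise-free model is the standard simplification; no nonlinear
  or stochastic dynamics.
* Whole-brain means only; no regional (control-node) analysis.
* PSI window placement and demeaning are explicit stand-ins for a
  proprietary device convention.
* The synthetic AC̄-PSI association is not independently plantable while AC̄
  and MC̄ are both density-driven; only the MC̄ chain carries designed
  effects.
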