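# Methods

## Problem

Given a `T x p` matrix of region-of-interest (ROI) time series sampled at a
known repetition time (TR), the package estimates a *dynamic functional
connectivity* (dFC) sequence: one symmetric, sparse, weighted network per
time point, together with a statistical decision for every node pair as to
whether its connectivity series is genuinely dynamic or merely noisy.

## The KELLER model

At each time point `t` the joint activity is modelled as a pairwise Markov
random field whose edge parameters `theta_mn(t)` encode conditional
dependence between regions.  Estimating the full joint is intractable
(partition function), so the graph is recovered by *neighbourhood
selection*: each region's dichotomised activity `d_n in {-1, +1}` is
regressed on the activity of the remaining regions through the logistic
conditional

    P(d_n | y_rest) = 1 / (1 + exp(-2 d_n <theta, y_rest>)),

and the per-region coefficient vectors are assembled into a network.
Temporal smoothness comes from Gaussian kernel weights

    w_t(t*) ∝ exp(-((t* - t) * TR / h)^2),

which concentrate each anchor fit on nearby samples; sparsity comes from an
l1 penalty `delta * ||theta||_1`.  The kernel-weighted penalised negative
log-likelihood is minimised independently for every (region, anchor) pair —
`p * T` convex problems per `(h, delta)` grid point.

Design choices that the source formulation leaves open, and how they were
fixed:

- **Predictors are the centred normalised values `y - 1/2`.**  The
  intercept-free conditional with predictors in `[0, 1]` is monotone
  increasing in every predictor, so a positive coupling could never express
  "partner low -> target low"; support recovery provably fails (we verified
  wrong signs and support on static instances).  Centring restores the
  symmetry of the +/- activity levels.  `predictor_mode='raw'` keeps the
  uncentred form and `'binary'` gives the fully dichotomised (Ising-style)
  regression for sensitivity checks.
- **Penalty form, not ball constraint, is the canonical path.**  The two are
  equivalent per fit (`delta` maps one-to-one onto a ball radius `C_delta`),
  but with one *fixed* radius across all anchors the projection spreads the
  coefficient budget instead of thresholding (almost no exact zeros on
  noise) and clips strong couplings, which suppresses exactly the temporal
  variance the dynamics test measures.  The proximal-gradient
  (soft-threshold) solver with Armijo-style backtracking keeps the penalised
  objective non-increasing; `fit_neighborhood` exposes the ball-constrained
  single fit via projected gradient with an exact sort-based l1-ball
  projection.
- **Kernel scaling.**  The kernel is `k(u / h)` with `k(u) = exp(-u^2)`, so
  `h` is a bandwidth in seconds directly comparable to sliding-window
  lengths; the default grid is 10..150 s in 10 s steps.  Distances are
  `index difference x TR`, making `h` portable across sampling rates.
- **Symmetrisation.**  Edge `(m, n)` combines the two directed estimates by
  their mean.  The estimator defaults to the OR rule (edge kept if either
  direction is nonzero): when one region drives another, the reverse
  regression is systematically weaker and the AND rule over-prunes
  (measured: mean benchmark F1 0.73 vs 0.69, OR better on every calibration
  seed).  `assemble_dfc` defaults to the conservative AND rule.

## Model selection

For every grid pair `(h, delta)` the selection score is a per-sample-scale
AIC: twice the *leave-self-out* kernel-weighted negative log-likelihood
(each anchor's own observation removed from its kernel average — in-sample
likelihood otherwise rewards arbitrarily small bandwidths) plus `2 k / ESS`
degrees-of-freedom per anchor, where `k` counts nonzero coefficients and
`ESS = 1 / sum w^2` is the kernel's effective sample size.  The chosen pair
is the *sparsest within one standard error* of the minimising score (SE
computed over independent kernel-width blocks).  Without the one-SE rule,
AIC-class scores keep spurious coefficients on pure-noise input, because the
sample correlations of a finite draw are "real" to any likelihood.  The
printed-form AIC with raw degrees-of-freedom count `2N`,
`N = sum_t Nz(theta_t) / 2`, is implemented as `aic()` (it equals
`2 p log 2` exactly for the all-zero estimate) but is not used for search:
its penalty grows with `T` while its likelihood term does not, so it always
selects the emptiest model.

## Sliding-window baselines

SWCGL computes (optionally tapered) Pearson correlations in maximally
overlapping windows (step one sample, length in seconds rounded by TR),
converts each to a covariance via `cov_ij = cor_ij * sd_i * sd_j`, and
sparsifies with the graphical lasso at a per-window penalty selected by
AIC.  Numerical choices:

- Taper: one-sided exponential, most recent sample weighted highest,
  half-life `L/4` by default; weighted means/SDs/correlations all use the
  same weights.  A symmetric (centre-peaked) taper and several half-lives
  were evaluated and performed indistinguishably.
- Window alignment: each network is assigned to the window's centre sample
  (left-of-centre for even `L`).
- Graphical-lasso AIC uses the Gaussian profile likelihood at the estimated
  precision with an *effective* sample size: the taper ESS multiplied by
  `(1 - r) / (1 + r)` with `r` the series' mean lag-1 autocorrelation.  The
  iid-likelihood without this correction overclaims information from
  autocorrelated windows and selects networks roughly twice as dense as the
  generating truth.
- Network weights are partial correlations from the sparsified precision
  matrix.

## Benchmark simulator

The generator emulates a resting-state-like multivariate series with known
time-varying structure: per state (default 3 states x 100 samples at
TR = 1 s, so change points at t = 100 and 200) an Erdos-Renyi or
Barabasi-Albert topology on 5 nodes is drawn with sparsity (fraction of
absent pairs) in [0.4, 0.7]; each active edge's strength ramps linearly
within [0.1, 0.75] ("emerging" up, "disappearing" down) or holds its value —
each edge modulates with probability 0.5 per state; edges leaving the
support ramp down to the floor and newly entering edges ramp up from it, so
trajectories are continuous up to the 0.1 activation floor.  The series is
driven by a first-order VAR, `y(t) = A(t) y(t-1) + eps`, with unit-variance
Gaussian innovations and a 100-sample burn-in.

Two structural choices matter and are deliberate:

- **Directed coupling realisation.**  A symmetric zero-diagonal VAR yields
  *zero* contemporaneous correlation for an isolated edge (the stationary
  covariance `sum_k A^{2k}` of a 2x2 antidiagonal block is diagonal), and
  symmetric matrices with several strengths near 0.75 are unstable, forcing
  a rescale that crushes the couplings far below the nominal range.  Each
  undirected edge is therefore realised as one directed coefficient (upper
  triangle); the triangular-plus-diagonal matrix is stable for *any*
  strengths, which keeps them exactly inside [0.1, 0.75].
- **Self-coupling 0.7.**  BOLD-like series are strongly positively
  autocorrelated; a positive diagonal also carries the lagged coupling into
  contemporaneous correlation, which is what correlation-based estimators
  measure.  Lag-1 autocorrelations of ~0.5-0.8 are typical of the data this
  emulates.

What the generator does *not* emulate: haemodynamic convolution, measurement
and physiological noise spectra, spatial correlation of noise, and
inter-subject variability beyond innovation redraws.  Passing benchmarks
therefore demonstrate method behaviour under an idealised piecewise-ramped
VAR, not performance on real recordings.

Benchmark "dynamic" labels mirror the data-analysis test: the SD over time
of each pair's true coupling trajectory is compared with the 95th percentile
of SDs of sliding-window (50-sample, unit-step) ordinary-least-squares
VAR(1) coefficient trajectories re-estimated from 500 amplitude-adjusted
phase-randomised surrogates.

## Surrogate testing

The test measure per pair is the sample SD (denominator `T - 1`) of its dFC
series.  Surrogates are amplitude-adjusted phase-randomised: Gaussianise
each column by rank-remapping onto sorted Gaussian deviates, rotate all
columns' spectra by one *common* random phase vector (preserving
cross-spectra, hence static correlation; the Nyquist bin is kept real for
even `T`), and rank-remap back onto the original amplitudes, so every
surrogate column is a permutation of the original.  Each surrogate is
re-estimated with the estimator's *selected settings frozen* (the chosen
`(h, delta)` for KELLER; the per-window penalties for the window methods).
For the window methods the SD statistic runs over the windowed correlation
series — the graphical lasso is the structure-recovery step, not the value
series the test measures (`series='precision'` switches to the sparsified
partial correlations).  Empirical p-values use the add-one rule
`p = (1 + #{null >= obs}) / (1 + n_null)`; the benchmark power computation
flags a pair when its observed SD exceeds the empirical 95th percentile of
its own null.  Bonferroni correction and the across-subject averaged test
(observed and per-index surrogate statistics averaged across subjects before
the empirical test) are available for cohort analyses; per-edge nulls are
the default, with pooling across edges as an option.

## Scoring

Edge recovery is scored per time point against the true support (nonzero
pattern only).  Two counting conventions are provided: the pair-based
precision/recall/F1 over `i < j` pairs excluding the diagonal
(`precision_recall_f1`), and the matrix-cell convention
(`matrix_cell_scores`) that counts all `p^2` adjacency cells with the
diagonal marked connected on both sides — the convention under which a
`W`-window benchmark yields confusion totals of `W x p^2` and which the
benchmark study reports.  Window-method scores align to window centres.
Detection power is the percentage of benchmark-dynamic pairs flagged.
Method comparison uses a two-sided permutation test on score means.

## Problem sizes and reproducibility

The benchmark study runs 10 seeded replicates with a coarse KELLER grid
(`h in {20, 60, 100, 140}` s, `delta in {0.02, 0.05, 0.1}`), 500 labelling
surrogates and 100 testing surrogates per replicate; the full default grids
remain the estimator defaults.  All randomness flows from one seed through
spawned child streams (topology, ramps, innovations, surrogates), and every
fit is deterministic given its inputs; batched anchor fits are numerically
identical to one-at-a-time fits.

## Known limitations

- The oracle information ceiling of the benchmark is below perfect recovery:
  thresholding the *true* per-timepoint stationary (partial) correlation of
  the generating VAR at the best fixed threshold yields cell-F1 of only
  0.84-0.95 across seeds, because edges near the activation floor are
  intrinsically invisible to contemporaneous-dependence methods.  Finite
  samples and response dichotomisation cost substantially more; measured
  cell-F1 means are near 0.70 for KELLER and 0.67-0.68 for the window
  baselines.
- Detection power of the SD test is modest here for all methods: the
  strongly autocorrelated series gives phase-randomised surrogates large
  spurious windowed-correlation variability, so only the strongest
  modulations exceed their null.  This matches published reports that
  single-session sliding-window dynamics detection is hard, and the power
  ordering between methods is not stable across replicates.
- The projected/proximal solvers are first-order; with very small `delta`
  and narrow kernels convergence to `1e-6` relative tolerance dominates run
  time.
- Real-data concerns (preprocessing, atlas extraction, haemodynamics,
  motion) are entirely out of scope; the reader for delimited text expects
  an already-extracted ROI-by-time matrix.
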