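# Methods

This note documents the statistical procedure, the numerical choices behind
it, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Models

For subject i with observed time `T_i = min(D_i, C_i)`, event indicator
`delta_i`, binary exposure `X_i`, covariates `Z_i` and mediator vector
`M_i` (p entries, p >> n):

* Outcome: Cox proportional hazards,
  `lambda_i(t) = lambda_0(t) exp(gamma X_i + theta' Z_i + beta' M_i)`,
  estimated through the Breslow log partial likelihood
  `l_n(Q) = sum_i delta_i {P_i'Q - log sum_{l: T_l >= T_i} exp(P_l'Q)}`.
* Mediators: `M_ki = c_k + alpha_k X_i + vartheta' Z_i + e_ki` with
  homoscedastic Gaussian errors, fit by OLS.

Causal interpretation of the decomposition requires the usual
no-unmeasured-confounding assumptions (exposure–outcome, mediator–outcome,
exposure–mediator, and no exposure-induced mediator–outcome confounders).
These are documented, untestable assumptions; nothing in the package checks
them.

### Effect decomposition

The counterfactual log hazard of `T(x, M_1(x*), ..., M_p(x*))` given Z is
approximated, using the normal mediator model and a log-normality argument,
by

    log lambda_0(t) + theta'Z + 1/2 sigma^2_{W beta}
      + sum_k beta_k (c_k + vartheta'Z) + gamma x + (sum_k alpha_k beta_k) x*,

with `sigma^2_{W beta} = sum_k beta_k^2 sigma^2_{M_k}`. Differencing in `x`
gives the natural direct effect `(x* - x) gamma`; differencing in the
mediator argument gives the total natural indirect effect
`(x* - x) sum_k alpha_k beta_k` — the baseline and variance-inflation terms
cancel, which the implementation reproduces exactly and tests bit-wise.
The approximation treats the hazard ratio as collapsible over the Gaussian
mediator distribution (a rare-event-style approximation); `sigma2_W_beta`
is reported as a diagnostic of how much marginalization inflation it
absorbs.

## The pipeline and its tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `screen_multiplier` | 2 (3 for exposure-path applications) | `d = floor(mult * n / ln n)` retained by SIS |
| `penalty.kind` | `mcp` | `mcp` or `lasso` |
| `penalty.a` | 3 | MCP shape; smaller = more aggressive unbiasing, must exceed 1 |
| `penalty.lambda_selection` | `ebic` | `ebic`, `bic`, or `cross_validation` |
| `penalty.ebic_gamma` | 0.5 | weight of the `2 gamma log |S1| * df` extended-BIC term |
| `penalty.n_lambda` | 100 | log-spaced grid from `lambda_max` down to `ratio * lambda_max` |
| `penalty.lambda_min_ratio` | auto | 0.01 when `n >` #penalized columns, else 0.05 |
| `penalty.tol` | 1e-7 | max absolute coefficient change at convergence |
| `penalty.dfmax` | `min(|S1|, max(50, n/20))` | path truncation guardrail (glmnet-style) |
| `alpha_level` | 0.05 | significance level on Bonferroni-adjusted p-values |
| `contrast` | (0, 1) | exposure values for the effect decomposition |

Screening ranks by standardized marginal coefficients (`|beta_hat|/SE` from
the marginal Cox fit, or `|alpha_hat|/SE` from OLS) rather than raw
correlations: censored outcomes have no well-defined Pearson correlation,
and standardization makes the ranking scale-invariant. Marginal fits adjust
for X and Z because the final model does; unadjusted ranking would favor
mediators merely correlated with the exposure. Ties are broken by lower
column index (deterministic).

### Why extended BIC

The selection stage sees `d = floor(2n/ln n)` screened candidates. The
largest marginal chi-square statistic among d null candidates grows like
`2 ln d`, which exceeds the ordinary BIC increment `ln(n_events)` at these
sample sizes — e.g. at n = 300, `2 ln 105 ≈ 9.3 > ln(195) ≈ 5.3` — so plain
BIC systematically admits the strongest few noise mediators (measured: mean
|S2| ≈ 23 at n = 300 with 35% censoring, of which ~19 are noise). That
inflates the Bonferroni factor `|S2|` and costs indirect-effect test power
without improving discovery. The extended BIC (penalty
`[ln(n_events) + 2 gamma ln d] * df`, gamma = 0.5) restores resistance to
the max-of-noise effect and is the standard pairing with folded-concave
penalties when the candidate set grows with n. Plain BIC and 10-fold
event-stratified cross-validation remain available.

### Post-selection inference

The Sobel and joint tests use `beta_hat_k` and `SE(beta_hat_k)` from an
unpenalized refit on `(X, Z, S2)`, not the penalized estimates: penalized
SEs are ill-defined and MCP estimates, though nearly unbiased when large,
are shrunk near the threshold. The refit-based estimates reproduce the
near-unbiasedness and ~95% CI coverage of the indirect-effect products seen
in the acceptance experiments. The Bonferroni multiplicity factor is
exactly `|S2|`. The joint-significance rule is MaxP: reject when both the
exposure->mediator t-test and the mediator->outcome Wald test fall below
the level; its p-value is the maximum of the two path p-values and it
provides no effect estimate. No formal correction is made for the fact
that S2 itself is data-chosen (standard practice for this procedure, and
the acceptance experiments quantify the resulting operating
characteristics); bootstrap CIs are out of scope.

CIs: direct effect from the Cox SE of `gamma_hat`; per-mediator indirect
effects normal on the log-HR scale with the Sobel SE, endpoints
exponentiated (log-symmetric); the total-effect variance sums the direct
and indirect contributions treating them as independent — cross-covariances
between Cox and mediator-model estimates are ignored, a documented
limitation. A marginal total effect (Cox on X, Z without mediators) is also
reported, clearly labeled, for comparison with the decomposition total.

## Numerical methods

**Cox fitting.** Newton–Raphson on the Breslow partial likelihood with step
halving; convergence when the relative change in log partial likelihood is
below 1e-9 (max 100 iterations); SEs from the inverse observed information.
Exactly collinear designs raise a named singular-information error;
monotone likelihood (the separation analogue) is flagged as non-converged,
as are "converged" solutions with |coef| > 15, which at this scale can only
be flat-likelihood artifacts. Ties are handled by Breslow's approximation
(the risk-set definition above); the Efron correction is available behind
`ties="efron"`, delegated to lifelines' reference implementation. Event
times in the simulation design are continuous, so the tie rule is benign
there. Kernels are numba-compiled; singular systems are detected via a
pivoted Gauss–Jordan solve that reports a flag instead of raising, which
keeps the hot loops exception-free.

**Penalized solver.** The objective is `(1/n) l_n(beta) - sum_k P_lambda
(beta_k)` with mediator columns standardized internally (coefficients are
reported on the original scale; centering is absorbed by the partial
likelihood's location invariance). Each lambda is solved by iteratively
reweighted least squares: a diagonal-Hessian quadratic expansion of the
partial likelihood (working weights `w_i` and responses from the subject-
level score), coordinate descent with the exact one-dimensional MCP
minimizer, then a line search on the true penalized objective along the
refresh direction. The line search matters: with many subjects sharing
risk sets the diagonal weights overestimate curvature and the plain IRLS
iteration converges linearly with rates near 1; allowing overrelaxed steps
(doubling up to 64x) and falling back to halving keeps the objective
monotone while restoring useful progress. Once the active set is stable, an
exact Newton polish on the active columns (full observed information,
sign-constrained steps, penalty curvature `-1/a` inside the MCP region)
gives quadratic local convergence; a subsequent full coordinate sweep
verifies the KKT conditions for the zeroed coordinates. The MCP coordinate
update handles the low-curvature case `v <= 1/a` (where the 1-D problem is
nonconvex and the firm-threshold formula is invalid) by comparing the
candidate minimizers explicitly.

`lambda_max` is the smallest lambda zeroing all penalized coordinates at
the (X, Z)-only fit, `max_j |x_j' g| / n`. Warm starts run down the grid;
the path stops early at `dfmax` active mediators — far above anything the
information criteria select, so this is a compute guardrail, not a model
restriction. Solutions at individual lambdas that fail to converge within
the refresh budget are flagged and the path continues.

**Censoring calibration.** Given c0, censoring is `C ~ U(0, c0)`, so
`P(censored | D) = min(D / c0, 1)`. The calibrator averages this closed
form over >= 50 simulated event-time replicates and solves for c0 by
Brent's method — a Rao–Blackwellized version of simulate-and-bisect that is
deterministic given its seed (a dedicated stream, offset from the data
streams). Mediators beyond the last nonzero hazard coefficient are not
generated during calibration since they cannot affect event times.

## Synthetic data: what it emulates and what it does not

The generator draws `X ~ B(1, 0.6)`, `Z_1 ~ B(1, 0.3)` (gender-like),
`Z_2 ~ U(0, 1)` (age-like), per-replicate mediator intercepts
`c_k ~ U(0, 1)`, Gaussian mediator errors with unit SD, and exponential
event times with rate `0.5 * exp(linear predictor)` (inverted exactly as
`-log U / rate`). Defaults place nonzero coefficients on the first eight
mediators — `alpha = (0.5, 0.45, 0.5, 0.4, 0.45, 0.45, 0, 0)`,
`beta = (0.55, 0.6, 0.65, 0.7, 0, 0, 0.5, 0.5)` — so exactly four mediators
(1–4) carry a nonzero product `alpha_k beta_k`, two (5–6) touch only the
exposure path and two (7–8) only the outcome path. Intercepts are redrawn
each replicate (the conservative reading of "chosen as a random number");
because `c_k` shifts a whole replicate's hazards, per-replicate censoring
fractions vary noticeably around the calibrated mean — that variation is
part of the design, not a calibration error. An optional dependence knob
builds `M~_k = M_k + sum_{l<k} rho^{k-l} M_l` (geometric-decay loadings;
the dependent-mediator construction leaves the loadings free, so a single
decay parameter is exposed), default off.

Not emulated: real methylation beta-value marginals (bounded, bimodal),
probe-level measurement error, batch effects, non-exponential baseline
hazards, or informative censoring. Passing tests therefore certify the
procedure under a correctly specified generative model with independent
uniform censoring; they do not certify robustness to those violations.

RNG discipline: every replicate draws from
`SeedSequence(entropy=seed, spawn_key=(replicate,))`, so replicates are
independent and individually reproducible; experiment scenarios derive
scenario seeds from the master seed; calibration uses its own offset
stream. End-to-end runs with a fixed config and seed are byte-identical.

## Experiment scale

The replicate-level experiments (and the acceptance script) use p = 2000
mediators and 100 replicates per scenario with the same eight-coefficient
nonzero head, sample sizes n in {300, 500, 1000} and censoring targets
{15%, 35%}. Full-scale reproduction (p = 10000, 500 replicates) is a
matter of passing different `--p`/`--replicates` flags to the `experiment`
command. Reported metrics: TPR (mean per-replicate fraction of the four
true mediators declared significant), FP (mean count of significant null
mediators), FDP (mean per-replicate V/R with 0/0 := 0; a pooled
`sum V / sum R` variant is reported alongside), and per-mediator estimation
summaries (mean estimate, empirical SE, mean Sobel SE, 95% CI coverage)
conditional on selection.

## Baseline comparators

Two reference analyses are provided for benchmarking. The *naive* approach
fits the marginal Cox model `(X, Z, M_k)` and the mediator model for every
one of the p candidates and Bonferroni-corrects over p; with thousands of
candidates the correction leaves it essentially powerless. The *one-step*
approach runs the MCP-penalized selection directly on all p mediators
without screening. Note that the one-step comparator inherits the lambda
rule: with the extended-BIC default it remains selection-consistent and can
match the screened pipeline's true-positive rate at desk scale (screening
then buys computation, roughly a 3x speedup, rather than accuracy), whereas
with plain BIC the unscreened path admits the strongest of p null
candidates and its TPR degrades sharply while the screened pipeline
degrades much less. Comparisons between the pipeline and the one-step
route are therefore statements about the combination of screening and
selection rule, not about screening alone.

## Known limitations

* Hazard-scale mediation requires the rare-event/log-normal approximation
  above; with common events and large `sigma^2_{W beta}` the decomposition
  is approximate by construction.
* No exposure–mediator interactions, time-varying covariates, stratified
  baselines, left truncation, frailty, multiple exposures, or iterative/
  conditional screening variants.
* Mediator missingness is rejected at ingest; imputation is upstream work.
* Total-effect CIs ignore cross-covariances between the outcome- and
  mediator-model estimates.
* The joint test's MaxP p-value is conservative under the full null (both
  paths zero); its family-wise error is correspondingly below nominal.
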