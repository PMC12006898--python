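# Methods

## Model

`trialbf` computes default Bayes factors for the two-sided
independent-groups t test from summary statistics alone. The null model
fixes the standardized effect size δ = (μ1 − μ2)/σ at zero; the
alternative gives δ a Cauchy(0, r) prior — the Jeffreys–Zellner–Siow (JZS)
setup, in which the Cauchy arises as a normal prior on δ whose relative
variance g is mixed over an inverse-gamma(1/2, r²/2). Conditioning on an
observed t statistic with ν = n1 + n2 − 2 degrees of freedom and
effective sample size N0 = n1·n2/(n1 + n2), the marginal likelihood ratio
reduces to a one-dimensional integral over g (see the README for the
formula). At r = 1 the mixing density is inverse-gamma(1/2, 1/2) and the
expression reduces to the classic unit-information JZS form; the
generalized scale is what makes the 0.707 default and the robustness
sweep expressible.

Assumptions inherited from the t test: independent random samples per
arm, normally distributed outcomes within arm, equal variances (hence the
pooled ν). The pipeline additionally assumes the published CI is
symmetric, Wald-type, and large-sample — see "CI back-conversion" below.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `prior_scale` (r) | 0.707 | Cauchy width on δ; presets wide = 1, ultrawide = √2 |
| `ci_level` | 0.80 | coverage of the published interval (a column, so mixed tables parse) |
| `quantile_rule` | normal | reference distribution for CI → SE back-conversion |
| `arm_rule` | replicate | how per-arm sizes derive from the printed total (below) |
| `allocation` | 2:1 | active:placebo weights, used only by the split rule |

Evidence labels follow the Jeffreys convention: BF10 > 3 substantial for
the effect, < 1/3 substantial for the null, otherwise anecdotal; the
thresholds are strict, so exactly 3 or 1/3 counts as anecdotal. Posterior
model probabilities assume equal prior odds, P10 = BF10/(BF10 + 1), and
are always computed from the unrounded Bayes factor: the published pair
(BF10 0.13, P10 11.11%) is only self-consistent via an unrounded 0.125,
not via the rounded 0.13 (which would give 11.50%).

## CI back-conversion and arm sizes

The standard error is recovered as `(upper − lower) / (2 q)` with q the
(1 + level)/2 quantile of a standard normal (default; the source
intervals come from a large-sample mixed model) or of a Student t with
n_total − 2 degrees of freedom (option). The t statistic is then
`difference / SE`, preserving sign. This back-conversion is exact when
the original interval was built as estimate ± q·SE with the same
quantile — which the synthetic-trials round-trip test verifies to 1e−9.

Forest tables print only a total n, so per-arm sizes must be
reconstructed. Two rules are provided:

- **split** — divide the total by the allocation weights (n1 rounded half
  up, n2 the remainder, total conserved). With the 2:1 default this
  reflects a trial pooling two active-dose arms against one placebo arm.
- **replicate** — use the printed total as the size of *each* arm
  (n1 = n2 = n_total, so ν = 2n − 2 and N0 = n/2).

The replicate rule is the analysis default. The choice was empirical:
across all eight rows of the packaged table, the Bayes factors implied by
the published posterior probabilities correspond to an effective sample
size of n_total/2 (implied N0/n ratios 0.46–0.51 row by row), which is
exactly the replicate convention and matches no split of the total. The
split rule (the design-natural choice) is retained as an option, and the
robustness module reports how conclusions vary with such settings.
Under the replicate rule the default run reproduces the published table
to within 0.02 on every BF10 and 0.8 percentage points on every P10.

Note the statistical consequence: relative to a genuine 2:1 split of the
total, the replicate rule roughly doubles N0 and ν, which strengthens
whatever direction the evidence points in. It is kept as the default
because the package's first job is to reproduce the published analysis;
for fresh re-analyses of other tables the split rule with the true
allocation is the better-grounded choice.

## Numerics

The g-integral is evaluated with adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, absolute tolerance 1e−10) after the change of
variables g = s·u/(1 − u) mapping (0, ∞) to (0, 1). The pivot s is set to
the integrand's mode, found by probing a log-spaced grid spanning both
characteristic scales r² (mixing density) and (1 + t²/ν)/N0 (likelihood);
this keeps the mass mid-interval whether r is 1e−4 or 1e4. The integrand
is evaluated in log space and stabilized by subtracting its maximum, so
very large |t| (tested at t = 80) never underflows. The quadrature's
reported error bound is surfaced on the result
(`quadrature_abs_err`); if the estimate exceeds tolerance a
`QuadratureError` is raised rather than returning a silent value.

An independent Monte-Carlo oracle (`mc_oracle_bf`) estimates BF10 as the
Cauchy-prior average of noncentral-t densities, nct(ν, δ√N0), over draws
δ ~ Cauchy(0, r), divided by the central-t density. It shares no code
with the quadrature path; the suite checks agreement within 3 MC standard
errors at 1e5 samples over a 180-point grid in (t, ν, N0, r).

Degenerate inputs are rejected with row-addressed messages: non-finite or
inverted CI bounds, estimates outside their interval, totals below 4,
splits leaving an arm under 2, non-positive prior scales.

## Robustness sweep

`robustness_curve` evaluates BF10 over a scale grid (default 200 points
on (0, 1.5], covering the ultrawide marker with margin) and at the three
named markers. A row is **stable** when all three marker BF10 values fall
on the same side of 1 — i.e. the favored hypothesis does not flip as the
prior widens; evidence *strength* is allowed to change, which is the
Bartlett–Lindley effect (BF10 → 0 as r → ∞) and is itself tested. As
r → 0 the alternative collapses onto the null and BF10 → 1. Stability
depends only on the markers, so it is invariant to grid resolution.

## Synthetic trials

`synthetic_trials` generates what the analysis layer consumes — a
(mean difference, CI, n) row — from a simple generative model: outcome
changes normal within arm, common SD σ, true between-arm difference δ.
The CI is built from the pooled-variance two-sample SE with the same
quantile rule the back-conversion uses, making the pipeline's recovered t
exactly the two-sample t of the raw draws (round-trip tested to 1e−9).
Per-replicate RNG substreams derive from (seed, rep index), so any single
replicate is reproducible in isolation.

Example scenarios use σ = 8 points of 52-week MDS-UPDRS-III change and
arm sizes 39/20 as an internal default of realistic magnitude for an
early-PD motor endpoint; it is a package convention, not a reported
quantity. What the generator does **not** emulate: the longitudinal
mixed-model adjustment behind real adjusted mean differences, covariate
imbalance, dropout, correlated subgroups carved from one trial, or
non-normal outcomes. Passing calibration tests therefore demonstrates
the summary-to-BF chain is self-consistent and behaves as theory predicts
(evidence of absence accumulates with n under a true null; substantial-H1
rates grow with |δ|/σ and n), not that the clinical conclusions of any
particular trial are correct.

Calibration runs in the test suite use 200–500 replicates per condition
and a 3×3 (effect × sample-size) grid; monotonicity checks allow 3
binomial standard errors of slack.

## Known limitations

- Two-sided default test only: no one-sided/directional variants, no
  informed (shifted) priors, no paired or one-sample tests, no posterior
  estimation of δ.
- The CI→SE inversion trusts the printed interval; asymmetric or
  non-Wald intervals (e.g. bootstrap) would bias t.
- Arm-size reconstruction from a printed total is inherently a
  convention; both supported rules are approximations to the unpublished
  per-arm n, and the Bayes factor is moderately sensitive to it.
- Posterior probabilities assume 1:1 prior odds between hypotheses.
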