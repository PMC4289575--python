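# Methods

## Data model

A study is a fourfold table in exposure-by-status orientation: `a`
exposed cases, `b` exposed controls, `c` unexposed cases, `d` unexposed
controls; the case arm has `n1 = a + c` subjects and the control arm
`n2 = b + d`. Counts are validated as non-negative integers and both
arms must be non-empty. The effect scale is the log odds ratio; the
arcsine difference `arcsin√(a/n1) − arcsin√(b/n2)` (variance
`1/(4n1) + 1/(4n2)`, defined for zero cells) supports the arcsine-scale
tests.

**Continuity rule.** Tables containing a zero cell get the
Haldane–Anscombe correction — 0.5 added to all four cells — before the
logOR and its asymptotic variance are computed. The rule applies
per study, never to the arcsine scale, and can be switched off
(`correction="none"`), in which case a zero cell is an error. The
pooled exposure rates used by the smoothed variance are computed from
raw totals; only if an entire pooled margin is zero is 0.5 added to the
pooled cells of that arm.

## Smoothed variance

With pooled rates `p1 = Σa/Σn1`, `p2 = Σb/Σn2`, each study's smoothed
variance is

    sv_i = 1/(n1_i p1 (1−p1)) + 1/(n2_i p2 (1−p2)),

the asymptotic logOR variance evaluated at the expected cell counts
under the pooled rates. Consequences that the package treats as
contract and tests directly: within a meta-analysis `sv_i` is a
function of `(n1_i, n2_i)` only; it is invariant to redistributing a
study's exposed/unexposed counts at fixed margins (and fixed pooled
totals); it scales as `1/size`; and ordering studies by smoothed
precision agrees with ordering by arm sizes whenever the studies are
comparable componentwise in `(n1, n2)`. For arbitrary size pairs no
size-based *total* order can agree with `sv` for every pooled-rate
pair, so the ordering property is asserted on metas with nested arm
sizes at a fixed case:control ratio — the regime in which the claim is
meaningful.

## Regression and rank tests

All regression tests share one weighted-least-squares primitive fitting
`y = α + βx` with weights `w`, solved by QR on the weighted design (and
cross-checked against closed-form normal equations to 1e-10 in the
suite). Slope inference uses `t = β̂/se(β̂)` on `k − 2` degrees of
freedom. The standard error comes from `(X'WX)⁻¹` scaled by a residual
dispersion factor `s² = RSS_w/(k−2)`:

* multiplicative `s²` for the Egger, AS-Egger, Harbord and Peters
  fits, matching standard Egger-type practice;
* `max(1, s²)` for the additive-weight fits (SVE, SVT, AS-Thompson),
  whose weights `1/(v_i + τ̂²)` are already on the correct absolute
  scale, so under-dispersion is not allowed to shrink the standard
  errors.

A slope or weighted RSS at rounding-noise level (≤ 1e-10 relative to
the weighted norm of `y`) is snapped to zero so that a perfectly flat
funnel reports statistic 0 and p = 1 instead of a ratio of machine
epsilons.

The between-study variance is the method-of-moments estimator for
meta-regression,

    τ̂² = max(0, (Q − (k−2)) / (Σw − tr((X'WX)⁻¹ X'W²X))),

with `Q` the weighted residual sum of squares of the fixed-effect fit
(`w = 1/v`). This generalises DerSimonian–Laird to the two-parameter
design; the suite confirms approximate unbiasedness at k = 200.

Rank tests use Kendall's S with the tie-adjusted null variance and a
continuity correction (`|S| − 1`; configurable). Begg standardises
effects against the fixed-effect pooled mean with conditional variances
`v_i − 1/Σ(1/v_j)`, floored at 1e-12 when non-positive (flagged).
Schwarzer works on the count scale: each study's exposed-case count is
standardised against the exact mean and variance of Fisher's noncentral
hypergeometric distribution at the Mantel–Haenszel pooled odds ratio,
computed by direct log-space summation over the support. Harbord's test
regresses score-based pseudo-effects `Z_i/V_i` on `1/√V_i`; studies
with degenerate margins (`V_i = 0`) are dropped with a warning. Peters'
test regresses logOR on `1/n` with weights `(a+b)(c+d)/n`; the
status-margin orientation `(a+c)(b+d)/n` is available as an option
because the secondary literature is ambiguous for case-control designs.

Per-test failure (collinear design, too few studies, degenerate meta)
is captured as a not-applicable result inside `run_all_tests`; the
batch never aborts. The fixed reporting order is Begg, Schwarzer,
AS-Begg, Egger, Harbord, Peters, AS-Egger, AS-Thompson, SVE, SVT.

**Known limitation.** When all studies share the same arm sizes the
smoothed standard error is constant and the SVE/SVT slope is not
identifiable; the tests report not-applicable. This is the structural
counterpart of the low power all asymmetry tests have when study sizes
are similar.

## Simulation model

One study: average exposure rate `r ~ U(0.3, 0.7)` (common regime) or
`U(0.1, 0.3)` (rare); `mu = logit(r)`; study effect
`θ_i ~ N(ln OR, τ²)`; exposure probabilities `p1 = expit(mu + θ_i/2)`
in cases and `p2 = expit(mu − θ_i/2)` in controls, so the study's true
odds ratio is exactly `exp(θ_i)` and `mu` is the average rate on the
logit scale; total size `n = round(exp(N(6.049, 0.848²)))`, floored at
10 (moments estimated from published Human Genome Epidemiology
meta-analyses); case fraction from a triangular distribution with mode
`1/(1+ratio)`, half-width 0.15, clipped to (0.05, 0.95) and arms
floored at 2 — so the per-study case:control ratio fluctuates
realistically around the 1:1…1:4 target instead of being fixed;
exposed counts `a ~ Bin(n1, p1)`, `b ~ Bin(n2, p2)`.

**Heterogeneity calibration.** The target is an I² level; τ² is set to
`s̄²·I²/(1−I²)` where `s̄²` is the arithmetic mean asymptotic logOR
variance over a pilot batch of 1,000 studies generated at τ² = 0 (I²
of 75/50/25/1 % therefore corresponds to τ² equal to 300/100/33/1 % of
the average within-study variance). A two-pass scheme is unavoidable
because the average within-study variance is unobservable before
generation. Note that the DerSimonian–Laird I² statistic computed on
the resulting metas weighs variances through the harmonic-type
"typical" within-study variance rather than the arithmetic mean; with
log-normally sized studies the empirical DL I² therefore sits above the
nominal target (≈ 0.39/0.66/0.84 for targets 0.25/0.50/0.75). The
suite checks that the empirical DL I² agrees with the value implied by
the calibrated τ² and the typical variance (within 2–5 points) and
that it is monotone in the target; calibrating against the typical
variance instead would change what "300 % of the average variance"
means and was deliberately not done.

**Selection.** Publication bias acts on each candidate study's
two-sided Wald p-value (from the continuity-corrected logOR):
inclusion probabilities 0.95 / 0.75 / 0.50 (mild) or 0.95 / 0.50 /
0.25 (severe) on the brackets `p ≤ 0.05`, `0.05 < p ≤ 0.5`, `p > 0.5`.
Independently, the 10 % most extreme candidate effects are censored
outright; "most extreme" defaults to the lowest decile of the pilot
θ̂ distribution (producing the classic missing lower-left chunk of the
funnel), with `high` and `absolute` directions available since the
convention is a modelling choice. Candidates are drawn until k studies
are accepted; selection decides membership only and never alters a
study's counts. An acceptance rate collapsing below ~1/2000 per
required study raises a runaway-selection error as a misconfiguration
guard.

## Experiment runner

The default grid is the full factorial: k ∈ {5, 10, 20, 30, 60} ×
OR ∈ {1.0, 1.2, 1.4, 1.6, 1.8, 2.0} × {common, rare} × I² ∈ {75, 50,
25, 1 %} × ratio ∈ {1:1…1:4} × {none, mild, severe} = 2,880 scenarios,
1,000 replicates each, rejection at p ≤ 0.10 (the conventional level
for asymmetry tests, which are chronically under-powered at typical k).
Each scenario receives a child seed derived from the master seed and
the scenario index via `numpy` seed sequences, so every cell is
reproducible bit-for-bit and independent of the others. Replicates
where a test is not applicable are excluded from that test's
denominator and reported separately; the Monte Carlo standard error
`√(p̂(1−p̂)/n)` uses the effective denominator (0.0095 at p̂ = 0.10,
n = 1,000).

The behavioural test suite runs reduced-scale versions of the
headline comparisons — 500 replicates of the no-bias reference cell
(k = 30, OR = 1.4, common events, balanced arms, I² = 1 %) for
empirical size, and severe-bias cells at k = 10/30/60 for SVT power —
sizes chosen to keep the suite fast while the 3-Monte-Carlo-error
bands remain informative.

## Numerical and design notes

* Weighted fits use `numpy.linalg.lstsq` on the square-root-weighted
  design for stability; covariance from explicit `(X'WX)⁻¹` (2×2).
* Noncentral hypergeometric moments are exact summations in log space
  (`gammaln`), stable for the support sizes that occur (hundreds);
  single-point supports return variance 0 and the affected study
  contributes a standardised deviation of 0 to Schwarzer's test.
* All ten tests are two-sided and invariant under a simultaneous flip
  of every study's exposure labels; this is enforced by tests for each
  method.
* The synthetic generator emulates study-size and arm-ratio
  heterogeneity, binomial sampling noise, normal random effects and
  p-value-driven selection. It does not emulate correlated outcomes,
  non-normal random-effect distributions, cohort/person-time designs,
  or selection mechanisms of the Copas type — conclusions from passing
  tests extend to real data only insofar as those features are absent.
* CSV is the single input dialect; results export as CSV or JSON with
  6 significant digits and a provenance block (package version, seed,
  config echo). Logging goes to stderr, results to stdout/files.
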