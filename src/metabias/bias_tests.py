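"""Funnel-plot asymmetry tests for meta-analyses of binary outcomes.

Ten tests are provided, in the fixed reporting order

    Begg, Schwarzer, AS-Begg, Egger, Harbord, Peters,
    AS-Egger, AS-Thompson, SVE, SVT

covering the three rank-correlation tests (Begg, Schwarzer, AS-Begg) and
seven weighted-regression tests.  The SVE and SVT tests regress the log
odds ratio on its *smoothed* standard error (see
:mod:`metabias.effect_measures`): SVE weights by the inverse smoothed
variance, SVT adds a method-of-moments between-study variance ``tau2`` to
the weights, ``w_i = 1/(sv_i + tau2)``.  For every regression test the
null hypothesis of no small-study effect is ``slope = 0``, assessed with a
t statistic on ``k - 2`` degrees of freedom.

All tests are two-sided and invariant under a simultaneous flip of the
exposure labels of every study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy import special, stats

from .effect_measures import (
    ContinuityRule,
    MetaAnalysis,
    arcsine_difference,
    log_odds_ratio,
    smoothed_variance,
)
from .exceptions import (
    CollinearDesignError,
    DegenerateMetaError,
    TooFewStudiesError,
    ValidationError,
)

__all__ = [
    "METHOD_ORDER",
    "RegressionFit",
    "TestResult",
    "wls_fit",
    "moments_tau2",
    "rank_correlation_test",
    "begg_test",
    "egger_test",
    "sve_test",
    "svt_test",
    "as_thompson_test",
    "harbord_test",
    "peters_test",
    "mantel_haenszel_or",
    "nchg_moments",
    "schwarzer_test",
    "run_all_tests",
]

#: Fixed reporting order of the ten tests.
METHOD_ORDER: tuple[str, ...] = (
    "Begg",
    "Schwarzer",
    "AS-Begg",
    "Egger",
    "Harbord",
    "Peters",
    "AS-Egger",
    "AS-Thompson",
    "SVE",
    "SVT",
)

#: Floor for negative variances in Begg's standardisation.
_VSTAR_FLOOR = 1e-12

Dispersion = Literal["fixed", "multiplicative", "floor"]
Measure = Literal["logOR", "arcsine"]


@dataclass(frozen=True)
class RegressionFit:
    """A weighted least-squares fit of effect on a single covariate.

    ``alpha`` is the intercept, ``beta`` the slope; ``tau2`` records any
    additive between-study variance folded into the weights (0 otherwise).
    Standard errors come from ``(X'WX)^-1`` scaled by the residual
    dispersion factor chosen by the caller.
    """

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    tau2: float
    weights: np.ndarray
    residuals: np.ndarray
    df: int
    dispersion: str

    @property
    def t_beta(self) -> float:
        # zero residual dispersion: a zero slope is "no asymmetry", not 0/0
        if self.se_beta == 0.0:
            return 0.0 if self.beta == 0.0 else math.copysign(math.inf, self.beta)
        return self.beta / self.se_beta

    @property
    def p_beta(self) -> float:
        """Two-sided p-value for slope = 0 on ``df`` degrees of freedom."""
        return float(2.0 * stats.t.sf(abs(self.t_beta), self.df))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one asymmetry test.

    ``df`` is ``None`` for the normal-approximation (rank) tests.
    ``applicable`` is False when a test could not be run on this meta
    (degenerate design, too few studies); then ``p_value`` is NaN and
    ``message`` explains why.  ``degenerate`` flags rank tests whose
    statistic is identically zero because one input vector is constant.
    """

    method: str
    statistic: float
    p_value: float
    n_studies: int
    df: Optional[int] = None
    applicable: bool = True
    degenerate: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.applicable and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def significant(self, alpha: float = 0.10) -> bool:
        return self.applicable and self.p_value <= alpha


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _is_constant(x: np.ndarray) -> bool:
    scale = max(1.0, float(np.max(np.abs(x))))
    return float(np.ptp(x)) <= 1e-12 * scale


def wls_fit(
    y: Sequence[float],
    x: Sequence[float],
    w: Sequence[float],
    *,
    dispersion: Dispersion = "multiplicative",
    tau2: float = 0.0,
) -> RegressionFit:
    """Weighted least squares of ``y`` on an intercept and ``x``.

    Parameters
    ----------
    y, x, w
        Effect values, covariate and positive weights, one entry per study.
    dispersion
        How the residual scale enters the coefficient standard errors:
        ``"fixed"`` uses ``(X'WX)^-1`` as is (weights treated as exact
        inverse variances); ``"multiplicative"`` scales it by
        ``s^2 = RSS_w / (k - 2)`` as in Egger-type regressions;
        ``"floor"`` scales by ``max(1, s^2)``, appropriate when the weights
        already contain an additive between-study variance so that
        under-dispersion should not shrink the standard errors.
    tau2
        Recorded on the fit for bookkeeping; not used in the computation.

    Raises
    ------
    TooFewStudiesError
        Fewer than 3 studies.
    CollinearDesignError
        Constant covariate.
    """
    y_arr = _as_float_array(y, "y")
    x_arr = _as_float_array(x, "x")
    w_arr = _as_float_array(w, "w")
    k = y_arr.size
    if not (x_arr.size == k and w_arr.size == k):
        raise ValidationError("y, x and w must have equal length")
    if k < 3:
        raise TooFewStudiesError(f"need at least 3 studies, got {k}")
    if np.any(w_arr <= 0):
        raise ValidationError("weights must be strictly positive")
    if _is_constant(x_arr):
        raise CollinearDesignError("covariate is constant across studies")

    design = np.column_stack([np.ones(k), x_arr])
    sqrt_w = np.sqrt(w_arr)
    coef, *_ = np.linalg.lstsq(design * sqrt_w[:, None], y_arr * sqrt_w, rcond=None)

    # Snap slope and weighted RSS that sit at rounding-noise level to zero,
    # so e.g. a perfectly flat funnel gives statistic 0, p = 1 rather than a
    # ratio of machine epsilons.
    noise = 1e-10 * max(1.0, math.sqrt(float(w_arr @ y_arr**2)))
    if abs(coef[1]) * float(np.ptp(x_arr)) <= noise:
        coef[1] = 0.0
    residuals = y_arr - design @ coef
    rss_w = float(w_arr @ residuals**2)
    if math.sqrt(rss_w) <= noise:
        rss_w = 0.0
    df = k - 2

    xtwx = design.T @ (w_arr[:, None] * design)
    cov_unscaled = np.linalg.inv(xtwx)
    s2 = rss_w / df
    if dispersion == "fixed":
        scale = 1.0
    elif dispersion == "multiplicative":
        scale = s2
    elif dispersion == "floor":
        scale = max(1.0, s2)
    else:  # pragma: no cover - guarded by Literal type
        raise ValidationError(f"unknown dispersion {dispersion!r}")
    cov = scale * cov_unscaled

    return RegressionFit(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        se_alpha=float(math.sqrt(cov[0, 0])),
        se_beta=float(math.sqrt(cov[1, 1])),
        tau2=float(tau2),
        weights=w_arr,
        residuals=residuals,
        df=df,
        dispersion=dispersion,
    )


def moments_tau2(
    y: Sequence[float], x: Sequence[float], v: Sequence[float]
) -> float:
    """Method-of-moments between-study variance for a meta-regression.

    Fits the fixed-effect regression with weights ``1/v`` and generalises
    the DerSimonian-Laird estimator to a two-parameter design:

        tau2 = max(0, (Q - (k - 2)) / (sum(w) - tr((X'WX)^-1 X'W^2X)))

    where ``Q`` is the weighted residual sum of squares.
    """
    v_arr = _as_float_array(v, "v")
    if np.any(v_arr <= 0):
        raise ValidationError("within-study variances must be positive")
    w = 1.0 / v_arr
    fit = wls_fit(y, x, w, dispersion="fixed")
    q = float(w @ fit.residuals**2)
    design = np.column_stack([np.ones(w.size), np.asarray(x, dtype=float)])
    xtwx = design.T @ (w[:, None] * design)
    xtw2x = design.T @ ((w**2)[:, None] * design)
    denom = float(w.sum() - np.trace(np.linalg.solve(xtwx, xtw2x)))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (w.size - 2)) / denom)


def _kendall_s(t: np.ndarray, s: np.ndarray) -> int:
    dt = np.sign(t[:, None] - t[None, :])
    ds = np.sign(s[:, None] - s[None, :])
    return int(np.sum(np.triu(dt * ds, k=1)))


def _tie_sums(x: np.ndarray) -> tuple[float, float, float]:
    _, counts = np.unique(x, return_counts=True)
    c = counts.astype(float)
    return (
        float(np.sum(c * (c - 1) * (2 * c + 5))),
        float(np.sum(c * (c - 1))),
        float(np.sum(c * (c - 1) * (c - 2))),
    )


def rank_correlation_test(
    t: Sequence[float],
    s: Sequence[float],
    *,
    method: str = "rank",
    continuity: bool = True,
) -> TestResult:
    """Kendall rank-correlation test between two study-level vectors.

    Computes the Kendall S statistic (concordant minus discordant pairs),
    its tie-adjusted null variance, and a two-sided normal p-value.  With
    ``continuity`` (default) the standardisation uses ``|S| - 1``.
    A constant input vector yields a degenerate result with ``p = 1``.
    """
    t_arr = _as_float_array(t, "t")
    s_arr = _as_float_array(s, "s")
    k = t_arr.size
    if s_arr.size != k:
        raise ValidationError("t and s must have equal length")
    if k < 3:
        raise TooFewStudiesError(f"need at least 3 studies, got {k}")

    if _is_constant(t_arr) or _is_constant(s_arr):
        return TestResult(
            method=method,
            statistic=0.0,
            p_value=1.0,
            n_studies=k,
            degenerate=True,
            message="constant input vector",
        )

    s_stat = _kendall_s(t_arr, s_arr)
    vt, t2_t, t3_t = _tie_sums(t_arr)
    vu, t2_u, t3_u = _tie_sums(s_arr)
    n = float(k)
    var = (n * (n - 1) * (2 * n + 5) - vt - vu) / 18.0
    var += t2_t * t2_u / (2.0 * n * (n - 1))
    var += t3_t * t3_u / (9.0 * n * (n - 1) * (n - 2))
    if var <= 0:
        return TestResult(
            method=method,
            statistic=0.0,
            p_value=1.0,
            n_studies=k,
            degenerate=True,
            message="zero null variance (all pairs tied)",
        )
    shift = 1.0 if continuity else 0.0
    z = math.copysign(max(abs(s_stat) - shift, 0.0), s_stat) / math.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(method=method, statistic=z, p_value=min(p, 1.0), n_studies=k)


def _effects(
    meta: MetaAnalysis, measure: Measure, correction: ContinuityRule
) -> tuple[np.ndarray, np.ndarray]:
    if measure == "logOR":
        ests = [log_odds_ratio(t, correction) for t in meta]
    elif measure == "arcsine":
        ests = [arcsine_difference(t) for t in meta]
    else:
        raise ValidationError(f"unknown measure {measure!r}")
    theta = np.array([e.theta for e in ests])
    var = np.array([e.var_asym for e in ests])
    return theta, var


def _require_k(meta: MetaAnalysis, minimum: int = 3) -> None:
    if meta.k < minimum:
        raise TooFewStudiesError(
            f"need at least {minimum} studies, got {meta.k}"
        )


def begg_test(
    meta: MetaAnalysis,
    measure: Measure = "logOR",
    correction: ContinuityRule = "haldane",
    continuity: bool = True,
) -> TestResult:
    """Begg's rank correlation test (AS-Begg on the arcsine scale).

    Standardises each effect against the fixed-effect pooled mean,
    ``t_i = (theta_i - theta_bar) / sqrt(v_i - 1/sum(1/v_j))``, and tests
    Kendall correlation between the ``t_i`` and the variances ``v_i``.
    Non-positive conditional variances (possible with extreme weights) are
    floored at 1e-12.
    """
    _require_k(meta)
    theta, v = _effects(meta, measure, correction)
    inv_v = 1.0 / v
    theta_bar = float(theta @ inv_v / inv_v.sum())
    v_star = v - 1.0 / inv_v.sum()
    flagged = bool(np.any(v_star <= 0))
    v_star = np.maximum(v_star, _VSTAR_FLOOR)
    t = (theta - theta_bar) / np.sqrt(v_star)
    name = "Begg" if measure == "logOR" else "AS-Begg"
    result = rank_correlation_test(t, v, method=name, continuity=continuity)
    if flagged and not result.message:
        result = TestResult(
            method=result.method,
            statistic=result.statistic,
            p_value=result.p_value,
            n_studies=result.n_studies,
            degenerate=result.degenerate,
            message="non-positive conditional variance floored",
        )
    return result


def _slope_result(fit: RegressionFit, name: str, k: int) -> TestResult:
    return TestResult(
        method=name,
        statistic=fit.t_beta,
        p_value=fit.p_beta,
        n_studies=k,
        df=fit.df,
    )


def egger_test(
    meta: MetaAnalysis,
    measure: Measure = "logOR",
    correction: ContinuityRule = "haldane",
) -> TestResult:
    """Egger's weighted regression of effect on its standard error.

    Fits ``theta_i = alpha + beta * se_i`` with weights ``1/v_i`` and tests
    ``beta = 0`` (t, ``k - 2`` df).  On the arcsine scale this is the
    AS-Egger test.
    """
    _require_k(meta)
    theta, v = _effects(meta, measure, correction)
    se = np.sqrt(v)
    fit = wls_fit(theta, se, 1.0 / v, dispersion="multiplicative")
    name = "Egger" if measure == "logOR" else "AS-Egger"
    return _slope_result(fit, name, meta.k)


def sve_test(
    meta: MetaAnalysis, correction: ContinuityRule = "haldane"
) -> TestResult:
    """Smoothed-variance Egger (SVE) test.

    Regresses the log odds ratio on its smoothed standard error with
    weights ``1/sv_i``.  All studies sharing the same arm sizes make the
    smoothed standard error constant, so the slope is not identifiable;
    this surfaces as a :class:`CollinearDesignError` (the test has no power
    when study sizes are all similar).
    """
    _require_k(meta)
    theta, _ = _effects(meta, "logOR", correction)
    sv = np.array([p.sv for p in smoothed_variance(meta)])
    fit = wls_fit(theta, np.sqrt(sv), 1.0 / sv, dispersion="floor")
    return _slope_result(fit, "SVE", meta.k)


def svt_test(
    meta: MetaAnalysis, correction: ContinuityRule = "haldane"
) -> TestResult:
    """Smoothed-variance Thompson (SVT) test.

    Like SVE, but first estimates the between-study variance ``tau2`` by
    the method of moments and refits with additive weights
    ``w_i = 1/(sv_i + tau2)``.  Reduces exactly to SVE when ``tau2 = 0``.
    """
    _require_k(meta)
    theta, _ = _effects(meta, "logOR", correction)
    sv = np.array([p.sv for p in smoothed_variance(meta)])
    se = np.sqrt(sv)
    tau2 = moments_tau2(theta, se, sv)
    fit = wls_fit(theta, se, 1.0 / (sv + tau2), dispersion="floor", tau2=tau2)
    return _slope_result(fit, "SVT", meta.k)


def as_thompson_test(meta: MetaAnalysis) -> TestResult:
    """Arcsine Thompson (AS-Thompson) test.

    The SVT construction on the arcsine scale: effect is the arcsine
    difference, within-study variance ``1/(4 n1) + 1/(4 n2)``, additive
    method-of-moments ``tau2`` in the weights, slope t-test.
    """
    _require_k(meta)
    theta, v = _effects(meta, "arcsine", "none")
    se = np.sqrt(v)
    tau2 = moments_tau2(theta, se, v)
    fit = wls_fit(theta, se, 1.0 / (v + tau2), dispersion="floor", tau2=tau2)
    return _slope_result(fit, "AS-Thompson", meta.k)


def harbord_test(meta: MetaAnalysis) -> TestResult:
    """Harbord's score-based regression test.

    Uses the score ``Z_i = a_i - E[a_i]`` and Fisher information ``V_i`` of
    the conditional likelihood at odds ratio 1, then applies the
    Egger-type regression to pseudo-effects ``Z_i/V_i`` with pseudo
    standard errors ``1/sqrt(V_i)``.  Studies with degenerate margins
    (``V_i = 0``) are dropped.
    """
    _require_k(meta)
    z_list, v_list = [], []
    dropped = 0
    for t in meta:
        n = t.n
        v = (
            (t.a + t.b) * (t.c + t.d) * t.n1 * t.n2 / (n**2 * (n - 1.0))
            if n > 1
            else 0.0
        )
        if v <= 0:
            dropped += 1
            continue
        z = t.a - (t.a + t.b) * t.n1 / n
        z_list.append(z)
        v_list.append(v)
    k = len(z_list)
    if k < 3:
        raise TooFewStudiesError(
            f"only {k} studies with non-degenerate margins ({dropped} dropped)"
        )
    z_arr = np.array(z_list)
    v_arr = np.array(v_list)
    fit = wls_fit(
        z_arr / v_arr, 1.0 / np.sqrt(v_arr), v_arr, dispersion="multiplicative"
    )
    result = _slope_result(fit, "Harbord", k)
    if dropped:
        result = TestResult(
            method=result.method,
            statistic=result.statistic,
            p_value=result.p_value,
            n_studies=k,
            df=result.df,
            message=f"{dropped} studies with degenerate margins dropped",
        )
    return result


def peters_test(
    meta: MetaAnalysis,
    correction: ContinuityRule = "haldane",
    weight_margin: Literal["exposure", "status"] = "exposure",
) -> TestResult:
    """Peters' regression of the log odds ratio on inverse total size.

    Weights are the product of the margin totals over ``n``:
    ``(a+b)(c+d)/n`` with the default ``"exposure"`` orientation, or
    ``(a+c)(b+d)/n`` with ``"status"``.
    """
    _require_k(meta)
    theta, _ = _effects(meta, "logOR", correction)
    n = np.array([t.n for t in meta], dtype=float)
    if weight_margin == "exposure":
        w = np.array([(t.a + t.b) * (t.c + t.d) / t.n for t in meta])
    elif weight_margin == "status":
        w = np.array([t.n1 * t.n2 / t.n for t in meta], dtype=float)
    else:
        raise ValidationError(f"unknown weight margin {weight_margin!r}")
    if np.any(w <= 0):
        raise DegenerateMetaError("zero Peters weight (empty margin)")
    fit = wls_fit(theta, 1.0 / n, w, dispersion="multiplicative")
    return _slope_result(fit, "Peters", meta.k)


def mantel_haenszel_or(meta: MetaAnalysis) -> float:
    """Mantel-Haenszel pooled odds ratio ``sum(a d / n) / sum(b c / n)``.

    If either sum is zero, tables containing a zero cell get the 0.5
    continuity correction and the sums are recomputed.
    """
    num = sum(t.a * t.d / t.n for t in meta)
    den = sum(t.b * t.c / t.n for t in meta)
    if num == 0 or den == 0:
        num = den = 0.0
        for t in meta:
            a, b, c, d = t.corrected_cells("haldane")
            num += a * d / t.n
            den += b * c / t.n
        if num == 0 or den == 0:
            raise DegenerateMetaError(
                "Mantel-Haenszel odds ratio undefined even after correction"
            )
    return num / den


def nchg_moments(
    n1: int, n2: int, m1: int, psi: float
) -> tuple[float, float]:
    """Mean and variance of Fisher's noncentral hypergeometric count.

    The exposed-case count ``a`` conditioned on all margins of a 2x2 table
    with arm sizes ``n1`` (cases), ``n2`` (controls), exposed total ``m1``
    and odds ratio ``psi`` has support ``max(0, m1-n2) .. min(m1, n1)`` and
    weights ``C(n1, a) C(n2, m1-a) psi^a``.  Computed by direct summation
    in log space.
    """
    if psi <= 0:
        raise ValidationError(f"odds ratio psi={psi} must be positive")
    lo = max(0, m1 - n2)
    hi = min(m1, n1)
    if m1 < 0 or m1 > n1 + n2 or lo > hi:
        raise ValidationError(
            f"infeasible margins n1={n1}, n2={n2}, m1={m1}"
        )
    a = np.arange(lo, hi + 1)
    logw = (
        special.gammaln(n1 + 1)
        - special.gammaln(a + 1)
        - special.gammaln(n1 - a + 1)
        + special.gammaln(n2 + 1)
        - special.gammaln(m1 - a + 1)
        - special.gammaln(n2 - m1 + a + 1)
        + a * math.log(psi)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    mean = float(w @ a)
    var = float(w @ (a - mean) ** 2)
    return mean, max(var, 0.0)


def schwarzer_test(
    meta: MetaAnalysis, continuity: bool = True
) -> TestResult:
    """Schwarzer's rank correlation test on count-scale deviations.

    Standardises each study's exposed-case count against its conditional
    expectation under the Mantel-Haenszel pooled odds ratio,
    ``z_i = (a_i - E_i)/sqrt(V_i)``, and tests Kendall correlation between
    the ``z_i`` and the conditional variances ``V_i``.  Avoids the logOR
    scale entirely, so it needs no continuity correction for zero cells.
    """
    _require_k(meta)
    psi = mantel_haenszel_or(meta)
    z = np.empty(meta.k)
    v = np.empty(meta.k)
    for i, t in enumerate(meta):
        mean, var = nchg_moments(t.n1, t.n2, t.a + t.b, psi)
        if var > 0:
            z[i] = (t.a - mean) / math.sqrt(var)
        else:
            z[i] = 0.0  # single-point support: count is deterministic
        v[i] = var
    return rank_correlation_test(z, v, method="Schwarzer", continuity=continuity)


_DISPATCH: dict[str, Callable[..., TestResult]] = {
    "Begg": lambda meta, correction: begg_test(meta, "logOR", correction),
    "Schwarzer": lambda meta, correction: schwarzer_test(meta),
    "AS-Begg": lambda meta, correction: begg_test(meta, "arcsine", correction),
    "Egger": lambda meta, correction: egger_test(meta, "logOR", correction),
    "Harbord": lambda meta, correction: harbord_test(meta),
    "Peters": lambda meta, correction: peters_test(meta, correction),
    "AS-Egger": lambda meta, correction: egger_test(meta, "arcsine", correction),
    "AS-Thompson": lambda meta, correction: as_thompson_test(meta),
    "SVE": lambda meta, correction: sve_test(meta, correction),
    "SVT": lambda meta, correction: svt_test(meta, correction),
}


def run_all_tests(
    meta: MetaAnalysis,
    methods: Optional[Sequence[str]] = None,
    correction: ContinuityRule = "haldane",
) -> list[TestResult]:
    """Run the requested asymmetry tests, never aborting the batch.

    Methods run in the fixed order of :data:`METHOD_ORDER`.  A test that
    cannot be applied to this meta-analysis (degenerate design, too few
    studies) yields a not-applicable :class:`TestResult` with ``p = NaN``
    rather than raising.
    """
    _require_k(meta)
    if methods is None:
        selected = list(METHOD_ORDER)
    else:
        unknown = [m for m in methods if m not in _DISPATCH]
        if unknown:
            raise ValidationError(
                f"unknown methods {unknown}; choose from {list(METHOD_ORDER)}"
            )
        selected = [m for m in METHOD_ORDER if m in set(methods)]
    results = []
    for name in selected:
        try:
            results.append(_DISPATCH[name](meta, correction))
        except (
            CollinearDesignError,
            TooFewStudiesError,
            DegenerateMetaError,
        ) as exc:
            results.append(
                TestResult(
                    method=name,
                    statistic=float("nan"),
                    p_value=float("nan"),
                    n_studies=meta.k,
                    applicable=False,
                    message=str(exc),
                )
            )
    return results
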