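"""Simulation of meta-analyses of observational case-control studies.

The generator emulates the landscape of Human Genome Epidemiology (HuGE)
reviews: many moderately sized case-control studies with unbalanced arms,
binary exposure, and odds ratios between 1 and 2.  One simulated study is
drawn as follows:

* total size ``n`` from a log-normal distribution, ``ln n ~ N(6.049,
  0.848^2)`` (calibrated to published HuGE meta-analyses), floored at 10;
* the case-arm fraction from a triangular distribution with mode
  ``1/(1 + ratio)`` for a target case:control ratio of ``1:ratio``, so the
  per-study ratio fluctuates realistically around the target instead of
  being fixed;
* an average exposure rate ``r`` from U(0.3, 0.7) ("common") or
  U(0.1, 0.3) ("rare"); ``mu = logit(r)`` is the study's average rate on
  the logit scale;
* a study-level log odds ratio ``theta_i ~ N(ln OR, tau2)``, split
  symmetrically about ``mu``: exposure probabilities
  ``p1 = expit(mu + theta_i/2)`` in cases and ``p2 = expit(mu -
  theta_i/2)`` in controls, so the study's true odds ratio is exactly
  ``exp(theta_i)``;
* exposed counts ``a ~ Bin(n1, p1)`` and ``b ~ Bin(n2, p2)``.

Heterogeneity is specified as a target I-squared; the between-study
variance is ``tau2 = s2_bar * I2 / (1 - I2)`` where ``s2_bar`` is the
average asymptotic logOR variance over a pilot batch of studies generated
without heterogeneity (I2 of 75/50/25/1 % corresponds to tau2 equal to
300/100/33/1 % of the average within-study variance).

Publication bias is induced through each candidate study's two-sided Wald
p-value: inclusion probabilities (0.95, 0.75, 0.50) for mild bias and
(0.95, 0.50, 0.25) for severe bias over the p-value brackets
``p <= 0.05``, ``0.05 < p <= 0.5`` and ``p > 0.5``; in addition the 10 %
most extreme effect estimates (by default the lowest decile of the pilot
theta-hat distribution) are censored outright.  Selection only decides
membership — it never alters a study's counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .effect_measures import FourfoldTable, MetaAnalysis, log_odds_ratio
from .exceptions import ConfigError, RunawaySelectionError

__all__ = [
    "Scenario",
    "StudyDraw",
    "SelectionModel",
    "Calibration",
    "MILD_SELECTION",
    "SEVERE_SELECTION",
    "sample_log_total_size",
    "sample_total_size",
    "sample_case_fraction",
    "calibrate_scenario",
    "resolve_tau2",
    "generate_study",
    "inclusion_probability",
    "generate_meta",
]

#: Parameters of ln(total study size), from published HuGE meta-analyses.
LOG_SIZE_MEAN = 6.049
LOG_SIZE_SD = 0.848

#: Smallest simulated study and smallest arm.
MIN_STUDY_SIZE = 10
MIN_ARM_SIZE = 2

#: Half-width of the triangular case-fraction distribution around its mode.
TRIANGLE_HALF_WIDTH = 0.15

#: Number of pilot studies used to calibrate tau2 and the censoring cutoff.
PILOT_SIZE = 1000

EventRegime = Literal["common", "rare"]
BiasLevel = Literal["none", "mild", "severe"]
CensorDirection = Literal["low", "high", "absolute"]

_REGIME_BOUNDS: dict[str, tuple[float, float]] = {
    "common": (0.3, 0.7),
    "rare": (0.1, 0.3),
}


@dataclass(frozen=True)
class Scenario:
    """One simulation cell.

    Parameters
    ----------
    k
        Number of studies in each simulated meta-analysis.
    or_true
        Underlying odds ratio (the mean of the random-effects
        distribution is ``ln(or_true)``).
    event_regime
        ``"common"`` draws average exposure rates from U(0.3, 0.7),
        ``"rare"`` from U(0.1, 0.3).
    i2_target
        Target I-squared in (0, 1); translated into ``tau2`` by pilot
        calibration.
    ratio
        Case:control size ratio target ``1:ratio`` (integer >= 1).
    bias
        Publication-bias level: ``"none"``, ``"mild"`` or ``"severe"``.
    seed
        Seed recorded with every output; ``None`` means caller-managed.
    """

    k: int
    or_true: float
    event_regime: EventRegime = "common"
    i2_target: float = 0.01
    ratio: int = 1
    bias: BiasLevel = "none"
    seed: Optional[int] = None
    censor_direction: CensorDirection = "low"

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ConfigError(f"k={self.k} must be at least 3")
        if self.or_true <= 0:
            raise ConfigError(f"or_true={self.or_true} must be positive")
        if self.event_regime not in _REGIME_BOUNDS:
            raise ConfigError(f"unknown event regime {self.event_regime!r}")
        if not 0.0 <= self.i2_target < 1.0:
            raise ConfigError(f"i2_target={self.i2_target} outside [0, 1)")
        if self.ratio < 1:
            raise ConfigError(f"ratio={self.ratio} must be >= 1")
        if self.bias not in ("none", "mild", "severe"):
            raise ConfigError(f"unknown bias level {self.bias!r}")
        if self.censor_direction not in ("low", "high", "absolute"):
            raise ConfigError(
                f"unknown censor direction {self.censor_direction!r}"
            )

    @property
    def log_or(self) -> float:
        return math.log(self.or_true)


@dataclass(frozen=True)
class StudyDraw:
    """One simulated study together with its latent parameters."""

    n_total: int
    n1: int
    n2: int
    mu: float
    theta_i: float
    p1: float
    p2: float
    table: FourfoldTable
    theta_hat: float
    var_hat: float
    p_value: float


@dataclass(frozen=True)
class SelectionModel:
    """P-value driven inclusion rules plus extreme-effect censoring.

    ``prob_rules`` maps the upper edge of each p-value bracket to an
    inclusion probability; brackets are half-open ``(lo, hi]`` scanned in
    order.  ``censor_fraction`` of the most extreme candidate effects are
    discarded outright.
    """

    level: str
    prob_rules: tuple[tuple[float, float], ...]
    censor_fraction: float = 0.10

    def probability(self, p_value: float) -> float:
        for edge, prob in self.prob_rules:
            if p_value <= edge:
                return prob
        return self.prob_rules[-1][1]


MILD_SELECTION = SelectionModel(
    level="mild", prob_rules=((0.05, 0.95), (0.5, 0.75), (1.0, 0.50))
)
SEVERE_SELECTION = SelectionModel(
    level="severe", prob_rules=((0.05, 0.95), (0.5, 0.50), (1.0, 0.25))
)

_SELECTION_BY_LEVEL: dict[str, Optional[SelectionModel]] = {
    "none": None,
    "mild": MILD_SELECTION,
    "severe": SEVERE_SELECTION,
}


def sample_log_total_size(
    rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray | float:
    """Draw ``ln(total size)`` values, Normal(6.049, 0.848^2)."""
    return rng.normal(LOG_SIZE_MEAN, LOG_SIZE_SD, size=size)


def sample_total_size(
    rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray | int:
    """Draw integer total study sizes (log-normal, rounded, floored at 10)."""
    n = np.rint(np.exp(sample_log_total_size(rng, size)))
    n = np.maximum(n, MIN_STUDY_SIZE).astype(int)
    return int(n) if size is None else n


def triangle_support(ratio: int) -> tuple[float, float, float]:
    """(low, mode, high) of the case-fraction triangular distribution."""
    mode = 1.0 / (1.0 + ratio)
    lo = max(0.05, mode - TRIANGLE_HALF_WIDTH)
    hi = min(0.95, mode + TRIANGLE_HALF_WIDTH)
    return lo, mode, hi


def sample_case_fraction(
    ratio: int, rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray | float:
    """Draw the case-arm fraction from the triangular distribution."""
    lo, mode, hi = triangle_support(ratio)
    return rng.triangular(lo, mode, hi, size=size)


def _split_arms(n_total: int, fraction: float) -> tuple[int, int]:
    n1 = int(round(fraction * n_total))
    n1 = min(max(n1, MIN_ARM_SIZE), n_total - MIN_ARM_SIZE)
    return n1, n_total - n1


def generate_study(
    scenario: Scenario, tau2: float, rng: np.random.Generator
) -> StudyDraw:
    """Draw one study under the scenario at between-study variance ``tau2``."""
    if tau2 < 0:
        raise ConfigError(f"tau2={tau2} must be non-negative")
    lo, hi = _REGIME_BOUNDS[scenario.event_regime]
    rate = rng.uniform(lo, hi)
    mu = float(logit(rate))
    theta_i = float(rng.normal(scenario.log_or, math.sqrt(tau2)))
    n_total = sample_total_size(rng)
    n1, n2 = _split_arms(n_total, float(sample_case_fraction(scenario.ratio, rng)))
    p1 = float(expit(mu + theta_i / 2.0))
    p2 = float(expit(mu - theta_i / 2.0))
    a = int(rng.binomial(n1, p1))
    b = int(rng.binomial(n2, p2))
    table = FourfoldTable(a, b, n1 - a, n2 - b)
    est = log_odds_ratio(table)
    z = est.theta / est.se
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return StudyDraw(
        n_total=n_total,
        n1=n1,
        n2=n2,
        mu=mu,
        theta_i=theta_i,
        p1=p1,
        p2=p2,
        table=table,
        theta_hat=est.theta,
        var_hat=est.var_asym,
        p_value=p_value,
    )


@dataclass(frozen=True)
class Calibration:
    """Pilot-batch quantities fixed before replicates are generated.

    ``s2_bar`` is the mean asymptotic logOR variance of ``pilot_size``
    studies generated at ``tau2 = 0``; ``tau2`` is the between-study
    variance implied by the scenario's I-squared target; the censor
    thresholds are deciles of the pilot theta-hat distribution used for
    the extreme-effect censoring step.
    """

    s2_bar: float
    tau2: float
    censor_low: float
    censor_high: float
    censor_center: float
    censor_abs_radius: float
    pilot_size: int = PILOT_SIZE


def calibrate_scenario(
    scenario: Scenario,
    rng: np.random.Generator,
    pilot_size: int = PILOT_SIZE,
) -> Calibration:
    """Run the pilot batch translating the I-squared target into ``tau2``.

    Also records the candidate theta-hat deciles that define "the 10 % most
    extreme effect sizes" for the censoring step of biased selection.
    """
    null_scenario = replace(scenario, bias="none")
    draws = [generate_study(null_scenario, 0.0, rng) for _ in range(pilot_size)]
    s2_bar = float(np.mean([d.var_hat for d in draws]))
    i2 = scenario.i2_target
    tau2 = s2_bar * i2 / (1.0 - i2)
    thetas = np.array([d.theta_hat for d in draws])
    frac = 0.10
    center = float(np.median(thetas))
    return Calibration(
        s2_bar=s2_bar,
        tau2=tau2,
        censor_low=float(np.quantile(thetas, frac)),
        censor_high=float(np.quantile(thetas, 1.0 - frac)),
        censor_center=center,
        censor_abs_radius=float(
            np.quantile(np.abs(thetas - center), 1.0 - frac)
        ),
        pilot_size=pilot_size,
    )


def resolve_tau2(
    scenario: Scenario,
    rng: np.random.Generator,
    pilot_size: int = PILOT_SIZE,
) -> float:
    """Between-study variance for the scenario's I-squared target,
    ``tau2 = s2_bar * I2 / (1 - I2)``."""
    return calibrate_scenario(scenario, rng, pilot_size).tau2


def inclusion_probability(
    p_value: float, model: Optional[SelectionModel]
) -> float:
    """Probability a study with this p-value is published and included."""
    if not 0.0 <= p_value <= 1.0:
        raise ConfigError(f"p-value {p_value} outside [0, 1]")
    if model is None:
        return 1.0
    return model.probability(p_value)


def _is_censored(
    theta_hat: float, calibration: Calibration, direction: CensorDirection
) -> bool:
    if direction == "low":
        return theta_hat <= calibration.censor_low
    if direction == "high":
        return theta_hat >= calibration.censor_high
    return abs(theta_hat - calibration.censor_center) >= calibration.censor_abs_radius


def generate_meta(
    scenario: Scenario,
    rng: np.random.Generator,
    calibration: Optional[Calibration] = None,
    return_draws: bool = False,
    max_candidates_per_study: int = 2000,
) -> MetaAnalysis | tuple[MetaAnalysis, list[StudyDraw]]:
    """Generate one meta-analysis of ``scenario.k`` studies.

    Without bias every candidate study is accepted.  With bias, candidates
    whose estimated effect falls in the censored extreme decile are
    discarded, and the rest are accepted with the p-value-bracket
    probability of the selection model; drawing continues until ``k``
    studies are accepted, preserving acceptance order.

    ``calibration`` may be precomputed (recommended when generating many
    replicates of one scenario); otherwise a pilot batch is run first,
    consuming draws from ``rng``.
    """
    if calibration is None:
        calibration = calibrate_scenario(scenario, rng)
    model = _SELECTION_BY_LEVEL[scenario.bias]
    accepted: list[StudyDraw] = []
    n_candidates = 0
    budget = max_candidates_per_study * scenario.k
    while len(accepted) < scenario.k:
        if n_candidates >= budget:
            rate = len(accepted) / max(n_candidates, 1)
            raise RunawaySelectionError(
                f"acceptance rate {rate:.2e} after {n_candidates} candidates"
            )
        draw = generate_study(scenario, calibration.tau2, rng)
        n_candidates += 1
        if model is not None:
            if _is_censored(
                draw.theta_hat, calibration, scenario.censor_direction
            ):
                continue
            if rng.uniform() > model.probability(draw.p_value):
                continue
        accepted.append(draw)
    meta = MetaAnalysis(tuple(d.table for d in accepted))
    if return_draws:
        return meta, accepted
    return meta
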