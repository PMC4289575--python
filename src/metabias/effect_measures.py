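"""Effect sizes and variance estimators for 2x2 exposure-by-status tables.

A case-control study with a binary exposure is summarised by the fourfold
table

    =========  ==========  =============
               Case group  Control group
    =========  ==========  =============
    Exposed        a            b
    Unexposed      c            d
    =========  ==========  =============

so the case arm has ``n1 = a + c`` subjects and the control arm has
``n2 = b + d``.  The package works on the log odds ratio scale,
``theta = ln(a d / (b c))``, whose usual asymptotic variance is
``1/a + 1/b + 1/c + 1/d``.

That asymptotic variance is intrinsically correlated with the estimated
log odds ratio itself, which is the root cause of spurious funnel-plot
asymmetry for binary outcomes.  The *smoothed variance* implemented here
replaces each study's observed cells by their expected values under the
exposure rates pooled over the whole meta-analysis:

    sv_i = 1 / (n1_i * p1 * (1 - p1)) + 1 / (n2_i * p2 * (1 - p2)),

with ``p1 = sum(a_i) / sum(n1_i)`` and ``p2 = sum(b_i) / sum(n2_i)``.
Within a given meta-analysis the pooled rates are constants, so a study's
smoothed variance depends on that study only through its arm sizes: the
exposure rates of the individual study do not affect it, and ranking
studies by smoothed precision is the same as ranking them by arm sizes.

The arcsine difference ``arcsin(sqrt(a/n1)) - arcsin(sqrt(b/n2))`` is also
provided; it is variance-stabilised (variance ``1/(4 n1) + 1/(4 n2)``) and
defined even for zero cells, so it never needs a continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

from .exceptions import DegenerateMetaError, InvalidTableError

ContinuityRule = Literal["haldane", "none"]

__all__ = [
    "FourfoldTable",
    "EffectEstimate",
    "SmoothedPrecision",
    "MetaAnalysis",
    "log_odds_ratio",
    "arcsine_difference",
    "smoothed_variance",
]


@dataclass(frozen=True)
class FourfoldTable:
    """One study's 2x2 exposure-by-status counts.

    Parameters
    ----------
    a, b, c, d
        Exposed cases, exposed controls, unexposed cases, unexposed
        controls.  Counts must be non-negative integers and both arms
        (``n1 = a + c``, ``n2 = b + d``) must contain at least one subject.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, int):
                raise InvalidTableError(
                    f"cell {name}={value!r} is not an integer count"
                )
            if value < 0:
                raise InvalidTableError(f"cell {name}={value} is negative")
        if self.n1 == 0 or self.n2 == 0:
            raise InvalidTableError(
                f"empty arm: n1={self.n1}, n2={self.n2} (need n1 >= 1 and n2 >= 1)"
            )

    @property
    def n1(self) -> int:
        """Case-arm size ``a + c``."""
        return self.a + self.c

    @property
    def n2(self) -> int:
        """Control-arm size ``b + d``."""
        return self.b + self.d

    @property
    def n(self) -> int:
        """Total study size."""
        return self.n1 + self.n2

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def flipped_exposure(self) -> "FourfoldTable":
        """Swap the exposed/unexposed labels (a<->c, b<->d)."""
        return FourfoldTable(self.c, self.d, self.a, self.b)

    def corrected_cells(self, rule: ContinuityRule = "haldane") -> tuple[float, float, float, float]:
        """Cells after the continuity rule.

        The Haldane-Anscombe rule adds 0.5 to all four cells of a table
        containing any zero cell; tables without zeros are untouched.
        """
        if rule == "haldane" and self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass(frozen=True)
class EffectEstimate:
    """An effect value with its asymptotic variance.

    ``theta`` is the effect on the chosen scale (log odds ratio or arcsine
    difference), ``var_asym`` its asymptotic variance and ``se`` the square
    root.  ``corrected`` records whether a continuity correction was used.
    """

    theta: float
    var_asym: float
    measure: str
    corrected: bool = False
    se: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.var_asym > 0:
            raise InvalidTableError(f"non-positive variance {self.var_asym}")
        object.__setattr__(self, "se", math.sqrt(self.var_asym))


@dataclass(frozen=True)
class SmoothedPrecision:
    """Smoothed variance of one study under the meta-analysis pooled rates."""

    sv: float
    pooled_rate_cases: float
    pooled_rate_controls: float
    se_smooth: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.sv > 0:
            raise DegenerateMetaError(f"non-positive smoothed variance {self.sv}")
        for r in (self.pooled_rate_cases, self.pooled_rate_controls):
            if not 0.0 < r < 1.0:
                raise DegenerateMetaError(f"pooled rate {r} outside (0, 1)")
        object.__setattr__(self, "se_smooth", math.sqrt(self.sv))


@dataclass(frozen=True)
class MetaAnalysis:
    """An ordered collection of studies.

    ``study_ids`` are optional free-text labels; defaults are ``study_1``,
    ``study_2``, ...
    """

    studies: tuple[FourfoldTable, ...]
    study_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        studies = tuple(self.studies)
        object.__setattr__(self, "studies", studies)
        if len(studies) < 1:
            raise InvalidTableError("a meta-analysis needs at least one study")
        ids = tuple(self.study_ids) or tuple(
            f"study_{i + 1}" for i in range(len(studies))
        )
        if len(ids) != len(studies):
            raise InvalidTableError(
                f"{len(ids)} study ids for {len(studies)} studies"
            )
        object.__setattr__(self, "study_ids", ids)

    @property
    def k(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[FourfoldTable]:
        return iter(self.studies)

    def __len__(self) -> int:
        return self.k

    def flipped_exposure(self) -> "MetaAnalysis":
        return MetaAnalysis(
            tuple(t.flipped_exposure() for t in self.studies), self.study_ids
        )

    @classmethod
    def from_counts(
        cls,
        rows: Iterable[Sequence[int]],
        study_ids: Sequence[str] = (),
    ) -> "MetaAnalysis":
        """Build from an iterable of (a, b, c, d) rows."""
        return cls(
            tuple(FourfoldTable(*row) for row in rows), tuple(study_ids)
        )


def log_odds_ratio(
    table: FourfoldTable, correction: ContinuityRule = "haldane"
) -> EffectEstimate:
    """Log odds ratio and its asymptotic variance.

    With the default ``"haldane"`` rule, 0.5 is added to every cell of a
    table containing a zero before computing ``ln(ad/bc)`` and
    ``1/a + 1/b + 1/c + 1/d``; with ``"none"`` a zero cell raises
    :class:`InvalidTableError`.
    """
    a, b, c, d = table.corrected_cells(correction)
    if min(a, b, c, d) <= 0:
        raise InvalidTableError(
            f"zero cell in {table} with continuity rule 'none'"
        )
    theta = math.log(a * d / (b * c))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(
        theta=theta,
        var_asym=var,
        measure="logOR",
        corrected=table.has_zero_cell and correction == "haldane",
    )


def arcsine_difference(table: FourfoldTable) -> EffectEstimate:
    """Arcsine difference of the exposure proportions.

    ``theta = arcsin(sqrt(a/n1)) - arcsin(sqrt(b/n2))`` with variance
    ``1/(4 n1) + 1/(4 n2)``; well defined for zero cells.
    """
    theta = math.asin(math.sqrt(table.a / table.n1)) - math.asin(
        math.sqrt(table.b / table.n2)
    )
    var = 0.25 / table.n1 + 0.25 / table.n2
    return EffectEstimate(theta=theta, var_asym=var, measure="arcsine")


def pooled_exposure_rates(meta: MetaAnalysis) -> tuple[float, float]:
    """Exposure proportions pooled over all studies, per arm.

    Returns ``(p1, p2)`` where ``p1 = sum(a_i)/sum(n1_i)`` and
    ``p2 = sum(b_i)/sum(n2_i)``.  If a pooled margin is zero (no exposed or
    no unexposed subject in an arm across the whole meta-analysis), 0.5 is
    added to each pooled cell of that arm so the rates stay inside (0, 1).
    """
    sum_a = sum(t.a for t in meta)
    sum_c = sum(t.c for t in meta)
    sum_b = sum(t.b for t in meta)
    sum_d = sum(t.d for t in meta)
    if sum_a == 0 or sum_c == 0:
        p1 = (sum_a + 0.5) / (sum_a + sum_c + 1.0)
    else:
        p1 = sum_a / (sum_a + sum_c)
    if sum_b == 0 or sum_d == 0:
        p2 = (sum_b + 0.5) / (sum_b + sum_d + 1.0)
    else:
        p2 = sum_b / (sum_b + sum_d)
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise DegenerateMetaError(
            f"pooled exposure rates ({p1}, {p2}) outside (0, 1)"
        )
    return p1, p2


def smoothed_variance(meta: MetaAnalysis) -> list[SmoothedPrecision]:
    """Smoothed variance of the log odds ratio for every study.

    Equivalent to the asymptotic logOR variance with each study's cells
    replaced by their expected values under the pooled exposure rates:
    ``sv_i = 1/(n1_i p1 (1-p1)) + 1/(n2_i p2 (1-p2))``.
    """
    p1, p2 = pooled_exposure_rates(meta)
    q1 = p1 * (1.0 - p1)
    q2 = p2 * (1.0 - p2)
    return [
        SmoothedPrecision(
            sv=1.0 / (t.n1 * q1) + 1.0 / (t.n2 * q2),
            pooled_rate_cases=p1,
            pooled_rate_controls=p2,
        )
        for t in meta
    ]
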