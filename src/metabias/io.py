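"""Reading and writing study data and results.

The single input dialect is a UTF-8 comma-delimited file with header
``study,a,b,c,d`` — one row per study in the exposure-by-status
orientation (``a`` exposed cases, ``b`` exposed controls, ``c`` unexposed
cases, ``d`` unexposed controls).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bias_tests import TestResult
from .effect_measures import (
    FourfoldTable,
    MetaAnalysis,
    arcsine_difference,
    log_odds_ratio,
    smoothed_variance,
)
from .exceptions import ValidationError
from .simulator import Scenario, generate_meta

__all__ = [
    "read_meta_csv",
    "write_meta_csv",
    "results_to_frame",
    "write_results",
    "funnel_coordinates",
    "make_fixture",
    "FIXTURE_PROFILES",
]

REQUIRED_COLUMNS = ("study", "a", "b", "c", "d")


def read_meta_csv(path: str | Path) -> MetaAnalysis:
    """Read a meta-analysis from a ``study,a,b,c,d`` CSV file.

    Counts must be non-negative integers; a malformed row raises
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise ValidationError(f"{path}: no study rows")
    tables = []
    ids = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        cells = []
        for col in ("a", "b", "c", "d"):
            value = getattr(row, col)
            try:
                as_float = float(value)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {row_number}: {col}={value!r} is not a number"
                ) from None
            if not as_float.is_integer():
                raise ValidationError(
                    f"{path}: row {row_number}: {col}={value!r} is not an integer"
                )
            if as_float < 0:
                raise ValidationError(
                    f"{path}: row {row_number}: {col}={value!r} is negative"
                )
            cells.append(int(as_float))
        try:
            tables.append(FourfoldTable(*cells))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row_number}: {exc}") from exc
        ids.append(str(row.study))
    return MetaAnalysis(tuple(tables), tuple(ids))


def write_meta_csv(meta: MetaAnalysis, path: str | Path) -> Path:
    """Write a meta-analysis in the same CSV schema; inverse of
    :func:`read_meta_csv`."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "study": list(meta.study_ids),
            "a": [t.a for t in meta],
            "b": [t.b for t in meta],
            "c": [t.c for t in meta],
            "d": [t.d for t in meta],
        }
    )
    frame.to_csv(path, index=False)
    return path


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Long-format table of test results (one row per method)."""
    return pd.DataFrame(
        {
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df if r.df is not None else np.nan for r in results],
            "p_value": [r.p_value for r in results],
            "n_studies": [r.n_studies for r in results],
            "applicable": [r.applicable for r in results],
            "message": [r.message for r in results],
        }
    )


def provenance_block(seed: Optional[int], config: dict) -> dict:
    """Provenance metadata (version + seed + config echo) for outputs."""
    return {"package": "metabias", "version": __version__, "seed": seed, "config": config}


def write_results(
    results: Sequence[TestResult],
    path: str | Path,
    fmt: str = "csv",
    provenance: Optional[dict] = None,
) -> Path:
    """Write test results as CSV or JSON (6 significant digits)."""
    path = Path(path)
    frame = results_to_frame(results)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.6g")
        if provenance is not None:
            side = path.with_suffix(path.suffix + ".provenance.json")
            side.write_text(json.dumps(provenance, indent=2, default=str))
    elif fmt == "json":
        payload = {"results": frame.to_dict(orient="records")}
        if provenance is not None:
            payload["provenance"] = provenance
        path.write_text(json.dumps(payload, indent=2, default=str))
    else:
        raise ValidationError(f"unknown output format {fmt!r}")
    return path


def funnel_coordinates(
    meta: MetaAnalysis, precision: str = "asymptotic"
) -> pd.DataFrame:
    """Per-study (theta, se) pairs for external funnel plotting.

    ``precision`` selects the standard-error scale: ``"asymptotic"``
    (from the continuity-corrected logOR variance), ``"smoothed"`` (from
    the smoothed variance) or ``"arcsine"``.
    """
    if precision == "asymptotic":
        ests = [log_odds_ratio(t) for t in meta]
        theta = [e.theta for e in ests]
        se = [e.se for e in ests]
    elif precision == "smoothed":
        theta = [log_odds_ratio(t).theta for t in meta]
        se = [p.se_smooth for p in smoothed_variance(meta)]
    elif precision == "arcsine":
        ests = [arcsine_difference(t) for t in meta]
        theta = [e.theta for e in ests]
        se = [e.se for e in ests]
    else:
        raise ValidationError(f"unknown precision scale {precision!r}")
    return pd.DataFrame(
        {"study": list(meta.study_ids), "theta": theta, "se": se}
    )


#: Named fixture profiles: deterministic simulated meta-analyses for tests
#: and documentation. All are synthetic.
FIXTURE_PROFILES: dict[str, Scenario] = {
    "null-meta": Scenario(k=20, or_true=1.0, event_regime="common", i2_target=0.01, ratio=1, bias="none"),
    "biased-meta": Scenario(k=30, or_true=1.6, event_regime="common", i2_target=0.50, ratio=1, bias="severe"),
    "rare-event-meta": Scenario(k=20, or_true=1.4, event_regime="rare", i2_target=0.25, ratio=3, bias="none"),
}


def make_fixture(name: str, seed: int, outdir: str | Path) -> Path:
    """Generate a named deterministic CSV fixture via the simulator.

    Profiles: ``null-meta`` (no bias, OR 1), ``biased-meta`` (severe
    selection, OR 1.6, moderate heterogeneity), ``rare-event-meta``
    (rare events, 1:3 arms) and ``equal-size-meta`` (all studies share
    the same arm sizes, so the smoothed standard error is constant and
    SVE/SVT report not-applicable by construction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.csv"
    rng = np.random.default_rng(seed)
    if name == "equal-size-meta":
        n1 = n2 = 100
        tables = []
        for _ in range(10):
            a = int(rng.binomial(n1, 0.4))
            b = int(rng.binomial(n2, 0.4))
            tables.append(FourfoldTable(a, b, n1 - a, n2 - b))
        meta = MetaAnalysis(tuple(tables))
    elif name in FIXTURE_PROFILES:
        meta = generate_meta(FIXTURE_PROFILES[name], rng)
    else:
        raise ValidationError(
            f"unknown fixture profile {name!r}; choose from "
            f"{sorted(FIXTURE_PROFILES) + ['equal-size-meta']}"
        )
    return write_meta_csv(meta, path)
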