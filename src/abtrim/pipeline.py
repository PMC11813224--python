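"""End-to-end orchestration: read or simulate coproduct tables, calibrate,
infer pools/efficiencies/ratios, QC, and compare variants statistically.

CSV dialect (UTF-8, "." decimal): ND cells are "NA", censored cells are
"CENSORED<limit>".  Measurement tables are tidy, one row per
(variant, replicate, channel, coproduct), carrying either a
``concentration_nM`` column or raw ``analyte_response`` /
``internal_standard_response`` columns to be calibrated against a
standards table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats

from . import __version__
from .datasets import scenario as _get_scenario
from .datasets import table1_fixture
from .kinetics import KineticParams, simulate_replicates
from .pathway import (
    CoproductTable,
    PathwayGraph,
    PoolTable,
    default_graph,
    pools_from_coproducts,
    qc_report,
)
from .quantify import StandardCurve, fit_standard_curve, internal_standard_ratio, invert_curve
from .values import ND, Value, format_value, is_nd, is_numeric, parse_value

__all__ = [
    "ConfigError",
    "RunConfig",
    "ComparisonResult",
    "compare_groups",
    "load_measurements",
    "load_standards",
    "write_tables",
    "run",
]

logger = logging.getLogger("abtrim")


class ConfigError(ValueError):
    """Invalid configuration or input schema (CLI exit code 1)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one pipeline run."""

    mode: str  # "measured" | "simulate" | "fixture"
    measurements_path: Optional[str] = None
    standards_path: Optional[str] = None
    pathway_path: Optional[str] = None
    scenario: Optional[str] = None
    params: Mapping = field(default_factory=dict)
    reference: Optional[str] = None
    test: str = "student"
    alpha: float = 0.05
    efficiency_aggregation: str = "per_replicate"  # or "pooled"
    out_dir: Optional[str] = None
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("measured", "simulate", "fixture"):
            raise ConfigError(f"mode must be measured/simulate/fixture, got {self.mode!r}")
        if self.mode == "measured" and not self.measurements_path:
            raise ConfigError("measured mode requires measurements_path")
        if self.mode == "simulate" and not (self.scenario or self.params):
            raise ConfigError("simulate mode requires a scenario name or kinetic params")
        if self.test not in ("student", "welch"):
            raise ConfigError(f"test must be 'student' or 'welch', got {self.test!r}")
        if self.efficiency_aggregation not in ("per_replicate", "pooled"):
            raise ConfigError("efficiency_aggregation must be per_replicate or pooled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def graph(self) -> PathwayGraph:
        if self.pathway_path:
            return PathwayGraph.from_yaml(self.pathway_path)
        return default_graph()


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_CHANNELS = ("light", "heavy")


def load_standards(path) -> dict[str, list[tuple[float, float]]]:
    """Read a standards table into per-analyte (concentration, ratio) points."""
    frame = _read_csv(path)
    required = {"analyte", "concentration_nM", "analyte_response", "internal_standard_response"}
    _require_columns(frame, required, path)
    points: dict[str, list[tuple[float, float]]] = {}
    for i, row in frame.iterrows():
        try:
            ratio = internal_standard_ratio(
                float(row["analyte_response"]), float(row["internal_standard_response"])
            )
            conc = float(row["concentration_nM"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: bad standards row {i}: {exc}") from exc
        points.setdefault(str(row["analyte"]), []).append((conc, ratio))
    return points


def load_measurements(
    path,
    graph: Optional[PathwayGraph] = None,
    curves: Optional[Mapping[str, StandardCurve]] = None,
) -> list[CoproductTable]:
    """Read a tidy measurement table into CoproductTables.

    With a ``concentration_nM`` column, values are taken as calibrated.
    With raw response columns, ``curves`` (one StandardCurve per analyte)
    is required to convert response ratios to concentrations.
    """
    graph = graph or default_graph()
    frame = _read_csv(path)
    base = {"variant", "replicate", "channel", "coproduct"}
    _require_columns(frame, base, path)

    raw_mode = "concentration_nM" not in frame.columns
    if raw_mode:
        _require_columns(
            frame, base | {"analyte_response", "internal_standard_response"}, path
        )
        if curves is None:
            raise ConfigError(
                f"{path}: raw-response measurements need a standards table for calibration"
            )

    known = set(graph.coproduct_ids)
    grouped: dict[tuple[str, int, str], dict[str, Value]] = {}
    for i, row in frame.iterrows():
        coproduct = str(row["coproduct"])
        if coproduct not in known:
            raise ConfigError(f"{path}: row {i}: unknown coproduct {coproduct!r}")
        channel = str(row["channel"])
        if channel not in _CHANNELS:
            raise ConfigError(f"{path}: row {i}: channel must be light/heavy, got {channel!r}")
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            raise ConfigError(f"{path}: row {i}: replicate must be an integer") from None
        if raw_mode:
            curve = curves.get(coproduct) if curves else None
            if curve is None:
                raise ConfigError(f"{path}: row {i}: no standard curve for {coproduct!r}")
            ratio = internal_standard_ratio(
                float(row["analyte_response"]), float(row["internal_standard_response"])
            )
            value: Value = invert_curve(curve, ratio)
        else:
            try:
                value = parse_value(str(row["concentration_nM"]))
            except ValueError as exc:
                raise ConfigError(f"{path}: row {i}: column concentration_nM: {exc}") from exc
        grouped.setdefault((str(row["variant"]), replicate, channel), {})[coproduct] = value

    tables = []
    for (variant, replicate, channel), values in grouped.items():
        missing = known - set(values)
        if missing:
            raise ConfigError(
                f"{path}: {variant} replicate {replicate} ({channel}) is missing "
                f"coproducts {sorted(missing)}"
            )
        tables.append(
            CoproductTable(variant=variant, values=values, replicate=replicate, channel=channel)
        )
    tables.sort(key=lambda t: (t.variant, t.replicate, t.channel))
    return tables


def write_measurements(tables: Sequence[CoproductTable], path) -> None:
    """Write CoproductTables in the same tidy dialect load_measurements reads."""
    rows = [
        {
            "variant": t.variant,
            "replicate": t.replicate,
            "channel": t.channel,
            "coproduct": coproduct,
            "concentration_nM": format_value(value),
        }
        for t in tables
        for coproduct, value in sorted(t.values.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, dtype=str).fillna("NA")
    except Exception as exc:
        raise ConfigError(f"cannot parse CSV {path}: {exc}") from exc


def _require_columns(frame: pd.DataFrame, required: set, path) -> None:
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: missing required columns {sorted(missing)}")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """Unpaired two-tailed t-test of one quantity, variant vs. reference."""

    quantity: str
    variant: str
    reference: str
    mean_a: Value
    mean_b: Value
    sd_a: Value
    sd_b: Value
    n_a: int
    n_b: int
    n_excluded: int
    t_statistic: Value
    p_value: Value
    stars: str
    reason: str = ""


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_a: Sequence[Value],
    values_b: Sequence[Value],
    test: str = "student",
    quantity: str = "",
    variant: str = "",
    reference: str = "",
) -> ComparisonResult:
    """Unpaired two-tailed t-test (Student pooled-variance; Welch optional).

    ND and censored observations are excluded (and counted); fewer than two
    numeric observations in either group yields an ND result with a reason.
    """
    if test not in ("student", "welch"):
        raise ConfigError(f"unknown test {test!r}")
    a = [float(v) for v in values_a if is_numeric(v)]
    b = [float(v) for v in values_b if is_numeric(v)]
    excluded = (len(values_a) - len(a)) + (len(values_b) - len(b))

    def _summary(xs):
        if not xs:
            return ND, ND
        mean = float(np.mean(xs))
        sd = float(np.std(xs, ddof=1)) if len(xs) > 1 else ND
        return mean, sd

    mean_a, sd_a = _summary(a)
    mean_b, sd_b = _summary(b)
    common = dict(
        quantity=quantity,
        variant=variant,
        reference=reference,
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        n_a=len(a),
        n_b=len(b),
        n_excluded=excluded,
    )
    if len(a) < 2 or len(b) < 2:
        return ComparisonResult(
            t_statistic=ND, p_value=ND, stars="", reason="fewer than 2 numeric values in a group", **common
        )
    result = _scipy_stats.ttest_ind(a, b, equal_var=(test == "student"))
    t_stat, p_value = float(result.statistic), float(result.pvalue)
    if math.isnan(t_stat):  # zero variance in both groups, identical means
        t_stat, p_value = 0.0, 1.0
    return ComparisonResult(
        t_statistic=t_stat, p_value=p_value, stars=_stars(p_value), **common
    )


# ---------------------------------------------------------------------------
# Tidy output frames
# ---------------------------------------------------------------------------


def _flags_for(table: PoolTable, target: str) -> str:
    codes = sorted(f.code.value for f in table.flags if f.target == target)
    return ";".join(codes)


def pools_frame(tables: Sequence[PoolTable]) -> pd.DataFrame:
    rows = []
    for table in tables:
        for species, value in table.pools.items():
            rows.append(
                {
                    "variant": table.variant,
                    "replicate": table.replicate,
                    "species": species,
                    "value": format_value(value),
                    "status": "ND" if is_nd(value) else "OK",
                    "flags": _flags_for(table, species),
                }
            )
        ratio = table.ratio_42_40
        rows.append(
            {
                "variant": table.variant,
                "replicate": table.replicate,
                "species": "Aβ42/Aβ40",
                "value": format_value(ratio),
                "status": "ND" if is_nd(ratio) else "OK",
                "flags": "",
            }
        )
    return pd.DataFrame(rows)


def efficiencies_frame(tables: Sequence[PoolTable]) -> pd.DataFrame:
    rows = [
        {
            "variant": table.variant,
            "replicate": table.replicate,
            "step": step,
            "value": format_value(value),
            "status": "ND" if is_nd(value) else "OK",
            "flags": _flags_for(table, step),
        }
        for table in tables
        for step, value in table.efficiencies.items()
    ]
    return pd.DataFrame(rows)


def _stats_frame(
    pool_tables: Sequence[PoolTable], reference: str, test: str
) -> pd.DataFrame:
    by_variant: dict[str, list[PoolTable]] = {}
    for table in pool_tables:
        by_variant.setdefault(table.variant, []).append(table)
    if reference not in by_variant:
        raise ConfigError(f"reference variant {reference!r} not present in the data")

    def _collect(tables: Sequence[PoolTable], kind: str, key: str) -> list[Value]:
        if kind == "pool":
            return [t.pools.get(key, ND) for t in tables]
        if kind == "efficiency":
            return [t.efficiencies.get(key, ND) for t in tables]
        return [t.ratio_42_40 for t in tables]

    quantities: list[tuple[str, str]] = []
    sample = by_variant[reference][0]
    quantities += [("pool", s) for s in sample.pools]
    quantities += [("efficiency", s) for s in sample.efficiencies]
    quantities += [("ratio", "Aβ42/Aβ40")]

    rows = []
    ref_tables = by_variant[reference]
    for variant in sorted(by_variant):
        if variant == reference:
            continue
        for kind, key in quantities:
            result = compare_groups(
                _collect(by_variant[variant], kind, key),
                _collect(ref_tables, kind, key),
                test=test,
                quantity=f"{kind}:{key}",
                variant=variant,
                reference=reference,
            )
            rows.append(
                {
                    "quantity": result.quantity,
                    "variant": result.variant,
                    "reference": result.reference,
                    "mean_variant": format_value(result.mean_a),
                    "sd_variant": format_value(result.sd_a),
                    "n_variant": result.n_a,
                    "mean_reference": format_value(result.mean_b),
                    "sd_reference": format_value(result.sd_b),
                    "n_reference": result.n_b,
                    "n_excluded": result.n_excluded,
                    "t": format_value(result.t_statistic),
                    "p": format_value(result.p_value),
                    "stars": result.stars,
                    "reason": result.reason,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _kinetic_params(config: RunConfig) -> KineticParams:
    if config.scenario:
        params = _get_scenario(config.scenario).params
        if config.params:
            params = replace(params, **dict(config.params))
    else:
        try:
            params = KineticParams(**dict(config.params))
        except TypeError as exc:
            raise ConfigError(f"bad kinetic params: {exc}") from exc
    if config.seed is not None:
        params = replace(params, seed=int(config.seed))
    return params


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the report bundle (tidy DataFrames).

    Deterministic given (inputs, config, seed).  If ``config.out_dir`` is
    set, writes pools.csv, efficiencies.csv, qc.csv, stats.csv and
    manifest.json there; nothing is written before all stages succeed.
    """
    logging.basicConfig(level=config.log_level)
    graph = config.graph()

    if config.mode == "simulate":
        params = _kinetic_params(config)
        logger.info("simulating %d replicates for variant %s", params.n_replicates, params.variant)
        coproduct_tables = simulate_replicates(params, graph)
    elif config.mode == "measured":
        curves = None
        if config.standards_path:
            logger.info("fitting standard curves from %s", config.standards_path)
            standards = load_standards(config.standards_path)
            curves = {
                analyte: fit_standard_curve(points, analyte=analyte)
                for analyte, points in standards.items()
            }
        coproduct_tables = load_measurements(config.measurements_path, graph, curves)
        logger.info("loaded %d coproduct tables", len(coproduct_tables))
    else:  # fixture
        from .datasets import implied_coproducts

        coproduct_tables = [implied_coproducts(t, graph) for t in table1_fixture(graph)]

    logger.info("inverting mass balance for %d tables", len(coproduct_tables))
    pool_tables = [pools_from_coproducts(t, graph) for t in coproduct_tables]

    if config.efficiency_aggregation == "pooled":
        pool_tables = _pooled_efficiencies(coproduct_tables, pool_tables, graph)

    bundle = {
        "pool_tables": pool_tables,
        "pools": pools_frame(pool_tables),
        "efficiencies": efficiencies_frame(pool_tables),
        "qc": qc_report(pool_tables),
        "stats": pd.DataFrame(),
        "manifest": _manifest(config),
    }
    if config.reference:
        bundle["stats"] = _stats_frame(pool_tables, config.reference, config.test)

    if config.out_dir:
        write_tables(bundle, config.out_dir)
    return bundle


def _pooled_efficiencies(
    coproduct_tables: Sequence[CoproductTable],
    pool_tables: Sequence[PoolTable],
    graph: PathwayGraph,
) -> list[PoolTable]:
    """Recompute efficiencies from replicate-mean coproducts per variant."""
    from .pathway import step_efficiencies

    by_variant: dict[str, list[CoproductTable]] = {}
    for table in coproduct_tables:
        by_variant.setdefault(table.variant, []).append(table)
    pooled: dict[str, Mapping[str, Value]] = {}
    for variant, tables in by_variant.items():
        means: dict[str, Value] = {}
        for coproduct in graph.coproduct_ids:
            numeric = [float(t.values[coproduct]) for t in tables if is_numeric(t.values[coproduct])]
            means[coproduct] = float(np.mean(numeric)) if numeric else ND
        pooled[variant] = step_efficiencies(
            CoproductTable(variant=variant, values=means), graph
        )
    return [replace(t, efficiencies=pooled[t.variant]) for t in pool_tables]


def _manifest(config: RunConfig) -> dict:
    payload = {k: getattr(config, k) for k in config.__dataclass_fields__}
    payload["params"] = dict(payload["params"])
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"config": payload, "config_sha256": digest, "seed": config.seed, "version": __version__}


def write_tables(bundle: Mapping, out_dir) -> None:
    """Write the report bundle as UTF-8 CSVs plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("pools", "efficiencies", "qc", "stats"):
        bundle[name].to_csv(out / f"{name}.csv", index=False, encoding="utf-8")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["manifest"], fh, indent=2, default=str)
    logger.info("wrote report bundle to %s", out)
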