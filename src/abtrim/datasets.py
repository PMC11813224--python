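"""Packaged fixtures and named simulation scenarios.

Ships the published per-variant Aβ pool table (wild-type enzyme in the
light and heavy isotope channels plus six PSEN1 FAD mutants) as the
ground-truth fixture, derives the coproduct tables it implies via the
forward suffix-sum map, and defines qualitative kinetic scenarios that
mirror the observed mutant phenotypes for tests and documentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .kinetics import KineticParams
from .pathway import (
    CoproductTable,
    PathwayGraph,
    PoolTable,
    default_graph,
    pools_from_coproducts,
)
from .values import ND, Censored, Value, is_nd, parse_value

__all__ = [
    "AICD_LOWEST_STANDARD_NM",
    "Scenario",
    "table1_fixture",
    "implied_coproducts",
    "scenario",
    "scenario_names",
]

#: Lowest AICD calibration standard (nM); the censoring limit for
#: endoproteolysis coproducts that could not be quantified.
AICD_LOWEST_STANDARD_NM = 62.5


def _load_pool_rows() -> list[tuple[str, dict[str, Value]]]:
    ref = resources.files("abtrim") / "data" / "table1.csv"
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = []
        for record in reader:
            variant = record.pop("variant")
            pools = {species: parse_value(token) for species, token in record.items()}
            rows.append((variant, pools))
    return rows


def implied_coproducts(
    pool_table: PoolTable,
    graph: Optional[PathwayGraph] = None,
    floor: float = AICD_LOWEST_STANDARD_NM,
) -> CoproductTable:
    """Coproduct table implied by a pool row via the forward suffix-sum map.

    Any suffix sum that touches an ND pool (an endoproteolysis product that
    fell below the lowest standard) is emitted as Censored(floor) instead of
    a number.  The result is the canonical test input for the mass-balance
    inversion: inverting it reproduces the pool row.
    """
    graph = graph or default_graph()
    values: dict[str, Value] = {}
    for branch in graph.branches:
        suffix = 0.0
        saw_nd = False
        for step in reversed(branch.steps):
            pool = pool_table.pools[step.product]
            if is_nd(pool):
                saw_nd = True
            else:
                suffix += float(pool)
            values[step.coproduct] = Censored(floor) if saw_nd else suffix
    return CoproductTable(variant=pool_table.variant, values=values)


def table1_fixture(graph: Optional[PathwayGraph] = None) -> list[PoolTable]:
    """The eight published per-variant pool rows, as full PoolTables.

    Pools are exactly as printed (ND cells preserved); efficiencies, the
    Aβ42/Aβ40 ratio and QC flags are derived by round-tripping each row
    through the forward map and the mass-balance inversion.
    """
    graph = graph or default_graph()
    tables = []
    for variant, pools in _load_pool_rows():
        printed = PoolTable(variant=variant, pools=pools)
        derived = pools_from_coproducts(implied_coproducts(printed, graph), graph)
        tables.append(derived)
    return tables


@dataclass(frozen=True)
class Scenario:
    """A named parameter set mirroring a qualitative enzyme phenotype."""

    name: str
    params: KineticParams
    rationale: str


_TRIM_STEPS_40 = ("Aβ49→Aβ46", "Aβ46→Aβ43", "Aβ43→Aβ40")
_TRIM_STEPS_42 = ("Aβ48→Aβ45", "Aβ45→Aβ42", "Aβ42→Aβ38")

# Wild-type continuation probabilities, chosen to match the per-step
# efficiencies implied by the published WT-L pool row (≈90/60/66% on the
# Aβ40 branch, ≈76/63/13% on the Aβ42 branch).
_WT_Q = {
    "Aβ49→Aβ46": 0.90,
    "Aβ46→Aβ43": 0.60,
    "Aβ43→Aβ40": 0.66,
    "Aβ48→Aβ45": 0.76,
    "Aβ45→Aβ42": 0.63,
    "Aβ42→Aβ38": 0.13,
}


def _build_scenarios() -> dict[str, Scenario]:
    base = dict(enzyme_conc=30.0, time=16.0, noise_cv=0.1, n_replicates=4)
    scenarios = {}

    scenarios["wt"] = Scenario(
        name="wt",
        params=KineticParams(
            kcat=2.0, branch_p49=0.5, continue_prob=dict(_WT_Q), variant="wt", **base
        ),
        rationale=(
            "Wild-type enzyme: nominal turnover (2 hr⁻¹), balanced branch "
            "choice, efficient early trimming."
        ),
    )

    scenarios["endo_deficient"] = Scenario(
        name="endo_deficient",
        params=KineticParams(
            kcat=0.4,
            branch_p49=0.4,
            continue_prob=dict(_WT_Q),
            variant="endo_deficient",
            **base,
        ),
        rationale=(
            "Endoproteolysis-deficient mutant (S169L/S170F/G378E-like): the "
            "initial ε cut is 5-fold slower, trimming probabilities normal, "
            "so all coproducts scale down together."
        ),
    )

    f386s_q = dict(_WT_Q)
    f386s_q["Aβ43→Aβ40"] = 0.20  # Aβ43 buildup
    f386s_q["Aβ48→Aβ45"] = 0.30  # Aβ48 buildup
    f386s_q["Aβ45→Aβ42"] = 0.35
    f386s_q["Aβ42→Aβ38"] = 0.08
    scenarios["f386s_like"] = Scenario(
        name="f386s_like",
        params=KineticParams(
            kcat=2.0,
            branch_p49=0.35,
            continue_prob=f386s_q,
            variant="f386s_like",
            **base,
        ),
        rationale=(
            "Trimming-deficient mutant with intact endoproteolysis "
            "(F386S-like): normal kcat, branch choice shifted toward Aβ48, "
            "deficient Aβ43→Aβ40 and Aβ48→Aβ45 steps → Aβ43 and Aβ48 pile up."
        ),
    )

    scenarios["palp_like"] = Scenario(
        name="palp_like",
        params=KineticParams(
            kcat=0.05,
            branch_p49=0.4,
            continue_prob=dict(_WT_Q),
            detection_floor=AICD_LOWEST_STANDARD_NM,
            variant="palp_like",
            **base,
        ),
        rationale=(
            "Near-null PALP-motif mutant (A431E/A434T-like): turnover reduced "
            "40-fold, so endoproteolysis coproducts fall below the 62.5 nM "
            "lowest standard and are censored."
        ),
    )
    return scenarios


_SCENARIOS = _build_scenarios()


def scenario_names() -> tuple[str, ...]:
    return tuple(sorted(_SCENARIOS))


def scenario(name: str) -> Scenario:
    """Look up a named scenario; unknown names list the available ones."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None
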