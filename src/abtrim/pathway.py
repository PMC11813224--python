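"""Branched processive-proteolysis topology and mass-balance maps.

γ-secretase processes the APP C-terminal fragment C99 by an initial
endoproteolytic (ε) cut followed by carboxypeptidase trimming of the long
Aβ intermediate, along one of two branches::

    C99 → Aβ49 → Aβ46 → Aβ43 → Aβ40   (coproducts AICD 50–99, ITL, VIV, IAT)
    C99 → Aβ48 → Aβ45 → Aβ42 → Aβ38   (coproducts AICD 49–99, VIT, TVI, VVIA)

Each cleavage releases a coproduct (an AICD for the ε cut, a tri- or
tetrapeptide for the trimming cuts) whose concentration counts the cleavage
events of that step.  The net pool of an intermediate Aβx at assay end is
therefore

    [Aβx] = [coproduct of the step producing Aβx] − [coproduct of the step
            consuming Aβx]

and, conversely, the coproduct of step *i* of a branch equals the suffix sum
of the pools of the step-*i* product and everything downstream of it.  The
forward map is unitriangular, so the inversion is exact; negative pools are
physically impossible and are preserved (not clipped) as a QC signal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Optional, Sequence

import yaml

from .values import ND, Value, is_censored, is_nd, is_numeric

__all__ = [
    "CleavageStep",
    "Branch",
    "PathwayGraph",
    "CoproductTable",
    "PoolTable",
    "QCCode",
    "QCFlag",
    "default_graph",
    "coproducts_from_pools",
    "pools_from_coproducts",
    "step_efficiencies",
    "ab42_ab40_ratio",
    "qc_report",
]


@dataclass(frozen=True)
class CleavageStep:
    """One proteolytic event: precursor → product + coproduct."""

    precursor: str
    product: str
    coproduct: str
    coproduct_sequence: Optional[str] = None

    @property
    def step_id(self) -> str:
        return f"{self.precursor}→{self.product}"


@dataclass(frozen=True)
class Branch:
    """An ordered chain of cleavage steps sharing one endoproteolytic entry."""

    name: str
    steps: tuple[CleavageStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a branch needs at least one step")
        for upstream, downstream in zip(self.steps, self.steps[1:]):
            if upstream.product != downstream.precursor:
                raise ValueError(
                    f"branch {self.name!r}: step {downstream.step_id} does not "
                    f"consume the product of {upstream.step_id}"
                )

    @property
    def endo_step(self) -> CleavageStep:
        """The endoproteolysis (ε) step that opens the branch."""
        return self.steps[0]

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(step.product for step in self.steps)


@dataclass(frozen=True)
class PathwayGraph:
    """The full branched topology, rooted at a shared substrate."""

    substrate: str
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        coproducts: list[str] = []
        precursors: list[str] = []
        for branch in self.branches:
            if branch.endo_step.precursor != self.substrate:
                raise ValueError(
                    f"branch {branch.name!r} does not start from the substrate"
                )
            for step in branch.steps:
                coproducts.append(step.coproduct)
                precursors.append(step.precursor)
        if len(set(coproducts)) != len(coproducts):
            raise ValueError("each coproduct must appear in exactly one step")
        trimming_precursors = [p for p in precursors if p != self.substrate]
        if len(set(trimming_precursors)) != len(trimming_precursors):
            raise ValueError("each non-terminal species is precursor of exactly one step")

    # -- lookups ---------------------------------------------------------

    def steps(self) -> Iterator[CleavageStep]:
        for branch in self.branches:
            yield from branch.steps

    @property
    def coproduct_ids(self) -> tuple[str, ...]:
        return tuple(step.coproduct for step in self.steps())

    @property
    def pool_species(self) -> tuple[str, ...]:
        """All Aβ intermediate/terminal species, branch by branch."""
        return tuple(s for branch in self.branches for s in branch.products)

    @property
    def trimming_steps(self) -> tuple[CleavageStep, ...]:
        return tuple(s for b in self.branches for s in b.steps[1:])

    def producing_step(self, species: str) -> CleavageStep:
        for step in self.steps():
            if step.product == species:
                return step
        raise KeyError(f"no step produces species {species!r}")

    def consuming_step(self, species: str) -> Optional[CleavageStep]:
        for step in self.steps():
            if step.precursor == species:
                return step
        return None

    def branch_of(self, species: str) -> Branch:
        for branch in self.branches:
            if species in branch.products:
                return branch
        raise KeyError(f"unknown species {species!r}")

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PathwayGraph":
        branches = []
        for raw in payload["branches"]:
            steps = tuple(
                CleavageStep(
                    precursor=s["precursor"],
                    product=s["product"],
                    coproduct=s["coproduct"],
                    coproduct_sequence=s.get("coproduct_sequence"),
                )
                for s in raw["steps"]
            )
            branches.append(Branch(name=raw["name"], steps=steps))
        return cls(substrate=payload["substrate"], branches=tuple(branches))

    @classmethod
    def from_yaml(cls, path) -> "PathwayGraph":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "substrate": self.substrate,
            "branches": [
                {
                    "name": b.name,
                    "steps": [
                        {
                            "precursor": s.precursor,
                            "product": s.product,
                            "coproduct": s.coproduct,
                            **(
                                {"coproduct_sequence": s.coproduct_sequence}
                                if s.coproduct_sequence
                                else {}
                            ),
                        }
                        for s in b.steps
                    ],
                }
                for b in self.branches
            ],
        }


def default_graph() -> PathwayGraph:
    """The canonical two-branch C99 processing topology (packaged config)."""
    ref = resources.files("abtrim") / "data" / "pathway.yaml"
    return PathwayGraph.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


class QCCode(enum.Enum):
    NEGATIVE_POOL = "NEGATIVE_POOL"
    EFFICIENCY_GT_100 = "EFFICIENCY_GT_100"
    PRECURSOR_ND = "PRECURSOR_ND"
    BELOW_LOD = "BELOW_LOD"


@dataclass(frozen=True)
class QCFlag:
    """One QC finding, keyed by (code, species-or-step)."""

    code: QCCode
    target: str
    detail: str = ""

    def __eq__(self, other) -> bool:  # one flag per (code, target) pair
        if not isinstance(other, QCFlag):
            return NotImplemented
        return (self.code, self.target) == (other.code, other.target)

    def __hash__(self) -> int:
        return hash((self.code, self.target))


@dataclass(frozen=True)
class CoproductTable:
    """Measured coproduct concentrations for one variant/replicate/channel."""

    variant: str
    values: Mapping[str, Value]
    replicate: int = 1
    channel: str = "light"

    def __post_init__(self) -> None:
        if self.replicate < 0:
            raise ValueError("replicate index must be >= 0")
        if self.channel not in ("light", "heavy"):
            raise ValueError(f"channel must be 'light' or 'heavy', got {self.channel!r}")
        for key, value in self.values.items():
            if is_nd(value) or is_censored(value):
                continue
            if not is_numeric(value):
                raise ValueError(f"coproduct {key!r}: non-numeric value {value!r}")
            if value < 0:
                raise ValueError(f"coproduct {key!r}: negative concentration {value}")

    def validate_against(self, graph: PathwayGraph) -> None:
        missing = set(graph.coproduct_ids) - set(self.values)
        if missing:
            raise KeyError(f"missing coproduct keys: {sorted(missing)}")
        unknown = set(self.values) - set(graph.coproduct_ids)
        if unknown:
            raise KeyError(f"unknown coproduct keys: {sorted(unknown)}")


@dataclass(frozen=True)
class PoolTable:
    """Inferred Aβ pool concentrations plus derived ratios, efficiencies, QC."""

    variant: str
    pools: Mapping[str, Value]
    ratio_42_40: Value = ND
    efficiencies: Mapping[str, Value] = field(default_factory=dict)
    flags: frozenset[QCFlag] = frozenset()
    replicate: int = 1


# ---------------------------------------------------------------------------
# Mass-balance maps
# ---------------------------------------------------------------------------


def coproducts_from_pools(
    pools: Mapping[str, float], graph: Optional[PathwayGraph] = None
) -> dict[str, float]:
    """Forward map: Aβ pools → coproduct concentrations (branch suffix sums).

    The coproduct of step *i* of a branch counts every molecule that passed
    through that cut, i.e. the sum of the step-*i* product pool and all pools
    downstream of it in the same branch.  The endoproteolysis coproduct equals
    the whole-branch pool sum; the terminal coproduct equals the terminal pool.
    Negative pools are allowed (the map is linear and exactly invertible).
    """
    graph = graph or default_graph()
    known = set(graph.pool_species)
    unknown = set(pools) - known
    if unknown:
        raise KeyError(f"unknown species ids: {sorted(unknown)}")
    missing = known - set(pools)
    if missing:
        raise KeyError(f"missing pool values for: {sorted(missing)}")
    for species, value in pools.items():
        if not is_numeric(value):
            raise ValueError(f"pool {species!r} is not a finite number: {value!r}")

    out: dict[str, float] = {}
    for branch in graph.branches:
        suffix = 0.0
        for step in reversed(branch.steps):
            suffix += float(pools[step.product])
            out[step.coproduct] = suffix
    return out


def pools_from_coproducts(
    coproducts: CoproductTable, graph: Optional[PathwayGraph] = None
) -> PoolTable:
    """Inverse map: coproducts → net Aβ pools, with QC flags.

    Pool of species X = (coproduct producing X) − (coproduct consuming X);
    terminal species keep their producing coproduct.  Negative results are
    preserved and flagged NEGATIVE_POOL; a pool whose defining coproduct is
    censored (below the lowest standard) or missing is ND, flagged BELOW_LOD
    or PRECURSOR_ND respectively.  Also fills per-step efficiencies and the
    Aβ42/Aβ40 ratio so the result has the full summary-row shape.
    """
    graph = graph or default_graph()
    coproducts.validate_against(graph)
    values = coproducts.values

    flags: set[QCFlag] = set()
    pools: dict[str, Value] = {}
    for branch in graph.branches:
        for step, downstream in zip(branch.steps, list(branch.steps[1:]) + [None]):
            producing = values[step.coproduct]
            consuming = 0.0 if downstream is None else values[downstream.coproduct]
            defining = [producing] if downstream is None else [producing, consuming]
            if any(is_censored(v) for v in defining):
                pools[step.product] = ND
                flags.add(
                    QCFlag(
                        QCCode.BELOW_LOD,
                        step.product,
                        "defining coproduct below the lowest standard",
                    )
                )
                continue
            if any(is_nd(v) for v in defining):
                pools[step.product] = ND
                flags.add(
                    QCFlag(QCCode.PRECURSOR_ND, step.product, "defining coproduct missing")
                )
                continue
            pool = float(producing) - float(consuming)
            pools[step.product] = pool
            if pool < 0:
                flags.add(
                    QCFlag(
                        QCCode.NEGATIVE_POOL,
                        step.product,
                        f"net pool {pool:.1f} nM < 0: production coproduct under-"
                        "detected or degradation coproduct over-detected",
                    )
                )

    efficiencies, eff_flags = _step_efficiencies_with_flags(coproducts, graph)
    flags |= eff_flags
    ratio = _ratio_42_40(pools)

    return PoolTable(
        variant=coproducts.variant,
        pools=pools,
        ratio_42_40=ratio,
        efficiencies=efficiencies,
        flags=frozenset(flags),
        replicate=coproducts.replicate,
    )


def _step_efficiencies_with_flags(
    coproducts: CoproductTable, graph: PathwayGraph
) -> tuple[dict[str, Value], set[QCFlag]]:
    values = coproducts.values
    efficiencies: dict[str, Value] = {}
    flags: set[QCFlag] = set()
    for branch in graph.branches:
        for upstream, step in zip(branch.steps, branch.steps[1:]):
            producing = values[upstream.coproduct]
            consuming = values[step.coproduct]
            if (
                not is_numeric(producing)
                or producing == 0
                or not is_numeric(consuming)
            ):
                # no (or unquantifiable) precursor production: efficiency nd
                efficiencies[step.step_id] = ND
                continue
            eff = 100.0 * float(consuming) / float(producing)
            efficiencies[step.step_id] = eff
            if eff > 100.0:
                flags.add(
                    QCFlag(
                        QCCode.EFFICIENCY_GT_100,
                        step.step_id,
                        f"{eff:.1f}% of the produced precursor apparently cleaved; "
                        ">100% is not possible",
                    )
                )
    return efficiencies, flags


def step_efficiencies(
    coproducts: CoproductTable, graph: Optional[PathwayGraph] = None
) -> dict[str, Value]:
    """Percent cleavage per trimming step: 100 × consuming / producing coproduct.

    Answers "given the level of Aβ precursor produced, how much of it was
    cleaved in the next step?".  Endoproteolysis steps have no efficiency (no
    upstream coproduct).  A zero, censored, or missing producing coproduct
    yields ND; values above 100% are returned unclipped (they are flagged by
    :func:`pools_from_coproducts`).
    """
    graph = graph or default_graph()
    coproducts.validate_against(graph)
    efficiencies, _ = _step_efficiencies_with_flags(coproducts, graph)
    return efficiencies


def _ratio_42_40(pools: Mapping[str, Value]) -> Value:
    ab42 = pools.get("Aβ42", ND)
    ab40 = pools.get("Aβ40", ND)
    if not is_numeric(ab42) or not is_numeric(ab40) or float(ab40) <= 0:
        return ND
    return float(ab42) / float(ab40)


def ab42_ab40_ratio(pools: PoolTable) -> Value:
    """Aβ42/Aβ40 pool ratio; ND when either pool is ND or Aβ40 ≤ 0.

    A non-positive denominator means essentially no Aβ40 was produced, so the
    ratio is not reliable and is withheld rather than reported as a huge number.
    """
    return _ratio_42_40(pools.pools)


def qc_report(pool_tables: Sequence[PoolTable]):
    """Aggregate QC flags across variants into one tidy frame.

    Deterministic ordering: (variant, code, target).  Returns a pandas
    DataFrame with columns variant, code, target, detail (empty if no flags).
    """
    import pandas as pd

    if len(pool_tables) == 0:
        raise ValueError("qc_report needs at least one pool table")
    rows = [
        {
            "variant": table.variant,
            "code": flag.code.value,
            "target": flag.target,
            "detail": flag.detail,
        }
        for table in pool_tables
        for flag in table.flags
    ]
    frame = pd.DataFrame(rows, columns=["variant", "code", "target", "detail"])
    return frame.sort_values(["variant", "code", "target"], kind="stable").reset_index(
        drop=True
    )
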