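"""Condition-specific submodel extraction.

Order of integration: exo-metabolomic bounds are applied first
(:mod:`exoflux.exoconstraints`), then reactions depending on gene
products called absent are shut, feasibility of the enforced minima is
verified, and finally every reaction unable to carry flux anywhere in
the constrained polytope is removed by FVA pruning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd

from . import netcore
from .netcore import InfeasibleModelError

PRUNE_TOL = 1e-6


@dataclass(frozen=True)
class ExpressionCalls:
    """Present/absent calls per gene (unlisted genes default to present)."""

    calls: Mapping[str, str]
    call_pvalue_cutoff: float = 0.05  # provenance only

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.calls.items()
               if c not in {"present", "absent"}}
        if bad:
            raise ValueError(f"calls must be 'present' or 'absent': {bad}")

    @property
    def absent(self) -> set[str]:
        return {g for g, c in self.calls.items() if c == "absent"}


def read_calls(path) -> ExpressionCalls:
    """Read the calls TSV (gene_id, call[, pvalue])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "call"} <= set(df.columns):
        raise ValueError("calls table needs columns gene_id, call")
    return ExpressionCalls(dict(zip(df["gene_id"], df["call"])))


@dataclass
class FeasibilityReport:
    feasible: bool
    objective_value: float | None
    #: enforced exchange constraints whose relaxation restores feasibility
    relaxation_set: list[str] = field(default_factory=list)


@dataclass
class PruneReport:
    removed_reactions: list[str]
    removed_metabolites: list[str]
    removed_genes: list[str]
    retained_reactions: int
    retained_metabolites: int
    retained_genes: int
    tolerance: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=1))
        return path

    def to_frame(self) -> pd.DataFrame:
        rows = [("reaction", r) for r in self.removed_reactions]
        rows += [("metabolite", m) for m in self.removed_metabolites]
        rows += [("gene", g) for g in self.removed_genes]
        return pd.DataFrame(rows, columns=["kind", "removed_id"])


def remove_absent_genes(model: cobra.Model, calls: ExpressionCalls,
                        ) -> tuple[cobra.Model, list[str]]:
    """Shut every reaction whose GPR is unsatisfiable with absent genes off.

    Reactions rescued by a present isozyme keep their bounds; a complex
    missing one mandatory subunit is disabled.  The gene list itself is
    untouched (pruning removes orphan genes later).  Returns a modified
    copy and the ids of the disabled reactions.
    """
    model = model.copy()
    known = {g.id for g in model.genes}
    absent = calls.absent
    unknown = absent - known
    if unknown:
        import logging
        logging.getLogger(__name__).warning(
            "ignoring absence calls for genes not in model: %s",
            sorted(unknown))
    absent &= known
    disabled = []
    for rxn in model.reactions:
        if netcore.reaction_blocked_by(rxn, absent):
            rxn.bounds = (0.0, 0.0)
            disabled.append(rxn.id)
    return model, disabled


def enforced_exchanges(model: cobra.Model) -> list[cobra.Reaction]:
    """Exchanges with an enforced minimum: forced secretion (lb > 0) or
    forced uptake (ub < 0)."""
    return [r for r in netcore.exchanges(model)
            if r.lower_bound > 0 or r.upper_bound < 0]


def check_consistency(model: cobra.Model) -> FeasibilityReport:
    """Can the model satisfy the enforced biomass and exchange minima?

    If not, a minimal relaxation set is sought by iterative
    single-constraint relaxation of the enforced exchange minima: first
    each constraint alone; if none suffices, constraints are relaxed
    cumulatively (greedy) until the model turns feasible.
    """
    sol = netcore.fba(model)
    if sol.ok:
        return FeasibilityReport(True, sol.objective_value)

    candidates = enforced_exchanges(model)

    def _relax(rxn: cobra.Reaction) -> None:
        if rxn.lower_bound > 0:
            rxn.lower_bound = 0.0
        if rxn.upper_bound < 0:
            rxn.upper_bound = 0.0

    # single-constraint pass
    for rxn in candidates:
        with model as m:
            _relax(m.reactions.get_by_id(rxn.id))
            if netcore.fba(m).ok:
                return FeasibilityReport(False, None, [rxn.id])
    # greedy cumulative pass
    relaxed: list[str] = []
    with model as m:
        for rxn in candidates:
            _relax(m.reactions.get_by_id(rxn.id))
            relaxed.append(rxn.id)
            if netcore.fba(m).ok:
                return FeasibilityReport(False, None, relaxed)
    return FeasibilityReport(False, None, [])


def prune(model: cobra.Model, tol: float = PRUNE_TOL,
          ) -> tuple[cobra.Model, PruneReport]:
    """Remove every reaction FVA pins to zero, then orphan metabolites/genes.

    FVA runs with all constraints active (enforced biomass minimum
    included), so "unable to support flux" means unable anywhere in the
    data-constrained polytope.  The operation is idempotent and never
    removes the biomass reaction or an enforced-minimum exchange (those
    carry flux by construction).
    """
    if not netcore.fba(model).ok:
        raise InfeasibleModelError(
            "cannot prune an infeasible model; run check_consistency first")
    ranges = netcore.fva(model)
    protected = {netcore.objective_reaction(model).id}
    protected |= {r.id for r in enforced_exchanges(model)}
    blocked = [rid for rid, row in ranges.iterrows()
               if abs(row["minimum"]) < tol and abs(row["maximum"]) < tol
               and rid not in protected]
    sub = model.copy()
    mets_before = {m.id for m in sub.metabolites}
    genes_before = {g.id for g in sub.genes}
    sub.remove_reactions([sub.reactions.get_by_id(r) for r in blocked],
                         remove_orphans=True)
    # drop genes that appear in no remaining GPR
    used_genes = {g.id for r in sub.reactions for g in r.genes}
    orphans = [g for g in list(sub.genes) if g.id not in used_genes]
    if orphans:
        cobra.manipulation.remove_genes(sub, orphans, remove_reactions=False)
    report = PruneReport(
        removed_reactions=sorted(blocked),
        removed_metabolites=sorted(mets_before - {m.id for m in sub.metabolites}),
        removed_genes=sorted(genes_before - {g.id for g in sub.genes}),
        retained_reactions=len(sub.reactions),
        retained_metabolites=len(sub.metabolites),
        retained_genes=len(sub.genes),
        tolerance=tol,
    )
    return sub, report


@dataclass
class ModelDiff:
    shared: dict[str, set[str]]
    unique_A: dict[str, set[str]]
    unique_B: dict[str, set[str]]

    def counts(self) -> pd.DataFrame:
        rows = []
        for kind in ("reactions", "metabolites", "genes"):
            rows.append({"kind": kind, "shared": len(self.shared[kind]),
                         "unique_A": len(self.unique_A[kind]),
                         "unique_B": len(self.unique_B[kind])})
        return pd.DataFrame(rows)


def model_diff(model_A: cobra.Model, model_B: cobra.Model) -> ModelDiff:
    """Partition reactions, metabolites, and genes of two models into
    shared / unique-to-A / unique-to-B sets."""
    def _ids(model):
        return {"reactions": {r.id for r in model.reactions},
                "metabolites": {m.id for m in model.metabolites},
                "genes": {g.id for g in model.genes}}

    a, b = _ids(model_A), _ids(model_B)
    return ModelDiff(
        shared={k: a[k] & b[k] for k in a},
        unique_A={k: a[k] - b[k] for k in a},
        unique_B={k: b[k] - a[k] for k in a},
    )


__all__ = [
    "ExpressionCalls", "FeasibilityReport", "ModelDiff", "PRUNE_TOL",
    "PruneReport", "check_consistency", "enforced_exchanges", "model_diff",
    "prune", "read_calls", "remove_absent_genes",
]
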