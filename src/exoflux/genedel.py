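"""In-silico single-gene deletion screening and lethal-set comparison.

A gene deletion shuts every reaction whose GPR becomes unsatisfiable
without the gene (isozymes rescue, complexes fail).  The screen relaxes
the biomass lower bound to zero and maximises growth for each knockout;
a gene is lethal when the residual maximum growth falls below a
threshold.  An alternative mode keeps the enforced growth minimum and
equates lethality with infeasibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import cobra
import pandas as pd

from . import netcore
from .netcore import InfeasibleModelError

LETHAL_TOL = 1e-6


@dataclass
class DeletionResult:
    """Per-gene knockout outcomes for one model."""

    max_growth: dict[str, float]
    lethal: dict[str, bool]
    affected_reactions: dict[str, list[str]]
    wild_type_growth: float
    lethal_tol: float

    @property
    def lethal_genes(self) -> set[str]:
        return {g for g, flag in self.lethal.items() if flag}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene_id": g, "max_growth": self.max_growth[g],
              "lethal": self.lethal[g],
              "n_affected_reactions": len(self.affected_reactions[g])}
             for g in sorted(self.max_growth)]
        )


def affected_reactions(model: cobra.Model, gene_id: str) -> list[str]:
    """Reactions disabled when *gene_id* alone is knocked out."""
    gene = model.genes.get_by_id(gene_id)
    return sorted(r.id for r in gene.reactions
                  if netcore.reaction_blocked_by(r, {gene_id}))


def delete_gene(model: cobra.Model, gene_id: str) -> cobra.Model:
    """Return a copy with the gene's dependent reactions shut to (0, 0)."""
    if gene_id not in {g.id for g in model.genes}:
        raise KeyError(f"gene {gene_id!r} not in model")
    model = model.copy()
    for rid in affected_reactions(model, gene_id):
        model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return model


def screen(model: cobra.Model, genes: Iterable[str] | None = None,
           lethal_tol: float = LETHAL_TOL,
           keep_biomass_minimum: bool = False) -> DeletionResult:
    """Single-gene deletion screen over all (or the given) model genes.

    By default the biomass lower bound is relaxed to zero before testing,
    so lethality means "no growth achievable at all" rather than "cannot
    meet the enforced minimum"; pass ``keep_biomass_minimum=True`` for
    the stricter infeasibility criterion.
    """
    wt = netcore.fba(model)
    if not wt.ok:
        raise InfeasibleModelError("wild-type model is infeasible")
    biomass = netcore.objective_reaction(model)
    gene_ids = sorted(g.id for g in model.genes) if genes is None \
        else sorted(genes)
    max_growth: dict[str, float] = {}
    lethal: dict[str, bool] = {}
    affected: dict[str, list[str]] = {}
    with model as m:
        if not keep_biomass_minimum:
            m.reactions.get_by_id(biomass.id).lower_bound = 0.0
        for gid in gene_ids:
            hit = affected_reactions(m, gid)
            affected[gid] = hit
            with m:
                for rid in hit:
                    m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
                sol = netcore.fba(m)
            growth = sol.objective_value if sol.ok else 0.0
            max_growth[gid] = growth
            lethal[gid] = (not sol.ok) or growth < lethal_tol
    return DeletionResult(max_growth=max_growth, lethal=lethal,
                          affected_reactions=affected,
                          wild_type_growth=wt.objective_value,
                          lethal_tol=lethal_tol)


@dataclass
class LethalSets:
    shared: set[str]
    unique_A: set[str]
    unique_B: set[str]
    #: genes lethal in one model and not even present in the other
    absent_from_B: set[str] = field(default_factory=set)
    absent_from_A: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {k: sorted(v) for k, v in self.__dict__.items()}, indent=1))
        return path


def lethal_sets(res_A: DeletionResult, res_B: DeletionResult) -> LethalSets:
    """Shared and model-unique lethal genes, with absence annotations.

    A gene is unique to A when it is lethal in A and either viable in B
    or not part of B's gene set at all (the latter are flagged
    separately, mirroring lethal genes that survive contextual pruning
    in only one model).
    """
    la, lb = res_A.lethal_genes, res_B.lethal_genes
    genes_a, genes_b = set(res_A.max_growth), set(res_B.max_growth)
    return LethalSets(
        shared=la & lb,
        unique_A=la - lb,
        unique_B=lb - la,
        absent_from_B=la - genes_b,
        absent_from_A=lb - genes_a,
    )


__all__ = ["DeletionResult", "LETHAL_TOL", "LethalSets", "affected_reactions",
           "delete_gene", "lethal_sets", "screen"]
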