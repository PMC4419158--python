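"""Comparison of two models' sampled flux distributions.

Shared reactions are partitioned by their sampling medians into group x
(more utilized by model A), group y (more utilized by model B), and
group z (difference within the threshold, opposite flux direction, or
loop reactions).  Loop reactions are those FVA drives to the ±500 cap in
both directions — thermodynamically infeasible internal cycles whose
medians carry no information.  The partition is then confronted with
differential-expression calls: for up- and downregulated genes, how
often do their associated reactions fall on the expected side?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd

from . import netcore
from .netcore import BOUND_CAP

UTILIZATION_THRESHOLD = 0.10
_ZERO_TOL = 1e-9


def find_loops(model: cobra.Model, cap: float = BOUND_CAP,
               tol: float = 1e-6) -> set[str]:
    """Reactions whose FVA range spans the full ±cap in both directions."""
    ranges = netcore.fva(model)
    return {rid for rid, row in ranges.iterrows()
            if row["minimum"] <= -cap + tol and row["maximum"] >= cap - tol}


@dataclass
class ComparisonResult:
    """Utilization partition of the shared reaction set."""

    shared_reactions: set[str]
    group_x: set[str]  # higher |median| in A
    group_y: set[str]  # higher |median| in B
    group_z: set[str]  # within threshold, opposite direction, or loops
    loops_A: set[str]
    loops_B: set[str]
    medians_A: Mapping[str, float]
    medians_B: Mapping[str, float]
    threshold: float

    @property
    def loops(self) -> set[str]:
        return (self.loops_A | self.loops_B) & self.shared_reactions

    def group_of(self, reaction_id: str) -> str | None:
        for name, group in (("x", self.group_x), ("y", self.group_y),
                            ("z", self.group_z)):
            if reaction_id in group:
                return name
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid in sorted(self.shared_reactions):
            ma, mb = self.medians_A[rid], self.medians_B[rid]
            rows.append({
                "reaction_id": rid, "median_A": ma, "median_B": mb,
                "rel_diff": _relative_difference(ma, mb),
                "group": self.group_of(rid),
                "loop": rid in self.loops,
            })
        return pd.DataFrame(rows)


def _relative_difference(ma: float, mb: float,
                         denominator: str = "max") -> float:
    scale = {"max": max(abs(ma), abs(mb)),
             "baseline_B": abs(mb),
             "mean": (abs(ma) + abs(mb)) / 2.0}[denominator]
    if scale < _ZERO_TOL:
        return 0.0
    return abs(ma - mb) / scale


def utilization_groups(medians_A: Mapping[str, float],
                       medians_B: Mapping[str, float],
                       loops: Iterable[str] = (),
                       threshold: float = UTILIZATION_THRESHOLD,
                       denominator: str = "max") -> ComparisonResult:
    """Partition shared reactions into x / y / z by median flux difference.

    A reaction is differently utilized when its medians differ by more
    than *threshold* of the larger magnitude (``denominator`` selects
    the scale: ``max`` (default), ``baseline_B``, or ``mean``).
    Opposite-sign median pairs, near-zero pairs, and loop reactions go
    to z regardless of the difference.
    """
    loops = set(loops)
    shared = set(medians_A) & set(medians_B)
    x, y, z = set(), set(), set()
    for rid in shared:
        ma, mb = float(medians_A[rid]), float(medians_B[rid])
        if rid in loops:
            z.add(rid)
        elif abs(ma) < _ZERO_TOL and abs(mb) < _ZERO_TOL:
            z.add(rid)
        elif ma * mb < 0 and abs(ma) > _ZERO_TOL and abs(mb) > _ZERO_TOL:
            z.add(rid)  # opposite directionality
        elif _relative_difference(ma, mb, denominator) > threshold:
            (x if abs(ma) > abs(mb) else y).add(rid)
        else:
            z.add(rid)
    return ComparisonResult(
        shared_reactions=shared, group_x=x, group_y=y, group_z=z,
        loops_A=loops, loops_B=loops,
        medians_A=dict(medians_A), medians_B=dict(medians_B),
        threshold=threshold)


def compare_models(medians_A: Mapping[str, float],
                   medians_B: Mapping[str, float],
                   model_A: cobra.Model, model_B: cobra.Model,
                   threshold: float = UTILIZATION_THRESHOLD,
                   denominator: str = "max") -> ComparisonResult:
    """Utilization partition with loop sets computed per model by FVA."""
    loops_a = find_loops(model_A)
    loops_b = find_loops(model_B)
    result = utilization_groups(medians_A, medians_B, loops_a | loops_b,
                                threshold, denominator)
    result.loops_A, result.loops_B = loops_a, loops_b
    return result


# ---------------------------------------------------------------------------
# DEG concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGTable:
    """Differentially expressed genes: direction is A-vs-B (up = higher in A)."""

    rows: pd.DataFrame  # columns gene_id, direction, fdr

    def __post_init__(self) -> None:
        required = {"gene_id", "direction", "fdr"}
        if not required <= set(self.rows.columns):
            raise ValueError(f"DEG table needs columns {sorted(required)}")
        if self.rows["gene_id"].duplicated().any():
            raise ValueError("DEG table has duplicate gene ids")
        bad = ~self.rows["direction"].isin(["up", "down"])
        if bad.any():
            raise ValueError("DEG direction must be 'up' or 'down'")
        if ((self.rows["fdr"] < 0) | (self.rows["fdr"] > 1)).any():
            raise ValueError("fdr must lie in [0, 1]")

    @classmethod
    def read(cls, path) -> "DEGTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))

    def genes(self, direction: str) -> list[str]:
        sel = self.rows[self.rows["direction"] == direction]
        return list(sel["gene_id"])


def gene_reaction_map(*models: cobra.Model) -> dict[str, set[str]]:
    """gene id -> ids of reactions whose GPR mentions it (union over models)."""
    mapping: dict[str, set[str]] = {}
    for model in models:
        for gene in model.genes:
            mapping.setdefault(gene.id, set()).update(
                r.id for r in gene.reactions)
    return mapping


def deg_concordance(result: ComparisonResult, degs: DEGTable,
                    gene_map: Mapping[str, set[str]]) -> dict:
    """Do reactions of up/down-regulated genes fall in the expected group?

    Reaction level: among the shared non-loop reactions associated with
    up (resp. down) genes, the percentage in x, y, and z.  Gene level:
    the percentage of up genes for which a strict majority of their
    classified reactions lie in x, and of down genes with a strict
    majority in y; ties count as non-majority.  Percentages are ``None``
    when the denominator is empty.
    """
    classified = result.group_x | result.group_y | result.group_z
    usable = classified - result.loops

    def _pct(k: int, n: int) -> float | None:
        return None if n == 0 else 100.0 * k / n

    report: dict = {"n_genes": {"up": 0, "down": 0}}
    for direction, majority_group in (("up", result.group_x),
                                      ("down", result.group_y)):
        genes = degs.genes(direction)
        report["n_genes"][direction] = len(genes)
        rxns: set[str] = set()
        majority_hits = 0
        genes_with_rxns = 0
        for g in genes:
            assoc = (gene_map.get(g, set()) & usable)
            if not assoc:
                continue
            genes_with_rxns += 1
            rxns |= assoc
            in_major = len(assoc & majority_group)
            if in_major * 2 > len(assoc):
                majority_hits += 1
        n = len(rxns)
        report[direction] = {
            "n_reactions": n,
            "pct_x": _pct(len(rxns & result.group_x), n),
            "pct_y": _pct(len(rxns & result.group_y), n),
            "pct_z": _pct(len(rxns & result.group_z), n),
            "n_genes_with_reactions": genes_with_rxns,
            "pct_genes_majority": _pct(majority_hits, genes_with_rxns),
        }
    return report


def write_concordance(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1))
    return path


__all__ = ["ComparisonResult", "DEGTable", "UTILIZATION_THRESHOLD",
           "compare_models", "deg_concordance", "find_loops",
           "gene_reaction_map", "utilization_groups", "write_concordance"]
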