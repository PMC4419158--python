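"""Stoichiometric model handling and the LP layer (FBA, FVA).

The in-memory container is :class:`cobra.Model`; this module adds the
pieces the pipeline needs on top of it: a documented JSON dialect and a
TSV table format alongside SBML L3/FBC, bound capping at ±500 mmol/gDW/h,
GPR evaluation against an absent-gene set, and FBA/FVA wrappers that
return plain results instead of raising on infeasibility.

Flux units are mmol/gDW/h throughout.  Exchange reactions follow the
COBRA convention ``met[e] <=> (nothing)``: positive flux is secretion,
negative flux is uptake.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
from cobra.core.gene import GPR
from cobra.util.array import create_stoichiometric_matrix

#: Default cap applied to unbounded / over-wide reaction bounds.
BOUND_CAP = 500.0

#: Identifier of the extracellular compartment.
EXTRACELLULAR = "e"

SOLVER = "glpk"


class ModelValidationError(ValueError):
    """A model file violates the dialect or the model invariants."""


class GPRParseError(ValueError):
    """A gene-protein-reaction rule could not be parsed."""


class InfeasibleModelError(RuntimeError):
    """An operation requiring a feasible model was called on an infeasible one."""


@dataclass
class FBAResult:
    """Outcome of a single flux-balance LP."""

    status: str  # "optimal" or "infeasible"
    objective_value: float | None
    fluxes: pd.Series | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# GPR logic
# ---------------------------------------------------------------------------

def parse_gpr(rule: str) -> GPR:
    """Parse a GPR string (case-insensitive and/or, parentheses, gene ids).

    Raises :class:`GPRParseError` on malformed rules instead of silently
    returning an empty (always-satisfied) rule.
    """
    rule = (rule or "").strip()
    # keywords are case-insensitive; cobra wants them lowercase
    rule = re.sub(r"(?i)\b(and|or)\b", lambda m: m.group(0).lower(), rule)
    with warnings.catch_warnings():
        warnings.simplefilter("error", SyntaxWarning)
        try:
            return GPR.from_string(rule)
        except (SyntaxWarning, SyntaxError, TypeError) as exc:
            raise GPRParseError(f"malformed GPR {rule!r}: {exc}") from exc


def evaluate_gpr(rule: str | GPR, absent: Iterable[str] = ()) -> bool:
    """Evaluate a GPR with the given genes absent and all others present.

    An empty rule is vacuously satisfied (the reaction needs no gene
    product).  ``and`` encodes complex subunits, ``or`` isozymes.
    """
    gpr = rule if isinstance(rule, GPR) else parse_gpr(rule)
    return bool(gpr.eval(knockouts=set(absent)))


def reaction_blocked_by(reaction: cobra.Reaction, absent: set[str]) -> bool:
    """True iff the reaction has a GPR and it is unsatisfiable with *absent* off."""
    rule = reaction.gene_reaction_rule
    if not rule.strip():
        return False
    return not evaluate_gpr(reaction.gpr, absent)


# ---------------------------------------------------------------------------
# Model construction / validation
# ---------------------------------------------------------------------------

def cap_bounds(model: cobra.Model, cap: float = BOUND_CAP) -> cobra.Model:
    """Clamp every reaction bound into [-cap, cap], in place.

    Reconstructions ship "infinite" bounds (±1000 or larger); all are
    normalised to ±500 so that loop reactions are recognisable by FVA
    hitting exactly ±500.
    """
    for rxn in model.reactions:
        lb = max(rxn.lower_bound, -cap)
        ub = min(rxn.upper_bound, cap)
        rxn.bounds = (lb, ub)
    return model


def is_exchange(reaction: cobra.Reaction) -> bool:
    """Boundary reaction moving a single extracellular metabolite."""
    mets = list(reaction.metabolites)
    return len(mets) == 1 and mets[0].compartment == EXTRACELLULAR


def exchanges(model: cobra.Model) -> list[cobra.Reaction]:
    return [r for r in model.reactions if is_exchange(r)]


def find_exchange(model: cobra.Model, metabolite_id: str) -> cobra.Reaction | None:
    """Locate the exchange reaction for a metabolite (id with or without ``_e``)."""
    met_e = metabolite_id if metabolite_id.endswith("_e") else metabolite_id + "_e"
    for rxn in exchanges(model):
        if next(iter(rxn.metabolites)).id == met_e:
            return rxn
    return None


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants; raise ModelValidationError on failure."""
    seen: set[str] = set()
    for met in model.metabolites:
        if met.id in seen:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        seen.add(met.id)
    gene_ids = {g.id for g in model.genes}
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        for g in rxn.genes:
            if g.id not in gene_ids:
                raise ModelValidationError(
                    f"reaction {rxn.id}: GPR references undeclared gene {g.id!r}"
                )
    objective_rxns = [r for r in model.reactions if r.objective_coefficient]
    if not objective_rxns:
        raise ModelValidationError("model declares no objective reaction")


def objective_reaction(model: cobra.Model) -> cobra.Reaction:
    for rxn in model.reactions:
        if rxn.objective_coefficient:
            return rxn
    raise ModelValidationError("model declares no objective reaction")


def stoichiometric_matrix(model: cobra.Model):
    """Dense S (metabolites x reactions) plus row/column id order."""
    S = create_stoichiometric_matrix(model, array_type="dense")
    return S, [m.id for m in model.metabolites], [r.id for r in model.reactions]


# ---------------------------------------------------------------------------
# File I/O: SBML (via cobra), JSON dialect, TSV tables
# ---------------------------------------------------------------------------

def _model_to_dict(model: cobra.Model) -> dict:
    return {
        "id": model.id or "model",
        "compartments": dict(model.compartments),
        "metabolites": [
            {"id": m.id, "name": m.name or "", "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name or "",
                "stoichiometry": {m.id: coef for m, coef in r.metabolites.items()},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gene_reaction_rule,
                "subsystem": r.subsystem or "",
            }
            for r in model.reactions
        ],
        "genes": sorted(g.id for g in model.genes),
        "objective": objective_reaction(model).id,
    }


def _model_from_dict(data: Mapping) -> cobra.Model:
    try:
        model = cobra.Model(data.get("id", "model"))
        model.solver = SOLVER
        comps = data.get("compartments") or {}
        mets = []
        for m in data["metabolites"]:
            met = cobra.Metabolite(
                m["id"], name=m.get("name", ""), compartment=m["compartment"]
            )
            mets.append(met)
        model.add_metabolites(mets)
        if comps:
            model.compartments = comps
        rxns = []
        for r in data["reactions"]:
            rxn = cobra.Reaction(
                r["id"],
                name=r.get("name", ""),
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
            )
            rxn.subsystem = r.get("subsystem", "")
            rxns.append(rxn)
        model.add_reactions(rxns)
        for r in data["reactions"]:
            rxn = model.reactions.get_by_id(r["id"])
            rxn.add_metabolites(
                {model.metabolites.get_by_id(k): float(v)
                 for k, v in r["stoichiometry"].items()}
            )
            gpr = r.get("gpr", "")
            if gpr:
                rxn.gpr = parse_gpr(gpr)
    except KeyError as exc:
        raise ModelValidationError(f"model dict missing required field {exc}") from exc
    declared = data.get("genes")
    if declared is not None:
        used = {g.id for g in model.genes}
        undeclared = used - set(declared)
        if undeclared:
            raise ModelValidationError(
                f"GPRs reference undeclared genes: {sorted(undeclared)}"
            )
    obj = data.get("objective")
    if obj:
        try:
            model.objective = model.reactions.get_by_id(obj)
        except KeyError:
            raise ModelValidationError(f"objective reaction {obj!r} not in model")
    return model


_TSV_COLUMNS = [
    "id", "name", "stoichiometry", "lower_bound", "upper_bound",
    "gpr", "subsystem", "objective",
]


def _model_to_reaction_table(model: cobra.Model) -> pd.DataFrame:
    obj = objective_reaction(model).id
    rows = []
    for r in model.reactions:
        stoich = ";".join(
            f"{m.id}:{coef:g}" for m, coef in sorted(
                r.metabolites.items(), key=lambda kv: kv[0].id)
        )
        rows.append({
            "id": r.id, "name": r.name or "", "stoichiometry": stoich,
            "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
            "gpr": r.gene_reaction_rule, "subsystem": r.subsystem or "",
            "objective": int(r.id == obj),
        })
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def _model_from_reaction_table(df: pd.DataFrame, model_id: str = "model") -> cobra.Model:
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ModelValidationError(f"reaction table missing columns {sorted(missing)}")
    mets: dict[str, dict] = {}
    reactions = []
    for _, row in df.iterrows():
        stoich = {}
        text = "" if pd.isna(row["stoichiometry"]) else str(row["stoichiometry"])
        for term in filter(None, (t.strip() for t in text.split(";"))):
            try:
                met_id, coef = term.rsplit(":", 1)
                stoich[met_id] = float(coef)
            except ValueError:
                raise ModelValidationError(
                    f"reaction {row['id']}: bad stoichiometry term {term!r}"
                )
            # compartment is the suffix after the last underscore
            mets.setdefault(met_id, {"id": met_id, "name": "",
                                     "compartment": met_id.rsplit("_", 1)[-1]})
        reactions.append({
            "id": str(row["id"]), "name": "" if pd.isna(row["name"]) else str(row["name"]),
            "stoichiometry": stoich,
            "lower_bound": float(row["lower_bound"]),
            "upper_bound": float(row["upper_bound"]),
            "gpr": "" if pd.isna(row["gpr"]) else str(row["gpr"]),
            "subsystem": "" if pd.isna(row["subsystem"]) else str(row["subsystem"]),
        })
    objective = df.loc[df["objective"].astype(int) == 1, "id"]
    data = {
        "id": model_id,
        "metabolites": list(mets.values()),
        "reactions": reactions,
        "objective": str(objective.iloc[0]) if len(objective) else None,
    }
    return _model_from_dict(data)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    if suffix == ".json":
        return "json"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise ValueError(f"cannot infer model format from {path.name!r}")


def read_model(path: str | Path, fmt: str | None = None,
               cap: float = BOUND_CAP) -> cobra.Model:
    """Read a model from SBML L3/FBC, the JSON dialect, or a reaction TSV.

    All bounds are capped to ±``cap`` (default ±500 mmol/gDW/h) and the
    model invariants are validated before returning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "sbml":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(str(path))
    elif fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path.name}: invalid JSON at line "
                                       f"{exc.lineno}: {exc.msg}") from exc
        model = _model_from_dict(data)
    elif fmt == "tsv":
        model = _model_from_reaction_table(pd.read_csv(path, sep="\t"), path.stem)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    model.solver = SOLVER
    cap_bounds(model, cap)
    validate_model(model)
    return model


def write_model(model: cobra.Model, path: str | Path, fmt: str | None = None) -> Path:
    """Write a model as SBML, JSON dialect, or reaction TSV (by extension)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=True))
    elif fmt == "tsv":
        _model_to_reaction_table(model).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


def model_from_dict(data: Mapping) -> cobra.Model:
    """Build a model from the JSON-dialect dictionary (programmatic entry)."""
    model = _model_from_dict(data)
    validate_model(model)
    return model


def model_to_dict(model: cobra.Model) -> dict:
    return _model_to_dict(model)


# ---------------------------------------------------------------------------
# LP layer
# ---------------------------------------------------------------------------

def fba(model: cobra.Model, objective: str | None = None,
        sense: str = "max") -> FBAResult:
    """Flux balance analysis: optimise one reaction's flux over S v = 0.

    Infeasibility is a returned status, not an exception, so callers can
    branch on it (consistency checking, knockout screens).
    """
    if sense not in {"max", "min"}:
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model as m:
        if objective is not None:
            m.objective = m.reactions.get_by_id(objective)
        m.objective_direction = "max" if sense == "max" else "min"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            solution = m.optimize()
        if solution.status != "optimal":
            return FBAResult(status="infeasible", objective_value=None, fluxes=None)
        return FBAResult(status="optimal",
                         objective_value=float(solution.objective_value),
                         fluxes=solution.fluxes.copy())


def fva(model: cobra.Model, reactions: Iterable[str] | None = None) -> pd.DataFrame:
    """Flux variability analysis over the *current* constraint set.

    Runs 2 LPs per reaction with no optimality requirement on the
    objective beyond the model's own bounds (any enforced biomass minimum
    is part of the polytope).  Returns a DataFrame indexed by reaction id
    with columns ``minimum`` and ``maximum``.
    """
    if not fba(model).ok:
        raise InfeasibleModelError(
            "model is infeasible; run contextualize.check_consistency first")
    reaction_list = None if reactions is None else [
        model.reactions.get_by_id(r) for r in reactions]
    result = cobra.flux_analysis.flux_variability_analysis(
        model, reaction_list=reaction_list, fraction_of_optimum=0.0,
        processes=1)
    return result[["minimum", "maximum"]]


__all__ = [
    "BOUND_CAP", "EXTRACELLULAR", "FBAResult", "GPRParseError",
    "InfeasibleModelError", "ModelValidationError", "cap_bounds",
    "evaluate_gpr", "exchanges", "fba", "find_exchange", "fva",
    "is_exchange", "model_from_dict", "model_to_dict", "objective_reaction",
    "parse_gpr", "reaction_blocked_by", "read_model", "stoichiometric_matrix",
    "validate_model", "write_model",
]
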