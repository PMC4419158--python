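"""Independent brute-force oracles used to cross-check the implementation.

Deliberately avoids the code paths under test: linear programs go
through scipy.optimize.linprog (HiGHS) on the raw (S, lb, ub) arrays
instead of cobra/GLPK, and GPR evaluation uses a hand-written recursive
descent parser instead of cobra's AST machinery.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import scipy.optimize

from exoflux import netcore


# ---------------------------------------------------------------------------
# LP oracle (scipy HiGHS on raw arrays)
# ---------------------------------------------------------------------------

def _arrays(model):
    S, _, rxn_ids = netcore.stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub, rxn_ids


def lp_optimize(model, objective_id: str, sense: str = "max"):
    """Optimal flux value by scipy linprog, or None if infeasible."""
    S, lb, ub, rxn_ids = _arrays(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0
    res = scipy.optimize.linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                                 bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return None
    return -res.fun if sense == "max" else res.fun


def lp_fva(model, reaction_ids=None) -> pd.DataFrame:
    """Per-reaction min/max via one independent LP per reaction and sense."""
    ids = reaction_ids or [r.id for r in model.reactions]
    rows = {}
    for rid in ids:
        rows[rid] = {"minimum": lp_optimize(model, rid, "min"),
                     "maximum": lp_optimize(model, rid, "max")}
    return pd.DataFrame.from_dict(rows, orient="index")


def lp_blocked_set(model, tol: float = 1e-6) -> set[str]:
    """Reactions whose independent min and max LPs are both below tol."""
    ranges = lp_fva(model)
    return {rid for rid, row in ranges.iterrows()
            if abs(row["minimum"]) < tol and abs(row["maximum"]) < tol}


def lp_lethal_genes(model, lethal_tol: float = 1e-6) -> set[str]:
    """Exhaustive knockout recomputation with the truth-table GPR oracle
    and an independent LP per gene (biomass lower bound relaxed)."""
    biomass = netcore.objective_reaction(model).id
    lethal = set()
    for gene in model.genes:
        knockout = model.copy()
        knockout.reactions.get_by_id(biomass).lower_bound = 0.0
        for rxn in knockout.reactions:
            rule = rxn.gene_reaction_rule
            if rule.strip() and not eval_gpr_string(rule, {gene.id}):
                rxn.bounds = (0.0, 0.0)
        growth = lp_optimize(knockout, biomass, "max")
        if growth is None or growth < lethal_tol:
            lethal.add(gene.id)
    return lethal


# ---------------------------------------------------------------------------
# GPR oracle (recursive descent, no cobra)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def eval_gpr_string(rule: str, absent: set[str]) -> bool:
    """Evaluate and/or/parenthesis gene rules against an absent set."""
    tokens = _TOKEN.findall(rule)
    if not tokens:
        return True
    pos = 0

    def parse_or() -> bool:
        nonlocal pos
        value = parse_and()
        while pos < len(tokens) and tokens[pos].lower() == "or":
            pos += 1
            value = parse_and() or value
        return value

    def parse_and() -> bool:
        nonlocal pos
        value = parse_atom()
        while pos < len(tokens) and tokens[pos].lower() == "and":
            pos += 1
            value = parse_atom() and value
        return value

    def parse_atom() -> bool:
        nonlocal pos
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            value = parse_or()
            assert tokens[pos] == ")", "unbalanced parentheses"
            pos += 1
            return value
        pos += 1
        return tok not in absent

    result = parse_or()
    assert pos == len(tokens), f"trailing tokens in {rule!r}"
    return result


def truth_table_agrees(rule: str, genes: list[str]) -> bool:
    """Exhaustively compare implementation vs oracle over all 2^n absent sets."""
    for mask in range(2 ** len(genes)):
        absent = {g for i, g in enumerate(genes) if mask >> i & 1}
        if netcore.evaluate_gpr(rule, absent) != eval_gpr_string(rule, absent):
            return False
    return True


# ---------------------------------------------------------------------------
# Uniform rejection sampling on the flux polytope (null-space box)
# ---------------------------------------------------------------------------

def rejection_sample(model, n_points: int, seed: int,
                     max_draws: int = 2_000_000) -> pd.DataFrame:
    """Uniform points on {v: Sv=0, lb<=v<=ub} by rejection in null-space
    coordinates; only usable when the null space has dimension <= 3."""
    import scipy.linalg

    S, lb, ub, rxn_ids = _arrays(model)
    N = scipy.linalg.null_space(S)
    k = N.shape[1]
    assert k <= 3, "rejection oracle limited to <=3 free dimensions"
    # bounding box of the polytope in null-space coordinates via LPs
    zeros = np.zeros(S.shape[0])
    box = []
    for j in range(k):
        lims = []
        for sign in (1.0, -1.0):
            res = scipy.optimize.linprog(
                -sign * N[:, j], A_eq=S, b_eq=zeros,
                bounds=list(zip(lb, ub)), method="highs")
            assert res.status == 0
            lims.append(float(N[:, j] @ res.x))
        box.append((min(lims), max(lims)))
    rng = np.random.default_rng(seed)
    accepted = []
    draws = 0
    while len(accepted) < n_points and draws < max_draws:
        batch = 5000
        draws += batch
        z = np.column_stack([rng.uniform(lo, hi, batch) for lo, hi in box])
        v = z @ N.T
        ok = np.all(v >= lb - 1e-9, axis=1) & np.all(v <= ub + 1e-9, axis=1)
        accepted.extend(v[ok])
    assert len(accepted) >= n_points, "rejection sampler starved"
    return pd.DataFrame(np.asarray(accepted[:n_points]), columns=rxn_ids)
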