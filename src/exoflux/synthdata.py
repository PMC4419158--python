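"""Synthetic inputs: a toy central-carbon network and matching data tables.

The generated network is a deliberately small caricature of the
metabolism the pipeline targets: a glucose-like exchange feeding a
linear glycolysis-like chain that branches into a lactate-like secretion
and a TCA-like cycle, an electron-transport-like chain turning the
cycle's reducing equivalents plus oxygen into ATP, an ATP-consuming
biomass drain with a phosphate requirement, an ATP maintenance drain,
and configurable dead-end reactions.  GPRs mix sole genes, ``and``
complexes (one with a designated mandatory subunit, mirroring a complex
that a single absent gene can disable), and ``or`` isozyme pairs.

The exo-profile generator inverts the concentration-to-flux conversion:
``signal_t1 = signal_t0 + flux * K`` with
``K = cell_conc * dry_weight * T * volume_factor``, so with zero noise
the constraint module recovers the constructed fluxes exactly.  Signals
are in mM (unit scale 1) to keep the round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import cobra
import numpy as np
import pandas as pd

from . import netcore
from .exoconstraints import CultureParams, flux_to_conc

#: Gene whose absence alone disables the complex-I-like ETC reaction.
MANDATORY_SUBUNIT_GENE = "gCI_M"

#: Default detection limit emitted for every metabolite (mM).
DETECTION_LIMIT_MM = 0.01


class GenerationError(RuntimeError):
    """The requested toy specification yields an unusable network."""


@dataclass(frozen=True)
class ToySpec:
    """Sizes of the toy network's pathway segments."""

    n_glycolysis_steps: int = 4
    n_cycle_steps: int = 3
    n_etc_steps: int = 2
    n_isozyme_pairs: int = 1
    n_dead_ends: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glycolysis_steps < 1 or self.n_cycle_steps < 2 \
                or self.n_etc_steps < 1:
            raise ValueError("need >=1 glycolysis, >=2 cycle, >=1 ETC steps")
        if self.n_isozyme_pairs < 0 or self.n_dead_ends < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_reactions(self) -> int:
        # 5 exchanges + 5 transporters + LDH + PDH + biomass + ATPM = 14
        return 14 + self.n_glycolysis_steps + self.n_cycle_steps \
            + self.n_etc_steps + self.n_dead_ends

    @property
    def n_metabolites(self) -> int:
        # 5 extracellular + 10 fixed cytosolic + chain intermediates
        return 15 + (self.n_glycolysis_steps - 1) + (self.n_cycle_steps - 1) \
            + (self.n_etc_steps - 1) + self.n_dead_ends


def make_toy_network(spec: ToySpec = ToySpec()) -> cobra.Model:
    """Build the toy network and verify it can grow."""
    G, C, E = spec.n_glycolysis_steps, spec.n_cycle_steps, spec.n_etc_steps
    mets: dict[str, dict] = {}

    def met(mid: str) -> str:
        comp = mid.rsplit("_", 1)[-1]
        mets.setdefault(mid, {"id": mid, "name": mid, "compartment": comp})
        return mid

    reactions: list[dict] = []

    def rxn(rid: str, stoich: Mapping[str, float], gpr: str = "",
            lb: float = 0.0, ub: float = 500.0, subsystem: str = "") -> None:
        reactions.append({
            "id": rid, "name": rid,
            "stoichiometry": {met(m): c for m, c in stoich.items()},
            "lower_bound": lb, "upper_bound": ub, "gpr": gpr,
            "subsystem": subsystem,
        })

    for m in ("glc", "lac", "o2", "co2", "pi"):
        rxn(f"EX_{m}_e", {f"{m}_e": -1.0}, lb=-500.0, subsystem="Exchange")

    rxn("T_glc", {"glc_e": -1, "glc_c": 1}, gpr="gT1 or gT2",
        subsystem="Transport")
    rxn("T_lac", {"lac_c": -1, "lac_e": 1}, subsystem="Transport")
    rxn("T_o2", {"o2_e": -1, "o2_c": 1}, subsystem="Transport")
    rxn("T_co2", {"co2_c": -1, "co2_e": 1}, subsystem="Transport")
    rxn("T_pi", {"pi_e": -1, "pi_c": 1}, subsystem="Transport")

    # glycolysis-like chain: glc_c -> ... -> 2 pyr_c + 2 atp_c
    chain = ["glc_c"] + [f"gly_{i}_c" for i in range(1, G)] + ["pyr_c"]
    for i in range(G):
        gpr = f"gGLY{i + 1}a or gGLY{i + 1}b" if i < spec.n_isozyme_pairs \
            else f"gGLY{i + 1}"
        if i == G - 1:
            stoich = {chain[i]: -1, "pyr_c": 2.0, "atp_c": 2.0}
        else:
            stoich = {chain[i]: -1, chain[i + 1]: 1.0}
        rxn(f"GLY{i + 1}", stoich, gpr=gpr, subsystem="Glycolysis")

    rxn("LDH", {"pyr_c": -1, "lac_c": 1}, gpr="gLDH", subsystem="Fermentation")
    rxn("PDH", {"pyr_c": -1, "accoa_c": 1, "nadh_c": 1, "co2_c": 1},
        gpr="gPDH1 and gPDH2", subsystem="TCA")

    # TCA-like cycle: accoa + oaa -> t_1 -> ... -> oaa, releasing NADH
    cyc = [f"tca_{i}_c" for i in range(1, C)]
    rxn("TCA1", {"accoa_c": -1, "oaa_c": -1, cyc[0]: 1}, gpr="gTCA1",
        subsystem="TCA")
    for i in range(1, C):
        src = cyc[i - 1]
        dst = cyc[i] if i < C - 1 else "oaa_c"
        rxn(f"TCA{i + 1}", {src: -1, dst: 1, "nadh_c": 1},
            gpr=f"gTCA{i + 1}", subsystem="TCA")

    # ETC-like chain: nadh + 1/2 o2 -> ATP, complex I with mandatory subunit
    eint = [f"etc_{i}_c" for i in range(1, E)]
    for i in range(E):
        if E == 1:
            stoich = {"nadh_c": -1, "o2_c": -0.5, "atp_c": 2.0}
        elif i == 0:
            stoich = {"nadh_c": -1, "o2_c": -0.5, eint[0]: 1, "atp_c": 1.0}
        elif i < E - 1:
            stoich = {eint[i - 1]: -1, eint[i]: 1, "atp_c": 1.0}
        else:
            stoich = {eint[i - 1]: -1, "atp_c": 1.0}
        gpr = f"gCI_A and gCI_B and {MANDATORY_SUBUNIT_GENE}" if i == 0 \
            else f"gETC{i + 1}a and gETC{i + 1}b"
        rxn(f"ETC{i + 1}", stoich, gpr=gpr, subsystem="OxPhos")

    rxn("BIOMASS", {"atp_c": -3.0, "pyr_c": -1.0, "pi_c": -0.5},
        subsystem="Biomass")
    rxn("ATPM", {"atp_c": -1.0}, subsystem="Maintenance")

    for i in range(1, spec.n_dead_ends + 1):
        rxn(f"DEADEND{i}", {"pyr_c": -1, f"dead_{i}_c": 1},
            gpr=f"gDEAD{i}", subsystem="DeadEnd")

    model = netcore.model_from_dict({
        "id": f"toy_G{G}C{C}E{E}",
        "compartments": {"c": "cytosol", "e": "extracellular"},
        "metabolites": list(mets.values()),
        "reactions": reactions,
        "objective": "BIOMASS",
    })
    sol = netcore.fba(model)
    if not sol.ok or sol.objective_value <= 0:
        raise GenerationError("toy specification yields no feasible growth")
    return model


def glycolysis_reactions(model: cobra.Model) -> list[str]:
    return [r.id for r in model.reactions if r.subsystem == "Glycolysis"]


# ---------------------------------------------------------------------------
# Synthetic ground truth and data tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTruth:
    """Designed exchange fluxes and gene sets for a two-condition study.

    Default fluxes make condition A glycolytic (double the glucose-like
    uptake and quadruple the lactate-like secretion of B), the shape the
    pipeline is meant to resolve.  Fluxes follow the COBRA sign
    convention (negative = uptake).  The phosphate-like drain is sized
    below the 5 % detection band, so its constructed call is
    "unchanged".
    """

    fluxes_A: Mapping[str, float] = field(
        default_factory=lambda: {"glc": -12.0, "lac": 16.0, "pi": -0.05})
    fluxes_B: Mapping[str, float] = field(
        default_factory=lambda: {"glc": -6.0, "lac": 4.0, "pi": -0.05})
    medium_mM: Mapping[str, float] = field(
        default_factory=lambda: {"glc": 11.11, "lac": 0.0, "pi": 1.0})
    absent_A: frozenset[str] = frozenset({"gT2"})
    absent_B: frozenset[str] = frozenset({"gT2"})
    up_genes: tuple[str, ...] = ()       # defaulted from the model if empty
    down_genes: tuple[str, ...] = ()
    noise_sd: float = 0.0
    detection_limit_mM: float = DETECTION_LIMIT_MM

    def expected_calls(self, params: CultureParams,
                       threshold: float = 0.05) -> dict[str, dict[str, str]]:
        """Constructed classification per condition from the same signal
        arithmetic the generator uses (noise-free)."""
        out: dict[str, dict[str, str]] = {}
        for cond, fluxes in (("A", self.fluxes_A), ("B", self.fluxes_B)):
            calls = {}
            for met, flux in fluxes.items():
                t0 = self._t0(met)
                change = flux_to_conc(flux, params) / t0
                if change < -threshold:
                    calls[met] = "uptake"
                elif change > threshold:
                    calls[met] = "secretion"
                else:
                    calls[met] = "unchanged"
            out[cond] = calls
        return out

    def _t0(self, met: str) -> float:
        conc = self.medium_mM.get(met, 0.0)
        return conc if conc > 0 else self.detection_limit_mM


def default_truth_genes(model: cobra.Model) -> tuple[tuple[str, ...],
                                                     tuple[str, ...]]:
    """Up = glycolysis + fermentation genes, down = ETC genes."""
    up, down = [], []
    for rxn in model.reactions:
        genes = sorted(g.id for g in rxn.genes)
        if rxn.subsystem in {"Glycolysis", "Fermentation"}:
            up.extend(genes)
        elif rxn.subsystem == "OxPhos":
            down.extend(genes)
    return tuple(dict.fromkeys(up)), tuple(dict.fromkeys(down))


def simulate_exo_profiles(model: cobra.Model, truth: SyntheticTruth,
                          params: CultureParams, seed: int = 0,
                          ) -> pd.DataFrame:
    """Two-time-point signals for conditions A, B, and the cell-free control.

    ``signal_t1 = signal_t0 + flux * K`` plus Gaussian noise; the control
    is drift-free plus noise.  Signals driven negative are clipped at 0.
    """
    rng = np.random.default_rng(seed)
    mets = sorted(set(truth.fluxes_A) | set(truth.fluxes_B))
    for met in mets:
        if netcore.find_exchange(model, met) is None:
            raise ValueError(f"truth flux for {met!r} has no model exchange")
    rows = []
    for cond in ("A", "B", "control"):
        fluxes = {"A": truth.fluxes_A, "B": truth.fluxes_B,
                  "control": {}}[cond]
        for met in mets:
            t0 = truth._t0(met)
            drift = flux_to_conc(fluxes.get(met, 0.0), params)
            t1 = t0 + drift + rng.normal(0.0, truth.noise_sd) \
                if truth.noise_sd > 0 else t0 + drift
            if t1 < 0:
                import logging
                logging.getLogger(__name__).warning(
                    "%s (%s): signal driven negative, clipped to 0", met, cond)
                t1 = 0.0
            rows.append({
                "metabolite_id": met, "condition": cond,
                "signal_t0": t0, "signal_t1": t1,
                "detection_limit_mM": truth.detection_limit_mM,
                "medium_conc_mM": truth.medium_mM.get(met, 0.0),
            })
    return pd.DataFrame(rows)


def simulate_expression(model: cobra.Model, truth: SyntheticTruth,
                        seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Presence/absence call tables per condition plus a DEG table.

    Returns ``(calls_A, calls_B, degs)``; DEG rows carry FDR values
    drawn below the 0.05 cutoff.  Up/down gene sets default to
    glycolytic/ETC genes when the truth leaves them empty.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(g.id for g in model.genes)

    def _calls(absent: frozenset[str]) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": genes,
            "call": ["absent" if g in absent else "present" for g in genes],
            "pvalue": [round(float(rng.uniform(0.05, 0.9)), 4)
                       if g in absent else
                       round(float(rng.uniform(1e-6, 0.049)), 6)
                       for g in genes],
        })

    up, down = truth.up_genes, truth.down_genes
    if not up and not down:
        up, down = default_truth_genes(model)
    deg_rows = [{"gene_id": g, "direction": "up",
                 "fdr": round(float(rng.uniform(1e-6, 0.049)), 6)}
                for g in up]
    deg_rows += [{"gene_id": g, "direction": "down",
                  "fdr": round(float(rng.uniform(1e-6, 0.049)), 6)}
                 for g in down]
    degs = pd.DataFrame(deg_rows, columns=["gene_id", "direction", "fdr"])
    return _calls(truth.absent_A), _calls(truth.absent_B), degs


__all__ = ["DETECTION_LIMIT_MM", "GenerationError", "MANDATORY_SUBUNIT_GENE",
           "SyntheticTruth", "ToySpec", "default_truth_genes",
           "glycolysis_reactions", "make_toy_network", "simulate_exo_profiles",
           "simulate_expression"]
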