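"""Exo-metabolomic measurements to exchange-reaction bounds.

Two-time-point spent-medium profiles (signal at 0 h and at the end of the
culture, for each cell line and for a cell-free control) are turned into

* qualitative calls per metabolite — uptake, secretion, unchanged, or
  excluded — from the change relative to the control,
* qualitative exchange bounds: medium concentration and detection limit
  converted to fluxes via the culture parameters, enforcing a minimum
  uptake or secretion in the observed direction, closing all unmeasured
  exchanges except a whitelist of basic medium components,
* quantitative bounds on a model pair: fold-change slopes and slope
  ratios restrict the weaker consumer's supply and raise the stronger
  secretor's minimum so the in-silico bound ratio matches the in-vitro
  signal ratio.

Concentrations are mM, fluxes mmol/gDW/h, signals arbitrary MS units
(the generator uses mM so the conversion is exactly invertible).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import cobra
import pandas as pd

from . import netcore
from .netcore import BOUND_CAP

log = logging.getLogger(__name__)


class DataError(ValueError):
    """A measurement table is missing or inconsistent."""


class ConstraintConflictError(ValueError):
    """A bound assignment would contradict the data or invert lb <= ub."""


# ---------------------------------------------------------------------------
# Culture parameters and flux conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CultureParams:
    """Culture-scale quantities converting concentrations to specific fluxes.

    cell_conc
        viable cells per mL at the end of the experiment.
    duration_h
        experiment length T in hours.
    dry_weight_g
        dry weight per cell in grams (see :func:`derive_dry_weight`).
    growth_rate_per_h
        measured exponential growth rate, 1/h; the biomass reaction is
        boxed to ±``growth_tolerance`` around it.
    oxygen_lb
        fixed oxygen-uptake lower bound, mmol/gDW/h (literature value).
    volume_factor
        mL-to-L conversion in the flux formula; kept explicit because it
        is the difference between the two printed forms of the formula.
    """

    cell_conc: float = 2.17e6
    duration_h: float = 48.0
    dry_weight_g: float = 3.645e-12
    growth_rate_per_h: float = 0.035
    growth_tolerance: float = 0.20
    oxygen_lb: float = -2.346
    volume_factor: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("cell_conc", "duration_h", "dry_weight_g",
                     "growth_rate_per_h", "volume_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.growth_tolerance < 1.0):
            raise ValueError("growth_tolerance must lie in (0, 1)")
        if self.oxygen_lb >= 0:
            raise ValueError("oxygen_lb must be negative (uptake)")


def derive_dry_weight(ref_mass_pg: float, ref_volume_um3: float,
                      cell_volume_um3: float) -> tuple[float, float]:
    """Scale a reference cell's dry mass to another cell type by volume.

    Returns ``(volume_ratio, dry_weight_pg)`` where
    ``volume_ratio = ref_volume / cell_volume`` and
    ``dry_weight_pg = ref_mass_pg / volume_ratio``.  With the U2OS
    reference (60 pg, 4000 um^3) and a 243 um^3 lymphoblast this gives
    16.46 and 3.645 pg.
    """
    if min(ref_mass_pg, ref_volume_um3, cell_volume_um3) <= 0:
        raise ValueError("all inputs must be positive")
    volume_ratio = ref_volume_um3 / cell_volume_um3
    return volume_ratio, ref_mass_pg / volume_ratio


def conc_to_flux(conc_mM: float, params: CultureParams) -> float:
    """Convert a medium concentration (mM) to a specific flux (mmol/gDW/h).

    Flux = conc / (cell_conc * dry_weight * T * volume_factor); the
    volume factor converts the per-mL cell concentration to per-L so
    units cancel to mmol per gram dry weight per hour.
    """
    if conc_mM < 0:
        raise ValueError("concentration must be non-negative")
    denom = (params.cell_conc * params.dry_weight_g * params.duration_h
             * params.volume_factor)
    if denom == 0:
        raise ValueError("conversion denominator is zero")
    return conc_mM / denom


def flux_to_conc(flux: float, params: CultureParams) -> float:
    """Inverse of :func:`conc_to_flux` (used by the synthetic generator)."""
    return flux * (params.cell_conc * params.dry_weight_g * params.duration_h
                   * params.volume_factor)


# ---------------------------------------------------------------------------
# Measurements and classification
# ---------------------------------------------------------------------------

CONTROL_CONDITION = "control"

#: Metabolites whose medium signal is dominated by spontaneous GlutaMax
#: breakdown; their exchanges are left unconstrained.
GLUTAMAX_ARTIFACTS = frozenset({"gln__L", "ala__L"})

#: Metabolites not producible by the modelled cells (vitamins, fungal or
#: plant sugars); excluded from constraint setting.
NON_PRODUCIBLE = frozenset({"ribflv", "tre", "etha4p", "eryth", "fru"})

#: Exchanges never quantitatively adjusted (inconclusive or essential).
SLOPE_SKIP = frozenset({
    "pi", "his__L", "cys__L", "val__L", "met__L", "ala__L", "gln__L",
})

#: Exchanges kept open regardless of the measurements: ions, basic medium
#: compounds, gases, essential amino acids, and cysteine.
DEFAULT_WHITELIST = frozenset({
    "pi", "h", "h2o", "co2", "o2", "nh4", "na1", "k", "cl", "ca2", "fe2",
    "so4", "his__L", "ile__L", "leu__L", "lys__L", "met__L", "phe__L",
    "thr__L", "trp__L", "val__L", "cys__L",
})


@dataclass(frozen=True)
class ExoMeasurement:
    """Two-time-point signal for one metabolite under one condition."""

    metabolite_id: str
    condition: str
    signal_t0: float
    signal_t1: float
    detection_limit_mM: float
    medium_conc_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.signal_t0 < 0 or self.signal_t1 < 0:
            raise ValueError(f"{self.metabolite_id}: negative signal")
        if self.detection_limit_mM <= 0:
            raise ValueError(f"{self.metabolite_id}: detection limit must be > 0")

    @property
    def fold_change(self) -> float:
        if self.signal_t0 <= 0:
            raise DataError(
                f"{self.metabolite_id} ({self.condition}): zero t0 signal, "
                "fold change undefined")
        return self.signal_t1 / self.signal_t0

    @property
    def fold_change_clamped(self) -> float:
        """Fold change with both signals floored at the detection limit,
        so values below detection cannot produce zero or undefined FCs."""
        floor = self.detection_limit_mM
        if self.signal_t1 < floor or self.signal_t0 < floor:
            log.warning("%s (%s): signal below detection limit, clamped",
                        self.metabolite_id, self.condition)
        return max(self.signal_t1, floor) / max(self.signal_t0, floor)


@dataclass(frozen=True)
class ExchangeClass:
    """Qualitative call for one metabolite exchange."""

    metabolite_id: str
    call: str  # uptake | secretion | unchanged | excluded
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if self.call not in {"uptake", "secretion", "unchanged", "excluded"}:
            raise ValueError(f"unknown call {self.call!r}")
        if self.call == "excluded" and not self.excluded_reason:
            raise ValueError("excluded calls require a reason")


@dataclass(frozen=True)
class ExclusionRules:
    """Which metabolites are excluded from constraint setting and why."""

    glutamax_artifacts: frozenset[str] = GLUTAMAX_ARTIFACTS
    non_producible: frozenset[str] = NON_PRODUCIBLE


def read_measurements(path) -> list[ExoMeasurement]:
    """Read the metabolomics TSV (one row per metabolite x condition)."""
    df = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "condition", "signal_t0", "signal_t1",
                "detection_limit_mM", "medium_conc_mM"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"metabolomics table missing columns {sorted(missing)}")
    return [
        ExoMeasurement(
            metabolite_id=str(r.metabolite_id), condition=str(r.condition),
            signal_t0=float(r.signal_t0), signal_t1=float(r.signal_t1),
            detection_limit_mM=float(r.detection_limit_mM),
            medium_conc_mM=float(r.medium_conc_mM),
        )
        for r in df.itertuples()
    ]


def measurements_to_frame(measurements: Iterable[ExoMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in measurements])


def _index_by_condition(measurements: Iterable[ExoMeasurement],
                        condition: str) -> dict[str, ExoMeasurement]:
    out: dict[str, ExoMeasurement] = {}
    for m in measurements:
        if m.condition == condition:
            out[m.metabolite_id] = m
    return out


def relative_change(cell: ExoMeasurement, control: ExoMeasurement,
                    mode: str = "fc_ratio") -> float:
    """Signed change of the cell-line profile relative to the control.

    ``fc_ratio`` (default): FC_cell / FC_control - 1.
    ``difference``: percent change of the cell signal minus percent
    change of the control signal.  The two agree whenever the control is
    drift-free; the published text does not pin the arithmetic down, so
    both are offered.
    """
    if mode == "fc_ratio":
        return cell.fold_change_clamped / control.fold_change_clamped - 1.0
    if mode == "difference":
        return cell.fold_change_clamped - control.fold_change_clamped
    raise ValueError(f"unknown change mode {mode!r}")


def classify_exchanges(measurements: Sequence[ExoMeasurement], condition: str,
                       model: cobra.Model, threshold: float = 0.05,
                       rules: ExclusionRules = ExclusionRules(),
                       change_mode: str = "fc_ratio") -> list[ExchangeClass]:
    """Call uptake/secretion per metabolite from the control-relative change.

    A decrease of the cell-line signal exceeding *threshold* relative to
    the cell-free control is called uptake, an increase secretion, and
    anything within the band unchanged.  Metabolites absent from the
    model, non-producible compounds, and GlutaMax breakdown products are
    excluded with a reason.
    """
    cell = _index_by_condition(measurements, condition)
    control = _index_by_condition(measurements, CONTROL_CONDITION)
    if not cell:
        raise DataError(f"no measurements for condition {condition!r}")
    classes = []
    for met_id, meas in cell.items():
        if met_id in rules.glutamax_artifacts:
            classes.append(ExchangeClass(met_id, "excluded",
                                         "GlutaMax breakdown"))
            continue
        if netcore.find_exchange(model, met_id) is None:
            classes.append(ExchangeClass(met_id, "excluded", "not in model"))
            continue
        if met_id in rules.non_producible:
            classes.append(ExchangeClass(met_id, "excluded", "non-producible"))
            continue
        ctrl = control.get(met_id)
        if ctrl is None:
            raise DataError(f"{met_id}: missing control measurement")
        change = relative_change(meas, ctrl, mode=change_mode)
        if change < -threshold:
            call = "uptake"
        elif change > threshold:
            call = "secretion"
        else:
            call = "unchanged"
        classes.append(ExchangeClass(met_id, call))
    return classes


# ---------------------------------------------------------------------------
# Qualitative bounds
# ---------------------------------------------------------------------------

def apply_qualitative_bounds(model: cobra.Model,
                             classes: Sequence[ExchangeClass],
                             measurements: Sequence[ExoMeasurement],
                             condition: str,
                             params: CultureParams,
                             whitelist: Iterable[str] = DEFAULT_WHITELIST,
                             oxygen_id: str = "o2",
                             ) -> tuple[cobra.Model, pd.DataFrame]:
    """Set exchange and biomass bounds from the qualitative calls.

    Per call, on the COBRA sign convention (negative flux = uptake):

    * uptake: lb = -flux(medium conc), ub = -flux(detection limit) — the
      detection limit enforces a minimum uptake;
    * secretion: lb = +flux(detection limit), ub = +500 — a minimum
      secretion with unconstrained capacity;
    * every other exchange is closed to (0, 0) except whitelisted basic
      medium components, which keep supply open, and GlutaMax artifacts,
      which stay untouched;
    * biomass is boxed to growth_rate x (1 ∓ growth_tolerance);
    * the oxygen exchange lower bound is fixed at ``params.oxygen_lb``.

    Returns a modified copy of the model and a bounds report
    (exchange_id, lb, ub, provenance).
    """
    model = model.copy()
    whitelist = set(whitelist)
    by_met = {c.metabolite_id: c for c in classes}
    meas = _index_by_condition(measurements, condition)
    report_rows = []

    def _flux(conc: float) -> float:
        return conc_to_flux(conc, params)

    for rxn in netcore.exchanges(model):
        met_e = next(iter(rxn.metabolites)).id
        met = met_e[:-2] if met_e.endswith("_e") else met_e
        cls = by_met.get(met)
        provenance = None
        if met == oxygen_id:
            rxn.bounds = (params.oxygen_lb, min(rxn.upper_bound, BOUND_CAP))
            provenance = "oxygen"
        elif cls is not None and cls.call == "uptake":
            m = meas[met]
            if m.medium_conc_mM <= 0 and met not in whitelist:
                raise ConstraintConflictError(
                    f"{met}: uptake called but no medium concentration")
            lb = -_flux(m.medium_conc_mM) if m.medium_conc_mM > 0 else -BOUND_CAP
            ub = -_flux(m.detection_limit_mM)
            if lb > ub:
                raise ConstraintConflictError(
                    f"{met}: uptake bounds inverted ({lb:.4g} > {ub:.4g})")
            rxn.bounds = (lb, ub)
            provenance = "qualitative"
        elif cls is not None and cls.call == "secretion":
            lb = _flux(meas[met].detection_limit_mM)
            rxn.bounds = (lb, BOUND_CAP)
            provenance = "qualitative"
        elif cls is not None and cls.call == "excluded" and \
                cls.excluded_reason == "GlutaMax breakdown":
            provenance = "unconstrained"  # leave the exchange as-is
        elif met in whitelist:
            m = meas.get(met)
            lb = -_flux(m.medium_conc_mM) if (m and m.medium_conc_mM > 0) \
                else -BOUND_CAP
            rxn.bounds = (lb, BOUND_CAP)
            provenance = "whitelist"
        else:
            rxn.bounds = (0.0, 0.0)
            provenance = "closed"
        report_rows.append({"exchange_id": rxn.id, "lb": rxn.lower_bound,
                            "ub": rxn.upper_bound, "provenance": provenance})

    biomass = netcore.objective_reaction(model)
    mu, tol = params.growth_rate_per_h, params.growth_tolerance
    biomass.bounds = (mu * (1 - tol), mu * (1 + tol))
    report_rows.append({"exchange_id": biomass.id, "lb": biomass.lower_bound,
                        "ub": biomass.upper_bound, "provenance": "biomass"})
    report = pd.DataFrame(report_rows,
                          columns=["exchange_id", "lb", "ub", "provenance"])
    return model, report


# ---------------------------------------------------------------------------
# Quantitative (slope-ratio) bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopeRatioRecord:
    """Fold-change slopes of two conditions and their ratio for one metabolite."""

    metabolite_id: str
    fc_A: float
    fc_B: float
    fc_medium: float
    slope_A: float
    slope_B: float
    slope_ratio: float  # slope_A / slope_B
    skip: bool = False


def slope_ratios(measurements: Sequence[ExoMeasurement],
                 condition_A: str, condition_B: str,
                 skip: Iterable[str] = SLOPE_SKIP,
                 detection_clamp: bool = True) -> list[SlopeRatioRecord]:
    """Per-metabolite fold changes, slopes, and the A:B slope ratio.

    FC = signal_t1 / signal_t0 per series; Slope = FC_cellline /
    FC_medium; Slope Ratio = slope_A / slope_B.  Metabolites on the skip
    list (phosphate, essential amino acids, GlutaMax artifacts) are
    emitted with ``skip=True`` so downstream bound adjustment leaves
    them alone.  Signals below the detection limit are clamped to it
    (with a warning) before computing fold changes.
    """
    skip = set(skip)
    a = _index_by_condition(measurements, condition_A)
    b = _index_by_condition(measurements, condition_B)
    ctrl = _index_by_condition(measurements, CONTROL_CONDITION)
    records = []
    for met_id in sorted(set(a) & set(b) & set(ctrl)):
        series = []
        ok = True
        for meas in (a[met_id], b[met_id], ctrl[met_id]):
            if detection_clamp and 0 < meas.signal_t1 < meas.detection_limit_mM:
                log.warning("%s (%s): t1 signal below detection limit, clamped",
                            met_id, meas.condition)
                meas = replace(meas, signal_t1=meas.detection_limit_mM)
            if meas.signal_t0 <= 0:
                log.warning("%s (%s): zero t0 signal, record dropped",
                            met_id, meas.condition)
                ok = False
                break
            series.append(meas.fold_change)
        if not ok:
            continue
        fc_a, fc_b, fc_m = series
        slope_a, slope_b = fc_a / fc_m, fc_b / fc_m
        records.append(SlopeRatioRecord(
            metabolite_id=met_id, fc_A=fc_a, fc_B=fc_b, fc_medium=fc_m,
            slope_A=slope_a, slope_B=slope_b, slope_ratio=slope_a / slope_b,
            skip=met_id in skip))
    return records


def apply_quantitative_bounds(model_A: cobra.Model, model_B: cobra.Model,
                              records: Sequence[SlopeRatioRecord],
                              classes_A: Sequence[ExchangeClass],
                              classes_B: Sequence[ExchangeClass],
                              ) -> tuple[cobra.Model, cobra.Model, pd.DataFrame]:
    """Impose the in-vitro exchange ratios on a model pair's bounds.

    Only metabolites commonly uptaken or commonly secreted by both
    conditions are adjusted.  With the slope ratio r = slope_A/slope_B
    and bound factor x = max(r, 1/r) >= 1:

    * common uptake — the stronger consumer has the *smaller* slope
      (its signal drops further); the weaker consumer's supply is
      restricted to |lb_weak| = |lb_strong| / x;
    * common secretion — the stronger secretor has the *larger* slope;
      its secretion minimum is raised to lb_strong = x * lb_weak.

    Skip-flagged records and uniquely exchanged metabolites are left
    untouched.  Returns modified copies plus an adjustment report.
    """
    model_A, model_B = model_A.copy(), model_B.copy()
    call_a = {c.metabolite_id: c.call for c in classes_A}
    call_b = {c.metabolite_id: c.call for c in classes_B}
    rows = []
    for rec in records:
        met = rec.metabolite_id
        if rec.skip or call_a.get(met) != call_b.get(met) \
                or call_a.get(met) not in {"uptake", "secretion"}:
            continue
        rxn_a = netcore.find_exchange(model_A, met)
        rxn_b = netcore.find_exchange(model_B, met)
        if rxn_a is None or rxn_b is None:
            continue
        r = rec.slope_ratio
        if r <= 0 or math.isclose(r, 1.0, rel_tol=1e-12):
            continue
        x = max(r, 1.0 / r)
        if call_a[met] == "uptake":
            # smaller slope = deeper signal drop = stronger consumer
            strong, weak = (rxn_a, rxn_b) if rec.slope_A < rec.slope_B \
                else (rxn_b, rxn_a)
            new_lb = strong.lower_bound / x
            if new_lb > weak.upper_bound:
                raise ConstraintConflictError(
                    f"{met}: restricted uptake lb {new_lb:.4g} crosses ub "
                    f"{weak.upper_bound:.4g}")
            weak.lower_bound = new_lb
            adjusted = "B" if weak is rxn_b else "A"
        else:  # common secretion
            strong, weak = (rxn_a, rxn_b) if rec.slope_A > rec.slope_B \
                else (rxn_b, rxn_a)
            new_lb = x * weak.lower_bound
            if new_lb > strong.upper_bound:
                raise ConstraintConflictError(
                    f"{met}: raised secretion lb {new_lb:.4g} crosses ub "
                    f"{strong.upper_bound:.4g}")
            strong.lower_bound = new_lb
            adjusted = "A" if strong is rxn_a else "B"
        rows.append({"metabolite_id": met, "call": call_a[met],
                     "slope_ratio": r, "factor": x, "adjusted_model": adjusted,
                     "lb_A": rxn_a.lower_bound, "lb_B": rxn_b.lower_bound})
    report = pd.DataFrame(rows, columns=["metabolite_id", "call", "slope_ratio",
                                         "factor", "adjusted_model",
                                         "lb_A", "lb_B"])
    return model_A, model_B, report


__all__ = [
    "CONTROL_CONDITION", "ConstraintConflictError", "CultureParams",
    "DataError", "DEFAULT_WHITELIST", "ExchangeClass", "ExclusionRules",
    "ExoMeasurement", "GLUTAMAX_ARTIFACTS", "NON_PRODUCIBLE", "SLOPE_SKIP",
    "SlopeRatioRecord", "apply_qualitative_bounds",
    "apply_quantitative_bounds", "classify_exchanges", "conc_to_flux",
    "derive_dry_weight", "flux_to_conc", "measurements_to_frame",
    "read_measurements", "relative_change", "slope_ratios",
]
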