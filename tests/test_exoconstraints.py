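"""Dry-weight scaling, flux conversion, classification, and bound setting."""

import pytest
from hypothesis import given, settings, strategies as st

from exoflux import exoconstraints as exo, netcore

from conftest import chain_model


def meas(met, cond, t0, t1, det=0.01, medium=0.0):
    return exo.ExoMeasurement(met, cond, t0, t1, det, medium)


# ---------------------------------------------------------------------------
# Dry weight and flux conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("args, ratio, dw", [
    ((60, 4000, 243), 16.46, 3.645),   # lymphoblast scaled from U2OS
    ((60, 4000, 4000), 1.0, 60.0),
    ((100, 1000, 250), 4.0, 25.0),
])
def test_dry_weight_volume_scaling(args, ratio, dw):
    got_ratio, got_dw = exo.derive_dry_weight(*args)
    assert got_ratio == pytest.approx(ratio, abs=5e-3)
    assert got_dw == pytest.approx(dw, abs=5e-4)


def test_dry_weight_rejects_non_positive_input():
    with pytest.raises(ValueError):
        exo.derive_dry_weight(60, 0, 243)


def test_conc_to_flux_zero_is_zero(params_A):
    assert exo.conc_to_flux(0.0, params_A) == 0.0


def test_conc_to_flux_reproduces_hand_arithmetic(params_A):
    # 11.11 / (2.17e6 * 3.645e-12 * 48 * 1000)
    assert exo.conc_to_flux(11.11, params_A) == pytest.approx(29.26, abs=0.01)


def test_conc_to_flux_halves_when_cell_conc_doubles(params_A):
    import dataclasses
    doubled = dataclasses.replace(params_A, cell_conc=2 * params_A.cell_conc)
    assert exo.conc_to_flux(10.0, doubled) == pytest.approx(
        exo.conc_to_flux(10.0, params_A) / 2)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(conc=st.floats(0.001, 100), factor=st.floats(1.1, 10))
def test_conc_to_flux_linearity_and_inverse_proportionality(conc, factor):
    import dataclasses
    p = exo.CultureParams()
    base = exo.conc_to_flux(conc, p)
    assert exo.conc_to_flux(conc * factor, p) == pytest.approx(base * factor)
    for name in ("cell_conc", "dry_weight_g", "duration_h"):
        scaled = dataclasses.replace(p, **{name: getattr(p, name) * factor})
        assert exo.conc_to_flux(conc, scaled) == pytest.approx(base / factor)


def test_flux_to_conc_inverts_conc_to_flux(params_A):
    assert exo.flux_to_conc(exo.conc_to_flux(5.0, params_A), params_A) \
        == pytest.approx(5.0)


def test_culture_params_validation():
    with pytest.raises(ValueError):
        exo.CultureParams(growth_tolerance=1.5)
    with pytest.raises(ValueError):
        exo.CultureParams(oxygen_lb=1.0)
    with pytest.raises(ValueError):
        exo.CultureParams(cell_conc=0)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ab_model():
    return chain_model()


@pytest.mark.parametrize("t1_cell, expected", [
    (80.0, "uptake"),      # 20 % drop vs flat control
    (103.0, "unchanged"),  # 3 % rise, inside the 5 % band
    (110.0, "secretion"),
])
def test_classification_against_flat_control(ab_model, t1_cell, expected):
    rows = [meas("a", "A", 100, t1_cell), meas("a", "control", 100, 100)]
    (call,) = exo.classify_exchanges(rows, "A", ab_model)
    assert call.call == expected


def test_control_drift_is_discounted(ab_model):
    # cell and control both drop 20 %: no evidence of uptake
    rows = [meas("a", "A", 100, 80), meas("a", "control", 100, 80)]
    (call,) = exo.classify_exchanges(rows, "A", ab_model)
    assert call.call == "unchanged"


def test_glutamax_artifacts_are_excluded(ab_model):
    rows = [meas("gln__L", "A", 100, 150),
            meas("gln__L", "control", 100, 100)]
    (call,) = exo.classify_exchanges(rows, "A", ab_model)
    assert call.call == "excluded"
    assert "GlutaMax" in call.excluded_reason


def test_metabolite_without_model_exchange_is_excluded(ab_model):
    rows = [meas("mystery", "A", 100, 50),
            meas("mystery", "control", 100, 100)]
    (call,) = exo.classify_exchanges(rows, "A", ab_model)
    assert (call.call, call.excluded_reason) == ("excluded", "not in model")


def test_non_producible_compound_is_excluded(ab_model):
    import cobra
    model = ab_model.copy()
    rib = cobra.Metabolite("ribflv_e", compartment="e")
    rxn = cobra.Reaction("EX_ribflv_e", lower_bound=-500, upper_bound=500)
    model.add_reactions([rxn])
    rxn.add_metabolites({rib: -1})
    rows = [meas("ribflv", "A", 100, 120), meas("ribflv", "control", 100, 100)]
    (call,) = exo.classify_exchanges(rows, "A", model)
    assert (call.call, call.excluded_reason) == ("excluded", "non-producible")


def test_missing_control_measurement_names_metabolite(ab_model):
    rows = [meas("a", "A", 100, 80)]
    with pytest.raises(exo.DataError, match="a"):
        exo.classify_exchanges(rows, "A", ab_model)


def test_change_modes_agree_with_driftfree_control(ab_model):
    rows = [meas("a", "A", 100, 80), meas("a", "control", 100, 100)]
    for mode in ("fc_ratio", "difference"):
        (call,) = exo.classify_exchanges(rows, "A", ab_model, change_mode=mode)
        assert call.call == "uptake"


# ---------------------------------------------------------------------------
# Qualitative bounds
# ---------------------------------------------------------------------------

def _bounded(model, rows, condition="A", whitelist=(), **params_kw):
    params = exo.CultureParams(**params_kw)
    classes = exo.classify_exchanges(rows, condition, model)
    return exo.apply_qualitative_bounds(model, classes, rows, condition,
                                        params, whitelist=whitelist)


def test_secreted_metabolite_gets_detection_limit_floor(ab_model, params_A):
    rows = [meas("a", "A", 100, 150, det=0.01), meas("a", "control", 100, 100)]
    model, report = _bounded(ab_model, rows)
    rxn = model.reactions.EX_a_e
    floor = exo.conc_to_flux(0.01, params_A)
    assert rxn.lower_bound == pytest.approx(floor)
    assert rxn.upper_bound == 500.0
    assert 0 < rxn.lower_bound < rxn.upper_bound


def test_uptaken_metabolite_bounds_are_negative_window(ab_model, params_A):
    rows = [meas("a", "A", 100, 80, det=0.01, medium=11.11),
            meas("a", "control", 100, 100)]
    model, _ = _bounded(ab_model, rows)
    rxn = model.reactions.EX_a_e
    assert rxn.lower_bound == pytest.approx(-exo.conc_to_flux(11.11, params_A))
    assert rxn.upper_bound == pytest.approx(-exo.conc_to_flux(0.01, params_A))
    assert rxn.lower_bound < rxn.upper_bound < 0


def test_biomass_window_is_growth_rate_with_20pct_tolerance(ab_model):
    rows = [meas("a", "A", 100, 80, medium=11.11),
            meas("a", "control", 100, 100)]
    model, _ = _bounded(ab_model, rows, growth_rate_per_h=0.035)
    assert model.reactions.BIO.bounds == (pytest.approx(0.028),
                                          pytest.approx(0.042))


def test_unmeasured_non_whitelist_exchange_is_closed():
    model = chain_model()
    rows = [meas("other", "A", 100, 100), meas("other", "control", 100, 100)]
    classes = exo.classify_exchanges(rows, "A", model)
    bounded, report = exo.apply_qualitative_bounds(
        model, classes, rows, "A", exo.CultureParams(), whitelist=())
    assert bounded.reactions.EX_a_e.bounds == (0.0, 0.0)
    tag = report.set_index("exchange_id").loc["EX_a_e", "provenance"]
    assert tag == "closed"


def test_whitelisted_exchange_keeps_supply_open():
    model = chain_model()
    rows = [meas("a", "A", 100, 100, medium=2.0),
            meas("a", "control", 100, 100)]
    bounded, report = _bounded(model, rows, whitelist={"a"})
    rxn = bounded.reactions.EX_a_e
    assert rxn.lower_bound == pytest.approx(-exo.conc_to_flux(
        2.0, exo.CultureParams()))
    assert rxn.upper_bound == 500.0


def test_uptake_without_medium_concentration_conflicts(ab_model):
    rows = [meas("a", "A", 100, 80, medium=0.0),
            meas("a", "control", 100, 100)]
    with pytest.raises(exo.ConstraintConflictError, match="a"):
        _bounded(ab_model, rows)


def test_oxygen_lower_bound_is_fixed():
    model = chain_model()
    import cobra
    o2 = cobra.Metabolite("o2_e", compartment="e")
    ex = cobra.Reaction("EX_o2_e", lower_bound=-500, upper_bound=500)
    model.add_reactions([ex])
    ex.add_metabolites({o2: -1})
    rows = [meas("a", "A", 100, 100), meas("a", "control", 100, 100)]
    bounded, report = _bounded(model, rows)
    assert bounded.reactions.EX_o2_e.lower_bound == pytest.approx(-2.346)
    tag = report.set_index("exchange_id").loc["EX_o2_e", "provenance"]
    assert tag == "oxygen"


# ---------------------------------------------------------------------------
# Slope ratios
# ---------------------------------------------------------------------------

def _ratio_rows(fc_a, fc_b, fc_m, met="a", t0=100.0, det=1e-6):
    return [meas(met, "A", t0, t0 * fc_a, det=det),
            meas(met, "B", t0, t0 * fc_b, det=det),
            meas(met, "control", t0, t0 * fc_m, det=det)]


def test_identical_profiles_give_unit_slope_ratio():
    (rec,) = exo.slope_ratios(_ratio_rows(0.7, 0.7, 1.0), "A", "B")
    assert rec.slope_ratio == pytest.approx(1.0)


def test_slope_ratio_is_ratio_of_fold_change_slopes():
    (rec,) = exo.slope_ratios(_ratio_rows(0.5, 0.8, 1.0), "A", "B")
    assert rec.slope_ratio == pytest.approx(0.625)
    assert (rec.fc_A, rec.fc_B) == (pytest.approx(0.5), pytest.approx(0.8))


def test_medium_drift_divides_out_of_slopes():
    (rec,) = exo.slope_ratios(_ratio_rows(0.5, 0.8, 2.0), "A", "B")
    assert rec.slope_A == pytest.approx(0.25)
    assert rec.slope_ratio == pytest.approx(0.625)


def test_phosphate_is_skip_flagged():
    (rec,) = exo.slope_ratios(_ratio_rows(0.5, 0.8, 1.0, met="pi"), "A", "B")
    assert rec.skip is True


def test_zero_t0_signal_drops_record_with_warning(caplog):
    rows = _ratio_rows(0.5, 0.8, 1.0) + [
        meas("b", "A", 0.0, 1.0), meas("b", "B", 100, 80),
        meas("b", "control", 100, 100)]
    with caplog.at_level("WARNING"):
        recs = exo.slope_ratios(rows, "A", "B", detection_clamp=False)
    assert [r.metabolite_id for r in recs] == ["a"]
    assert "b" in caplog.text


# ---------------------------------------------------------------------------
# Quantitative bounds
# ---------------------------------------------------------------------------

def _two_exchange_models(lb_a=(-10, -0.01), lb_b=(-10, -0.01),
                         sec_a=(0.01, 500), sec_b=(0.01, 500)):
    def make(up, sec):
        m = chain_model()
        m.reactions.EX_a_e.bounds = up
        import cobra
        s = cobra.Metabolite("s_e", compartment="e")
        ex = cobra.Reaction("EX_s_e", lower_bound=sec[0], upper_bound=sec[1])
        m.add_reactions([ex])
        ex.add_metabolites({s: -1})
        return m
    return make(lb_a, sec_a), make(lb_b, sec_b)


def _record(met, slope_a, slope_b, skip=False):
    return exo.SlopeRatioRecord(met, slope_a, slope_b, 1.0, slope_a, slope_b,
                                slope_a / slope_b, skip)


def _classes(call_by_met):
    return [exo.ExchangeClass(m, c) for m, c in call_by_met.items()]


def test_unit_ratio_leaves_bounds_unchanged():
    a, b = _two_exchange_models()
    cls = _classes({"a": "uptake"})
    a2, b2, _ = exo.apply_quantitative_bounds(a, b, [_record("a", 0.8, 0.8)],
                                              cls, cls)
    assert a2.reactions.EX_a_e.bounds == a.reactions.EX_a_e.bounds
    assert b2.reactions.EX_a_e.bounds == b.reactions.EX_a_e.bounds


def test_stronger_secretor_minimum_is_raised_by_the_ratio():
    a, b = _two_exchange_models()
    cls = _classes({"s": "secretion"})
    a2, b2, rep = exo.apply_quantitative_bounds(a, b, [_record("s", 2.0, 1.0)],
                                                cls, cls)
    assert a2.reactions.EX_s_e.lower_bound == pytest.approx(0.02)
    assert b2.reactions.EX_s_e.lower_bound == pytest.approx(0.01)


def test_weaker_consumer_supply_is_restricted_by_the_ratio():
    a, b = _two_exchange_models()
    cls = _classes({"a": "uptake"})
    # A's signal drops further (smaller slope): B's supply shrinks
    a2, b2, _ = exo.apply_quantitative_bounds(a, b, [_record("a", 0.5, 1.0)],
                                              cls, cls)
    assert a2.reactions.EX_a_e.lower_bound == pytest.approx(-10.0)
    assert b2.reactions.EX_a_e.lower_bound == pytest.approx(-5.0)


def test_skip_flagged_records_leave_both_models_untouched():
    a, b = _two_exchange_models()
    cls = _classes({"a": "uptake"})
    a2, b2, rep = exo.apply_quantitative_bounds(
        a, b, [_record("a", 0.5, 1.0, skip=True)], cls, cls)
    assert a2.reactions.EX_a_e.bounds == a.reactions.EX_a_e.bounds
    assert b2.reactions.EX_a_e.bounds == b.reactions.EX_a_e.bounds
    assert rep.empty


def test_uniquely_exchanged_metabolites_are_not_adjusted():
    a, b = _two_exchange_models()
    cls_a = _classes({"a": "uptake"})
    cls_b = _classes({"a": "unchanged"})
    a2, b2, rep = exo.apply_quantitative_bounds(a, b, [_record("a", 0.5, 1.0)],
                                                cls_a, cls_b)
    assert rep.empty
    assert b2.reactions.EX_a_e.bounds == b.reactions.EX_a_e.bounds


def test_quantitative_adjustment_preserves_bound_order():
    a, b = _two_exchange_models()
    cls = _classes({"a": "uptake", "s": "secretion"})
    records = [_record("a", 0.3, 0.9), _record("s", 5.0, 1.0)]
    a2, b2, _ = exo.apply_quantitative_bounds(a, b, records, cls, cls)
    for m in (a2, b2):
        for r in m.reactions:
            assert r.lower_bound <= r.upper_bound


def test_identical_condition_profiles_yield_identical_models(
        toy_model, measurements, params_A):
    """Symmetric inputs must produce bound-for-bound identical models."""
    sym = [m for m in measurements if m.condition in ("A", "control")]
    sym += [exo.ExoMeasurement(m.metabolite_id, "B", m.signal_t0, m.signal_t1,
                               m.detection_limit_mM, m.medium_conc_mM)
            for m in measurements if m.condition == "A"]
    cls_a = exo.classify_exchanges(sym, "A", toy_model)
    cls_b = exo.classify_exchanges(sym, "B", toy_model)
    ma, _ = exo.apply_qualitative_bounds(toy_model, cls_a, sym, "A", params_A)
    mb, _ = exo.apply_qualitative_bounds(toy_model, cls_b, sym, "B", params_A)
    records = exo.slope_ratios(sym, "A", "B")
    ma2, mb2, rep = exo.apply_quantitative_bounds(ma, mb, records, cls_a, cls_b)
    assert rep.empty
    for ra, rb in zip(ma2.reactions, mb2.reactions):
        assert ra.id == rb.id and ra.bounds == rb.bounds
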