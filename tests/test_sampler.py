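"""Warm-up generation, the ACHR chain, and median summaries."""

import numpy as np
import pandas as pd
import pytest

from exoflux import netcore, sampler

import oracles
from conftest import build_model, chain_model


def parallel_paths(n=2, total=10.0):
    """One uptake split across n parallel paths: an n-simplex polytope."""
    rxns = [("EX_a_e", {"a_e": -1}, -total, 0.0, ""),
            ("EX_b_e", {"b_e": -1}, 0.0, total, "")]
    for i in range(n):
        rxns.append((f"P{i}", {"a_e": -1, "b_e": 1}, 0.0, total, ""))
    return build_model(rxns, objective="EX_b_e", model_id=f"simplex{n}")


def two_chains():
    """Two independent bounded chains: a 2-D box polytope."""
    return build_model([
        ("EX_a_e", {"a_e": -1}, -5.0, 0.0, ""),
        ("CONVA", {"a_e": -1, "ap_e": 1}, 0.0, 500.0, ""),
        ("EX_ap_e", {"ap_e": -1}, 0.0, 500.0, ""),
        ("EX_b_e", {"b_e": -1}, -3.0, 0.0, ""),
        ("CONVB", {"b_e": -1, "bp_e": 1}, 0.0, 500.0, ""),
        ("EX_bp_e", {"bp_e": -1}, 0.0, 500.0, ""),
    ], objective="EX_ap_e", model_id="box2")


def fixed_point_model():
    model = chain_model()
    model.reactions.EX_a_e.bounds = (-4.0, -4.0)
    return model


def _feasible(model, points, tol=1e-6):
    S, _, _ = netcore.stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    arr = np.asarray(points)
    return (np.max(np.abs(arr @ S.T)) < tol
            and np.all(arr >= lb - tol) and np.all(arr <= ub + tol))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def test_config_defaults_are_the_published_settings():
    cfg = sampler.paper_config()
    assert (cfg.n_warmup, cfg.n_files, cfg.points_per_file,
            cfg.steps_per_point) == (10_000, 100, 5_000, 2_500)


@pytest.mark.parametrize("kw", [{"n_files": 0}, {"steps_per_point": -1},
                                {"burn_in_files": 4, "n_files": 4}])
def test_config_rejects_bad_counts(kw):
    with pytest.raises(ValueError):
        sampler.desk_config(**kw)


# ---------------------------------------------------------------------------
# Warm-up
# ---------------------------------------------------------------------------

def test_warmup_points_are_feasible(toy_model):
    warmup = sampler.generate_warmup(toy_model, n_warmup=80, seed=1)
    assert warmup.shape == (80, len(toy_model.reactions))
    assert _feasible(toy_model, warmup)


def test_warmup_on_point_polytope_is_constant():
    model = fixed_point_model()
    warmup = sampler.generate_warmup(model, n_warmup=10, seed=0)
    assert np.allclose(warmup, warmup[0], atol=1e-8)


def test_warmup_spans_the_free_flux_range():
    model = two_chains()
    warmup = sampler.generate_warmup(model, n_warmup=24, seed=0)
    idx = [r.id for r in model.reactions].index("CONVA")
    assert warmup[:, idx].min() == pytest.approx(0.0, abs=1e-6)
    assert warmup[:, idx].max() == pytest.approx(5.0, abs=1e-6)


def test_warmup_refuses_infeasible_model():
    model = chain_model()
    model.reactions.BIO.lower_bound = 11.0
    with pytest.raises(netcore.InfeasibleModelError):
        sampler.generate_warmup(model, 10, 0)


# ---------------------------------------------------------------------------
# ACHR chain
# ---------------------------------------------------------------------------

def _desk(seed=0, **kw):
    defaults = dict(n_warmup=60, n_files=2, points_per_file=150,
                    steps_per_point=30, seed=seed)
    defaults.update(kw)
    return sampler.SamplerConfig(**defaults)


def test_fixed_point_polytope_returns_that_point():
    model = fixed_point_model()
    sample = sampler.sample_model(model, _desk())
    expected = netcore.fba(model).fluxes
    assert np.allclose(sample.points, expected[sample.reaction_ids].values,
                       atol=1e-8)


def test_every_stored_point_is_feasible(toy_model):
    sample = sampler.sample_model(toy_model, _desk(seed=5))
    assert len(sample.points) == 300
    assert _feasible(toy_model, sample.points)


def test_same_seed_gives_bit_identical_points(toy_model):
    a = sampler.sample_model(toy_model, _desk(seed=9))
    b = sampler.sample_model(toy_model, _desk(seed=9))
    assert a.points.equals(b.points)


def test_different_seeds_decorrelate(toy_model):
    a = sampler.sample_model(toy_model, _desk(seed=1))
    b = sampler.sample_model(toy_model, _desk(seed=2))
    assert not a.points.equals(b.points)


def test_burn_in_discards_leading_files(toy_model):
    full = sampler.sample_model(toy_model, _desk(seed=3))
    burned = sampler.sample_model(toy_model, _desk(seed=3, burn_in_files=1))
    assert len(burned.points) == 150
    pd.testing.assert_frame_equal(
        burned.points, full.points.iloc[150:].reset_index(drop=True))


def test_marginal_means_match_rejection_oracle():
    """On a 2-simplex with known geometry, ACHR means agree with uniform
    rejection sampling within 3 combined Monte-Carlo standard errors."""
    model = parallel_paths(2)
    sample = sampler.sample_model(model, _desk(seed=4, n_files=4,
                                               steps_per_point=60))
    reference = oracles.rejection_sample(model, 20_000, seed=4)
    for rid in sample.reaction_ids:
        a, r = sample.points[rid], reference[rid]
        se = np.sqrt(a.var() / len(a) + r.var() / len(r))
        assert abs(a.mean() - r.mean()) < 3 * max(se, 1e-12), rid


# ---------------------------------------------------------------------------
# Medians and persistence
# ---------------------------------------------------------------------------

def _sample_from(points, columns):
    return sampler.FluxSample(points=pd.DataFrame(points, columns=columns),
                              config=_desk())


def test_median_examples():
    s = _sample_from({"r1": [2.0] * 5, "r2": [1, 2, 3, 4, 5]},
                     ["r1", "r2"])
    med = sampler.sample_medians(s)
    assert med["r1"] == 2.0 and med["r2"] == 3.0


def test_medians_match_sort_based_oracle(toy_model):
    sample = sampler.sample_model(toy_model, _desk(seed=6))
    med = sampler.sample_medians(sample)
    for rid in sample.reaction_ids:
        col = np.sort(sample.points[rid].to_numpy())
        n = len(col)
        brute = col[n // 2] if n % 2 else (col[n // 2 - 1] + col[n // 2]) / 2
        assert med[rid] == pytest.approx(brute)


def test_medians_are_equivariant_to_reorder_and_sign_flip():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(51, 3))
    base = sampler.sample_medians(_sample_from(pts, ["a", "b", "c"]))
    reordered = sampler.sample_medians(
        _sample_from(pts[:, [2, 0, 1]], ["c", "a", "b"]))
    for rid in "abc":
        assert base[rid] == reordered[rid]
    flipped = pts.copy()
    flipped[:, 1] *= -1
    flip = sampler.sample_medians(_sample_from(flipped, ["a", "b", "c"]))
    assert flip["b"] == -base["b"]


def test_empty_sample_is_rejected():
    with pytest.raises(ValueError):
        sampler.sample_medians(_sample_from(np.empty((0, 1)), ["r"]))


def test_write_read_round_trip(toy_model, tmp_path):
    sample = sampler.sample_model(toy_model, _desk(seed=8))
    manifest = sample.write(tmp_path / "chunks")
    assert manifest.name == "manifest.json"
    back = sampler.FluxSample.read(tmp_path / "chunks")
    assert back.reaction_ids == sample.reaction_ids
    assert back.config == sample.config
    assert np.allclose(back.points, sample.points, atol=1e-9)
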