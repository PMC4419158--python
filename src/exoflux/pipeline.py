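"""End-to-end pipeline: data -> condition-specific models -> predictions.

Per condition: qualitative exchange bounds, absent-gene removal,
consistency check, FVA pruning.  Then on the pair: quantitative
slope-ratio bounds, ACHR sampling, median comparison with loop
exclusion, DEG concordance, and the single-gene deletion screen.  Every
stage writes its artifact to the output directory and a run manifest
records config and seed, so a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import (contextualize, exoconstraints, fluxcompare, genedel, netcore,
               sampler)
from .exoconstraints import CultureParams


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" ({hint})" if hint else ""))


@dataclass
class PipelineConfig:
    model_path: str
    metabolomics_path: str
    calls_path_A: str
    calls_path_B: str
    deg_path: str
    out_dir: str
    condition_A: str = "A"
    condition_B: str = "B"
    params_A: CultureParams = field(default_factory=CultureParams)
    params_B: CultureParams = field(
        default_factory=lambda: CultureParams(growth_rate_per_h=0.032))
    whitelist: frozenset[str] = exoconstraints.DEFAULT_WHITELIST
    classification_threshold: float = 0.05
    utilization_threshold: float = 0.10
    prune_tol: float = contextualize.PRUNE_TOL
    lethal_tol: float = genedel.LETHAL_TOL
    sampler_preset: str = "desk"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("params_A", "params_B"):
            if key in data:
                data[key] = CultureParams(**data[key])
        if "whitelist" in data:
            data["whitelist"] = frozenset(data["whitelist"])
        cfg = cls(**data)
        for key in ("model_path", "metabolomics_path", "calls_path_A",
                    "calls_path_B", "deg_path"):
            if not Path(getattr(cfg, key)).exists():
                raise PipelineError("config", f"{key} does not exist: "
                                    f"{getattr(cfg, key)}")
        return cfg


def _sampler_config(preset: str, seed: int) -> sampler.SamplerConfig:
    if preset == "desk":
        return sampler.desk_config(seed=seed)
    if preset == "paper":
        return sampler.paper_config(seed=seed)
    raise PipelineError("config", f"unknown sampler preset {preset!r}")


def build_condition_model(model, measurements, condition, params, calls,
                          whitelist=exoconstraints.DEFAULT_WHITELIST,
                          threshold=0.05, prune_tol=contextualize.PRUNE_TOL):
    """Qualitative bounds -> absent-gene removal -> consistency -> prune.

    Returns (submodel, classes, bounds_report, prune_report).
    """
    classes = exoconstraints.classify_exchanges(
        measurements, condition, model, threshold=threshold)
    bounded, bounds_report = exoconstraints.apply_qualitative_bounds(
        model, classes, measurements, condition, params, whitelist)
    constrained, _disabled = contextualize.remove_absent_genes(bounded, calls)
    feas = contextualize.check_consistency(constrained)
    if not feas.feasible:
        raise PipelineError(
            "consistency",
            f"condition {condition!r} model infeasible",
            f"relaxation candidates: {feas.relaxation_set}")
    submodel, prune_report = contextualize.prune(constrained, tol=prune_tol)
    return submodel, classes, bounds_report, prune_report


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full two-condition workflow; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = netcore.read_model(config.model_path)
    measurements = exoconstraints.read_measurements(config.metabolomics_path)
    calls_A = contextualize.read_calls(config.calls_path_A)
    calls_B = contextualize.read_calls(config.calls_path_B)
    degs = fluxcompare.DEGTable.read(config.deg_path)

    submodels, classes, reports = {}, {}, {}
    for cond, params, calls in ((config.condition_A, config.params_A, calls_A),
                                (config.condition_B, config.params_B, calls_B)):
        sub, cls, bounds_report, prune_report = build_condition_model(
            model, measurements, cond, params, calls,
            whitelist=config.whitelist,
            threshold=config.classification_threshold,
            prune_tol=config.prune_tol)
        submodels[cond], classes[cond] = sub, cls
        netcore.write_model(sub, out / f"submodel_{cond}.json")
        bounds_report.to_csv(out / f"bounds_{cond}.tsv", sep="\t", index=False)
        prune_report.to_json(out / f"prune_{cond}.json")
        reports[cond] = {"pruned": len(prune_report.removed_reactions)}

    a, b = config.condition_A, config.condition_B
    records = exoconstraints.slope_ratios(measurements, a, b)
    model_A, model_B, quant_report = exoconstraints.apply_quantitative_bounds(
        submodels[a], submodels[b], records, classes[a], classes[b])
    quant_report.to_csv(out / "quantitative_bounds.tsv", sep="\t", index=False)

    scfg = _sampler_config(config.sampler_preset, config.seed)
    sample_A = sampler.sample_model(model_A, scfg)
    sample_B = sampler.sample_model(model_B, scfg)
    sample_A.write(out / "samples_A")
    sample_B.write(out / "samples_B")
    med_A = sampler.sample_medians(sample_A)
    med_B = sampler.sample_medians(sample_B)

    comparison = fluxcompare.compare_models(
        dict(med_A), dict(med_B), model_A, model_B,
        threshold=config.utilization_threshold)
    comparison.to_frame().to_csv(out / "comparison.tsv", sep="\t", index=False)
    gene_map = fluxcompare.gene_reaction_map(model_A, model_B)
    concordance = fluxcompare.deg_concordance(comparison, degs, gene_map)
    fluxcompare.write_concordance(concordance, out / "concordance.json")

    res_A = genedel.screen(model_A, lethal_tol=config.lethal_tol)
    res_B = genedel.screen(model_B, lethal_tol=config.lethal_tol)
    res_A.to_frame().to_csv(out / "knockouts_A.tsv", sep="\t", index=False)
    res_B.to_frame().to_csv(out / "knockouts_B.tsv", sep="\t", index=False)
    sets = genedel.lethal_sets(res_A, res_B)
    sets.to_json(out / "lethal_sets.json")

    diff = contextualize.model_diff(model_A, model_B)
    manifest = {
        "seed": config.seed,
        "sampler_preset": config.sampler_preset,
        "config_hash": hashlib.sha256(
            json.dumps(_config_fingerprint(config), sort_keys=True).encode()
        ).hexdigest(),
        "conditions": {a: reports[a], b: reports[b]},
        "model_diff": {k: {kk: len(vv) for kk, vv in getattr(diff, k).items()}
                       for k in ("shared", "unique_A", "unique_B")},
        "groups": {"x": len(comparison.group_x),
                   "y": len(comparison.group_y),
                   "z": len(comparison.group_z)},
        "lethal": {"shared": len(sets.shared),
                   "unique_A": len(sets.unique_A),
                   "unique_B": len(sets.unique_B)},
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _config_fingerprint(config: PipelineConfig) -> dict:
    fp = {}
    for k, v in vars(config).items():
        if isinstance(v, CultureParams):
            fp[k] = vars(v).copy()
        elif isinstance(v, frozenset):
            fp[k] = sorted(v)
        else:
            fp[k] = v
    return fp


__all__ = ["PipelineConfig", "PipelineError", "build_condition_model",
           "run_pipeline"]
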