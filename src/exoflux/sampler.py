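"""Uniform flux sampling by Artificial Centering Hit-and-Run (ACHR).

The steady-state flux space {v : S v = 0, lb <= v <= ub} is a convex
polytope inside the null space of S.  ACHR walks through it by drawing a
direction from the current point through the running center of all
points seen so far, which adapts step directions to the polytope's
elongation; every ``steps_per_point``-th iterate is stored.

Warm-up points are LP vertices: first the 2n flux-variability optima,
then optima of random-coefficient objectives.  All stored points satisfy
|S v| < 1e-6 and the bounds (asserted at save time); a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

import cobra

from . import netcore
from .netcore import InfeasibleModelError

FEASIBILITY_TOL = 1e-6
_PROJECT_EVERY = 100  # steps between null-space re-projections
_DIRECTION_TOL = 1e-11


@dataclass(frozen=True)
class SamplerConfig:
    """ACHR run settings.

    The ``paper`` preset reproduces the published cluster-scale run
    (10,000 warm-up points, 100 files x 5,000 points, 2,500 steps per
    point); the ``desk`` preset is sized for toy networks.
    """

    n_warmup: int = 10_000
    n_files: int = 100
    points_per_file: int = 5_000
    steps_per_point: int = 2_500
    seed: int = 0
    tolerance: float = FEASIBILITY_TOL
    burn_in_files: int = 0

    def __post_init__(self) -> None:
        for name in ("n_warmup", "n_files", "points_per_file",
                     "steps_per_point"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in_files < 0 or self.burn_in_files >= self.n_files:
            raise ValueError("burn_in_files must lie in [0, n_files)")

    @property
    def n_points(self) -> int:
        return (self.n_files - self.burn_in_files) * self.points_per_file


def desk_config(seed: int = 0, **overrides) -> SamplerConfig:
    """Desk-scale profile for small networks and tests."""
    defaults = dict(n_warmup=200, n_files=4, points_per_file=250,
                    steps_per_point=100, seed=seed)
    defaults.update(overrides)
    return SamplerConfig(**defaults)


def paper_config(seed: int = 0, **overrides) -> SamplerConfig:
    return SamplerConfig(seed=seed, **overrides)


@dataclass
class FluxSample:
    """Stored sampling points (n_points x n_reactions) plus provenance."""

    points: pd.DataFrame
    config: SamplerConfig

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.points.columns)

    def write(self, directory: str | Path) -> Path:
        """Write one TSV per file chunk plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        per = self.config.points_per_file
        n_chunks = int(np.ceil(len(self.points) / per))
        names = []
        for i in range(n_chunks):
            chunk = self.points.iloc[i * per:(i + 1) * per]
            name = f"points_{i:04d}.tsv"
            chunk.to_csv(directory / name, sep="\t", index=False,
                         float_format="%.10g")
            names.append(name)
        manifest = {"config": asdict(self.config), "files": names,
                    "n_points": len(self.points),
                    "reactions": self.reaction_ids}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return directory / "manifest.json"

    @classmethod
    def read(cls, directory: str | Path) -> "FluxSample":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        frames = [pd.read_csv(directory / f, sep="\t")
                  for f in manifest["files"]]
        points = pd.concat(frames, ignore_index=True)[manifest["reactions"]]
        return cls(points=points, config=SamplerConfig(**manifest["config"]))


# ---------------------------------------------------------------------------
# Polytope extraction and warm-up
# ---------------------------------------------------------------------------

@dataclass
class _Polytope:
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    nullspace: np.ndarray  # n_reactions x k orthonormal basis

    def check(self, point: np.ndarray, tol: float = FEASIBILITY_TOL) -> bool:
        return (np.max(np.abs(self.S @ point), initial=0.0) < tol
                and np.all(point >= self.lb - tol)
                and np.all(point <= self.ub + tol))


def _extract_polytope(model: cobra.Model) -> _Polytope:
    S, _, rxn_ids = netcore.stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    ns = scipy.linalg.null_space(S)
    return _Polytope(S=S, lb=lb, ub=ub, reaction_ids=rxn_ids, nullspace=ns)


def _lp_vertex(poly: _Polytope, c: np.ndarray) -> np.ndarray | None:
    res = scipy.optimize.linprog(
        -c, A_eq=poly.S, b_eq=np.zeros(poly.S.shape[0]),
        bounds=list(zip(poly.lb, poly.ub)), method="highs")
    return res.x if res.status == 0 else None


def generate_warmup(model: cobra.Model, n_warmup: int = 200,
                    seed: int = 0) -> np.ndarray:
    """Feasible LP vertices spanning the polytope.

    The 2n per-reaction min/max optima (the FVA vertices) come first;
    random Gaussian objectives fill up to ``n_warmup``.  Raises if the
    model is infeasible.
    """
    poly = _extract_polytope(model)
    n = len(poly.reaction_ids)
    points: list[np.ndarray] = []
    for j in range(n):
        if len(points) >= n_warmup:
            break
        for sign in (1.0, -1.0):
            if len(points) >= n_warmup:
                break
            c = np.zeros(n)
            c[j] = sign
            x = _lp_vertex(poly, c)
            if x is None:
                raise InfeasibleModelError(
                    "model infeasible; cannot generate warm-up points")
            points.append(x)
    rng = np.random.default_rng(seed)
    while len(points) < n_warmup:
        x = _lp_vertex(poly, rng.standard_normal(n))
        if x is None:
            raise InfeasibleModelError(
                "model infeasible; cannot generate warm-up points")
        points.append(x)
    warmup = np.asarray(points)
    # snap LP round-off onto the null space so the chain starts clean
    if poly.nullspace.size:
        warmup = warmup @ poly.nullspace @ poly.nullspace.T
    else:
        warmup = np.zeros_like(warmup)
    return np.clip(warmup, poly.lb, poly.ub)


# ---------------------------------------------------------------------------
# The ACHR chain
# ---------------------------------------------------------------------------

def _step_interval(x: np.ndarray, d: np.ndarray, lb: np.ndarray,
                   ub: np.ndarray) -> tuple[float, float]:
    """Allowed step range [a_lo, a_hi] keeping x + a d inside the box."""
    a_lo, a_hi = -np.inf, np.inf
    pos = d > _DIRECTION_TOL
    neg = d < -_DIRECTION_TOL
    if pos.any():
        a_hi = min(a_hi, np.min((ub[pos] - x[pos]) / d[pos]))
        a_lo = max(a_lo, np.max((lb[pos] - x[pos]) / d[pos]))
    if neg.any():
        a_hi = min(a_hi, np.min((lb[neg] - x[neg]) / d[neg]))
        a_lo = max(a_lo, np.max((ub[neg] - x[neg]) / d[neg]))
    return a_lo, a_hi


def achr_sample(model: cobra.Model, warmup: np.ndarray | None = None,
                config: SamplerConfig | None = None) -> FluxSample:
    """Run the ACHR chain and return the stored points.

    Direction = (random previously seen point - running center),
    normalised; the step size is uniform on the feasible segment.  The
    running center is the mean over warm-up plus stored points.  Points
    are re-projected onto the null space of S every 100 steps to control
    numerical drift.  Degenerate polytopes (a single point) yield that
    point repeated.
    """
    config = config or desk_config()
    poly = _extract_polytope(model)
    if warmup is None:
        warmup = generate_warmup(model, config.n_warmup, config.seed)
    warmup = np.asarray(warmup, dtype=float)
    if warmup.ndim != 2 or warmup.shape[0] == 0:
        raise ValueError("warmup must be a nonempty 2-D array")

    rng = np.random.default_rng(config.seed)
    n_store_total = config.n_files * config.points_per_file
    n_keep_from = config.burn_in_files * config.points_per_file

    center = warmup.mean(axis=0)
    n_seen = warmup.shape[0]
    x = warmup[rng.integers(warmup.shape[0])].copy()
    stored: list[np.ndarray] = []
    proj = poly.nullspace  # may be (n, 0) for a point polytope
    degenerate = proj.shape[1] == 0 or np.allclose(
        warmup.max(axis=0), warmup.min(axis=0), atol=1e-9)

    step_count = 0
    for _ in range(n_store_total):
        if degenerate:
            stored.append(center.copy())
            continue
        for _ in range(config.steps_per_point):
            d = None
            for _attempt in range(100):
                j = rng.integers(n_seen)
                ref = warmup[j] if j < warmup.shape[0] \
                    else stored[j - warmup.shape[0]]
                cand = ref - center
                norm = np.linalg.norm(cand)
                if norm > _DIRECTION_TOL:
                    d = cand / norm
                    break
            if d is None:
                raise RuntimeError(
                    "could not find a nonzero sampling direction; "
                    "polytope may be degenerate")
            a_lo, a_hi = _step_interval(x, d, poly.lb, poly.ub)
            if not np.isfinite(a_lo) or not np.isfinite(a_hi) \
                    or not a_hi - a_lo > 0:
                continue  # numerically stuck on a face; try a new direction
            x = x + rng.uniform(a_lo, a_hi) * d
            step_count += 1
            if step_count % _PROJECT_EVERY == 0:
                x = proj @ (proj.T @ x)
                np.clip(x, poly.lb, poly.ub, out=x)
        x = proj @ (proj.T @ x)
        np.clip(x, poly.lb, poly.ub, out=x)
        if not poly.check(x, config.tolerance):
            raise RuntimeError("sampler produced an infeasible point")
        stored.append(x.copy())
        center = (center * n_seen + x) / (n_seen + 1)
        n_seen += 1

    points = np.asarray(stored)[n_keep_from:]
    return FluxSample(points=pd.DataFrame(points, columns=poly.reaction_ids),
                      config=config)


def sample_medians(sample: FluxSample) -> pd.Series:
    """Per-reaction median flux over the stored points (sign preserved)."""
    if sample.points.empty:
        raise ValueError("empty sample")
    return sample.points.median(axis=0)


def sample_model(model: cobra.Model, config: SamplerConfig | None = None,
                 ) -> FluxSample:
    """Convenience wrapper: warm-up then ACHR with one config."""
    config = config or desk_config()
    warmup = generate_warmup(model, config.n_warmup, config.seed)
    return achr_sample(model, warmup, config)


__all__ = ["FEASIBILITY_TOL", "FluxSample", "SamplerConfig", "achr_sample",
           "desk_config", "generate_warmup", "paper_config", "sample_medians",
           "sample_model"]
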