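"""Flux sampling over the steady-state polytope {v : S v = 0, lb <= v <= ub}.

The default walker is an artificially-centered hit-and-run (ACHR)
chain behind a small, pluggable contract: any callable producing an
``(n_points, n_reactions)`` matrix of feasible rows under a fixed seed
can stand in for it (e.g. an adaptive box sampler).  Directions are
differences of feasible points, so every step stays inside the affine
space S v = 0 up to numerical drift well below the 1e-6 feasibility
tolerance.

``sample_adaptive`` implements the batched stopping rule driven by
saved density-exploration parameters (target span between central and
furthest retained solutions, and target retained-solution count).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    InfeasibleModelError,
    MetabolicModel,
    check_flux_feasible,
    fba,
    optimize_objective,
)

__all__ = [
    "FluxSampleSet",
    "SamplingParameters",
    "generate_warmup",
    "sample_fluxes",
    "sample_adaptive",
]


@dataclass
class SamplingParameters:
    """Saved stopping parameters from a density-exploration run.

    ``span`` is the Euclidean distance between the central and furthest
    retained solutions; ``retained_count`` the number of retained
    solutions; ``percentile`` the chosen threshold percentile.
    """

    span: float
    retained_count: int
    percentile: int

    def __post_init__(self):
        if self.span < 0:
            raise ValueError("span must be >= 0")
        if not 1 <= int(self.percentile) <= 100:
            raise ValueError("percentile must lie in [1, 100]")
        if self.retained_count < 1:
            raise ValueError("retained_count must be >= 1")

    def to_dict(self) -> dict:
        return {
            "span": float(self.span),
            "retained_count": int(self.retained_count),
            "percentile": int(self.percentile),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingParameters":
        return cls(
            span=d["span"],
            retained_count=d["retained_count"],
            percentile=d["percentile"],
        )


@dataclass
class FluxSampleSet:
    """N sampled flux vectors over R reactions of one model."""

    matrix: np.ndarray
    reaction_ids: list[str]
    seed: int | None = None
    model_digest: str = ""
    budget_exhausted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("sample matrix must be 2-D")
        if self.matrix.shape[1] != len(self.reaction_ids):
            raise ValueError("column count must match reaction id count")
        if self.matrix.shape[0] < 1:
            raise ValueError("a sample set needs at least one row")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rid)]

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, columns=self.reaction_ids).to_csv(
            path, sep="\t", index=False
        )
        sidecar = {
            "seed": self.seed,
            "model_digest": self.model_digest,
            "budget_exhausted": self.budget_exhausted,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str) -> "FluxSampleSet":
        df = pd.read_csv(path, sep="\t")
        seed, digest, exhausted = None, "", False
        try:
            with open(str(path) + ".json") as fh:
                sc = json.load(fh)
            seed = sc.get("seed")
            digest = sc.get("model_digest", "")
            exhausted = sc.get("budget_exhausted", False)
        except FileNotFoundError:
            pass
        return cls(
            matrix=df.to_numpy(dtype=float),
            reaction_ids=list(df.columns),
            seed=seed,
            model_digest=digest,
            budget_exhausted=exhausted,
        )


def _assert_feasible(model: MetabolicModel, matrix: np.ndarray) -> None:
    for i, row in enumerate(matrix):
        if not check_flux_feasible(model, row):
            raise RuntimeError(f"sampled row {i} violates feasibility tolerances")


def _nullspace_basis(model: MetabolicModel) -> np.ndarray:
    """Orthonormal basis of {v : S v = 0} (columns)."""
    from scipy.linalg import null_space

    n = len(model.reactions)
    if len(model.metabolites) == 0:
        return np.eye(n)
    return null_space(model.S.toarray())


def generate_warmup(model: MetabolicModel, count: int | None = None) -> FluxSampleSet:
    """Feasible points spanning the polytope via per-reaction max/min LPs.

    The first ``2R`` points maximize then minimize each reaction in
    model order; further points optimize deterministic pseudo-random
    +-1 objectives.  Default count is ``2R``.
    """
    n = len(model.reactions)
    if count is None:
        count = 2 * n
    if count < 1:
        raise ValueError("count must be >= 1")
    fba(model)  # raises InfeasibleModelError early
    rng = np.random.default_rng(0)  # only used past the 2R deterministic slots
    rows = []
    k = 0
    while len(rows) < count:
        if k < 2 * n:
            c = np.zeros(n)
            c[k // 2] = 1.0
            sense = "max" if k % 2 == 0 else "min"
        else:
            c = rng.choice([-1.0, 1.0], size=n)
            sense = "max"
        rows.append(optimize_objective(model, c, sense))
        k += 1
    matrix = np.array(rows)
    _assert_feasible(model, matrix)
    return FluxSampleSet(
        matrix=matrix,
        reaction_ids=model.reaction_ids,
        seed=None,
        model_digest=model.digest(),
    )


def sample_fluxes(
    model: MetabolicModel,
    n_points: int,
    seed: int,
    thinning: int = 100,
    warmup: FluxSampleSet | None = None,
    initial_point: np.ndarray | None = None,
) -> FluxSampleSet:
    """Draw ``n_points`` feasible flux vectors with an ACHR chain.

    Same seed + same model digest -> bit-identical output.  ``thinning``
    is the number of chain steps per retained sample.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    lb, ub = model.lower_bounds, model.upper_bounds

    if warmup is None:
        warmup = generate_warmup(model)
    W = warmup.matrix

    # Degenerate polytope: a single point.
    if np.max(W.max(axis=0) - W.min(axis=0), initial=0.0) < 1e-12:
        matrix = np.repeat(W[:1], n_points, axis=0)
        _assert_feasible(model, matrix)
        return FluxSampleSet(matrix, model.reaction_ids, seed, model.digest())

    rng = np.random.default_rng(seed)
    pool = list(W)
    center = W.mean(axis=0)
    x = center.copy() if initial_point is None else np.asarray(initial_point, float).copy()
    n_center = len(pool)
    # orthonormal null-space basis: every step re-projects the walker onto
    # the steady-state subspace so clip-induced drift cannot accumulate
    N = _nullspace_basis(model)

    samples = np.empty((n_points, len(model.reactions)))
    recorded = 0
    steps_since_record = 0
    stall = 0
    while recorded < n_points:
        d = pool[rng.integers(len(pool))] - center
        nd = float(np.linalg.norm(d))
        if nd < 1e-12:
            stall += 1
            if stall > 1000:
                # chain collapsed onto the center; emit current point
                samples[recorded] = x
                recorded += 1
                stall = 0
            continue
        stall = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = (lb - x) / d
            hi = (ub - x) / d
        pos = d > 1e-11
        neg = d < -1e-11
        alphas_hi = np.concatenate([hi[pos], lo[neg]])
        alphas_lo = np.concatenate([lo[pos], hi[neg]])
        amax = alphas_hi.min() if alphas_hi.size else 0.0
        amin = alphas_lo.max() if alphas_lo.size else 0.0
        if amax - amin < 1e-12:
            continue
        alpha = rng.uniform(amin, amax)
        x = x + alpha * d
        # re-project onto S v = 0, then guard against tiny bound violations
        x = N @ (N.T @ x)
        np.clip(x, lb, ub, out=x)
        n_center += 1
        center = center + (x - center) / n_center
        steps_since_record += 1
        if steps_since_record >= thinning:
            samples[recorded] = x
            pool.append(x.copy())
            recorded += 1
            steps_since_record = 0

    _assert_feasible(model, samples)
    return FluxSampleSet(samples, model.reaction_ids, seed, model.digest())


def sample_adaptive(
    model: MetabolicModel,
    params: SamplingParameters,
    batch: int = 500,
    max_points: int = 50_000,
    seed: int = 0,
    thinning: int = 100,
    span_rtol: float = 0.05,
    span_eps: float = 1e-9,
) -> FluxSampleSet:
    """Sample in batches until saved stopping parameters are reached.

    After every batch the density-exploration filter runs on the
    accumulated samples; sampling stops once the retained count reaches
    ``params.retained_count`` and the central-furthest span is within
    ``span_rtol`` of ``params.span`` (the span condition is waived for a
    degenerate zero span target).  Hitting ``max_points`` first sets
    ``budget_exhausted`` on the returned set.  The last filter result is
    stored under ``meta["resos"]``.
    """
    from . import resos as _resos  # local import; resos consumes this module's types

    if batch < 10:
        raise ValueError("batch must be >= 10")
    if max_points < batch:
        raise ValueError("max_points must be >= batch")

    warmup = generate_warmup(model)
    chunks: list[np.ndarray] = []
    total = 0
    last_point = None
    result = None
    batch_index = 0
    exhausted = False
    while True:
        n_draw = min(batch, max_points - total)
        s = sample_fluxes(
            model,
            n_draw,
            seed=seed + batch_index,
            thinning=thinning,
            warmup=warmup,
            initial_point=last_point,
        )
        chunks.append(s.matrix)
        last_point = s.matrix[-1]
        total += n_draw
        batch_index += 1
        accumulated = np.vstack(chunks)
        sset = FluxSampleSet(accumulated, model.reaction_ids, seed, model.digest())
        if accumulated.shape[0] >= 10:
            scores = _resos.score_solutions(sset, method="continuous")
            # reuse the saved percentile threshold rather than re-deriving
            # the inflection on every batch
            result = _resos.filter_at_percentile(sset, scores, params.percentile)
            count_ok = result.params.retained_count >= params.retained_count
            if params.span <= span_eps:
                span_ok = True
            else:
                span_ok = (
                    abs(result.params.span - params.span)
                    / max(params.span, span_eps)
                    <= span_rtol
                )
            if count_ok and span_ok:
                break
        if total >= max_points:
            exhausted = True
            break

    out = FluxSampleSet(
        np.vstack(chunks),
        model.reaction_ids,
        seed,
        model.digest(),
        budget_exhausted=exhausted,
    )
    out.meta["resos"] = result
    return out
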