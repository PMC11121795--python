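"""Density exploration of sampled flux solution spaces.

Identifies the densest region of a set of sampled steady-state flux
vectors.  Two scoring methods are provided:

* ``continuous`` — each solution's total is its summed Euclidean
  distance to every other solution; small totals mark dense regions.
* ``discrete`` — per-reaction histograms (normalized to unit area);
  each solution's total is the summed density of the bins its fluxes
  fall in; large totals mark dense regions.

The *central* solution minimizes (continuous) / maximizes (discrete)
the total; the *furthest* solution is its opposite extreme among the
retained set.  The retained set itself is chosen by a dynamic,
non-arbitrary percentile: every percentile 1..100 of the totals is
tested, the span (Euclidean distance between central and
furthest-at-percentile) is traced as a curve over percentiles, and the
percentile at the first concavity change (sign change of the second
finite difference of the smoothed curve) is selected.  Solutions past
that threshold are treated as outliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling import FluxSampleSet, SamplingParameters

__all__ = [
    "DensityScores",
    "ResosResult",
    "pairwise_distance",
    "score_solutions",
    "find_central",
    "find_furthest",
    "dynamic_percentile",
    "filter_solutions",
    "run_resos",
]

#: hard cap on sample count for the O(N^2) continuous method
MAX_SAMPLES = 50_000
#: moving-average window for the span-vs-percentile curve
SMOOTH_WINDOW = 5
#: moving-average window applied to the curve's second difference
CURVATURE_WINDOW = 11
#: percentiles excluded at both curve ends when locating the inflection
#: (covers the edge artifacts of the two shrinking-window averages)
EDGE_MARGIN = 10


@dataclass
class DensityScores:
    """Per-solution density totals plus their normalization."""

    totals: np.ndarray
    normalized: np.ndarray
    method: str  # "continuous" | "discrete"

    def ranking_key(self) -> np.ndarray:
        """Totals oriented so that *smaller = denser* for both methods."""
        return self.totals if self.method == "continuous" else -self.totals


@dataclass
class ResosResult:
    central_index: int
    furthest_index: int
    percentile: int
    retained_indices: np.ndarray
    params: SamplingParameters
    curve: pd.DataFrame  # columns: percentile, retained_count, span
    method: str = "continuous"
    fallback_warning: bool = False

    def to_json(self, path: str) -> None:
        doc = {
            "central_index": int(self.central_index),
            "furthest_index": int(self.furthest_index),
            "percentile": int(self.percentile),
            "retained_indices": [int(i) for i in self.retained_indices],
            "params": self.params.to_dict(),
            "method": self.method,
            "fallback_warning": bool(self.fallback_warning),
            "curve": self.curve.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ResosResult":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            central_index=doc["central_index"],
            furthest_index=doc["furthest_index"],
            percentile=doc["percentile"],
            retained_indices=np.asarray(doc["retained_indices"], dtype=int),
            params=SamplingParameters.from_dict(doc["params"]),
            curve=pd.DataFrame(doc["curve"]),
            method=doc.get("method", "continuous"),
            fallback_warning=doc.get("fallback_warning", False),
        )


def pairwise_distance(a, b) -> float:
    """Euclidean distance between two flux vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("flux vectors must be finite")
    return float(np.linalg.norm(a - b))


def _continuous_totals(matrix: np.ndarray, block: int = 1024) -> np.ndarray:
    """Row sums of the full pairwise Euclidean distance matrix.

    Computed blockwise so the N x N matrix is never materialized.
    """
    from scipy.spatial.distance import cdist

    n = matrix.shape[0]
    totals = np.zeros(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        totals[start:stop] = cdist(matrix[start:stop], matrix).sum(axis=1)
    return totals


def _discrete_totals(matrix: np.ndarray, bins: int) -> np.ndarray:
    """Summed per-reaction bin densities for each solution.

    Each reaction's histogram is normalized to unit area; a solution
    scores the density of the bin its flux falls in, summed over
    reactions.
    """
    n, r = matrix.shape
    totals = np.zeros(n)
    for j in range(r):
        col = matrix[:, j]
        dens, edges = np.histogram(col, bins=bins, density=True)
        # right-most edge is inclusive, mirroring np.histogram counting
        idx = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, bins - 1)
        totals += dens[idx]
    return totals


def score_solutions(
    samples: FluxSampleSet, method: str = "continuous", bins: int = 100
) -> DensityScores:
    """Score every sampled solution by local density."""
    if method not in ("continuous", "discrete"):
        raise ValueError(f"unknown method {method!r}")
    matrix = samples.matrix
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to score")
    if n > MAX_SAMPLES:
        raise ValueError(f"sample count {n} exceeds cap {MAX_SAMPLES}")
    if method == "continuous":
        totals = _continuous_totals(matrix)
        grand = totals.sum()
        if grand <= 0.0:
            raise ValueError(
                "degenerate normalization: all samples identical (grand sum 0)"
            )
        return DensityScores(totals=totals, normalized=totals / grand, method=method)
    if bins < 1:
        raise ValueError("bins must be >= 1")
    totals = _discrete_totals(matrix, bins)
    grand = totals.sum()
    normalized = totals / grand if grand > 0 else np.full(n, 1.0 / n)
    return DensityScores(totals=totals, normalized=normalized, method=method)


def find_central(scores: DensityScores) -> int:
    """Index of the densest solution; ties break to the smallest index."""
    return int(np.argmin(scores.ranking_key()))


def find_furthest(scores: DensityScores) -> int:
    """Index of the least dense solution; ties break to the smallest index."""
    return int(np.argmax(scores.ranking_key()))


def _smooth(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; shrinks the window near the edges."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def dynamic_percentile(samples: FluxSampleSet, scores: DensityScores) -> ResosResult:
    """Choose the retention threshold at the span curve's concavity change.

    For each percentile p of the density totals, solutions at or below
    the p-th percentile are retained; the "span" — how far the
    furthest retained solution is from the central one, measured as
    the difference of their summed-distance totals in per-neighbor
    units (monotone in p; sample-size invariant) — is recorded, along
    with their raw Euclidean vector distance.  The chosen percentile
    sits at the first sign change of the second finite difference of
    the (smoothed) span curve — past that point the central-furthest
    separation accelerates and the retained set starts absorbing
    outliers.  When the curvature never changes sign, the percentile of
    maximum |curvature| is used (percentile 100 when the curve is
    exactly linear), with a warning flag set.
    """
    matrix = samples.matrix
    n = matrix.shape[0]
    if n < 10:
        raise ValueError("dynamic percentile needs at least 10 samples")
    key = scores.ranking_key()
    central = int(np.argmin(key))

    percentiles = np.arange(1, 101)
    thresholds = np.percentile(key, percentiles)  # linear interpolation
    counts = np.empty(100, dtype=int)
    spans = np.empty(100)
    vector_spans = np.empty(100)
    furthest_at = np.empty(100, dtype=int)
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    for i, thr in enumerate(thresholds):
        m = int(np.searchsorted(sorted_key, thr, side="right"))
        m = max(m, 1)
        retained = order[:m]
        # furthest retained solution; ties break to smallest index
        cand = retained[sorted_key[:m] == sorted_key[m - 1]]
        fu = int(cand.min())
        counts[i] = m
        furthest_at[i] = fu
        # span: difference between the furthest and central solutions'
        # density totals, in average-distance units (per-neighbor), so
        # values are comparable across sample counts
        spans[i] = float(key[fu] - key[central]) / (n - 1)
        vector_spans[i] = pairwise_distance(matrix[central], matrix[fu])

    smoothed = _smooth(spans)
    d2 = np.zeros(100)
    d2[1:-1] = smoothed[2:] - 2.0 * smoothed[1:-1] + smoothed[:-2]
    # curvature is itself noisy at percentile granularity; smooth it and
    # keep clear of the edge artifacts of the shrinking-window average
    d2s = _smooth(d2, CURVATURE_WINDOW)
    scale = max(np.max(np.abs(smoothed)), 1.0)
    tol = 1e-9 * scale
    lo_margin, hi_margin = EDGE_MARGIN, 100 - EDGE_MARGIN

    chosen = None
    fallback = False
    prev_sign = 0
    for i in range(lo_margin, hi_margin):
        if abs(d2s[i]) <= tol:
            continue
        s = 1 if d2s[i] > 0 else -1
        if prev_sign != 0 and s != prev_sign:
            chosen = int(percentiles[i])
            break
        prev_sign = s
    if chosen is None:
        fallback = True
        inner = np.abs(d2s[lo_margin:hi_margin])
        if np.max(inner) > tol:
            chosen = int(percentiles[lo_margin + int(np.argmax(inner))])
        else:
            chosen = 100

    pi = chosen - 1
    m = counts[pi]
    retained = np.sort(order[:m])
    params = SamplingParameters(
        span=float(spans[pi]), retained_count=int(m), percentile=int(chosen)
    )
    curve = pd.DataFrame(
        {
            "percentile": percentiles,
            "retained_count": counts,
            "span": spans,
            "vector_span": vector_spans,
        }
    )
    return ResosResult(
        central_index=central,
        furthest_index=int(furthest_at[pi]),
        percentile=int(chosen),
        retained_indices=retained,
        params=params,
        curve=curve,
        method=scores.method,
        fallback_warning=fallback,
    )


def filter_at_percentile(
    samples: FluxSampleSet, scores: DensityScores, percentile: int
) -> ResosResult:
    """Retain solutions at a previously saved percentile threshold.

    Reuses a threshold saved from a prior run on the same (baseline)
    model instead of re-deriving the inflection — the saved-parameter
    reuse path for case-specific and knockout analyses.
    """
    if not 1 <= int(percentile) <= 100:
        raise ValueError("percentile must lie in [1, 100]")
    key = scores.ranking_key()
    central = int(np.argmin(key))
    thr = np.percentile(key, percentile)
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    m = max(int(np.searchsorted(sorted_key, thr, side="right")), 1)
    retained = order[:m]
    cand = retained[sorted_key[:m] == sorted_key[m - 1]]
    fu = int(cand.min())
    n = samples.n_samples
    span = float(key[fu] - key[central]) / (n - 1)
    params = SamplingParameters(
        span=span, retained_count=int(m), percentile=int(percentile)
    )
    curve = pd.DataFrame(
        {
            "percentile": [int(percentile)],
            "retained_count": [int(m)],
            "span": [span],
            "vector_span": [
                pairwise_distance(samples.matrix[central], samples.matrix[fu])
            ],
        }
    )
    return ResosResult(
        central_index=central,
        furthest_index=fu,
        percentile=int(percentile),
        retained_indices=np.sort(retained),
        params=params,
        curve=curve,
        method=scores.method,
    )


def filter_solutions(samples: FluxSampleSet, result: ResosResult) -> FluxSampleSet:
    """Return exactly the retained rows of ``samples``."""
    idx = np.asarray(result.retained_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty retained set")
    if idx.min() < 0 or idx.max() >= samples.n_samples:
        raise IndexError("retained index out of range for this sample set")
    return FluxSampleSet(
        matrix=samples.matrix[idx],
        reaction_ids=samples.reaction_ids,
        seed=samples.seed,
        model_digest=samples.model_digest,
        meta={"retained_from": samples.n_samples, "percentile": result.percentile},
    )


def run_resos(
    samples: FluxSampleSet, method: str = "continuous", bins: int = 100
) -> tuple[DensityScores, ResosResult]:
    """Convenience wrapper: score, threshold, and return both stages."""
    scores = score_solutions(samples, method=method, bins=bins)
    result = dynamic_percentile(samples, scores)
    return scores, result
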