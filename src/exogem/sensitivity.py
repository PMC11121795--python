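"""Sensitivity of metabolic tasks to perturbations of measured exchanges.

Each measured exchange is swept across its bounds on an even grid
(100 steps by default); every task is evaluated at each grid point.
The per-task response is summarized as a slope after min-max rescaling
of both axes to [0, 1], making slopes comparable across tasks and
metabolites (a decreasing linear response scores -1, an increasing one
+1, a flat one 0).

Per-patient slope tables stack into a (task x metabolite x patient)
cube, flattened task-major into a patients x features matrix for
PLS-DA.  PLS-DA is a NIPALS implementation against one-hot group
labels with X deflation, giving mutually orthogonal score vectors and
per-component explained label variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicModel
from .tasks import TaskDefinition, evaluate_task_full

__all__ = [
    "SensitivityCube",
    "PlsdaResult",
    "perturbation_sweep",
    "response_slope",
    "build_cube",
    "flatten_cube",
    "unflatten_cube",
    "plsda",
    "pca_check",
]

DEFAULT_SWEEP_STEPS = 100
#: below this many feasible sweep points a slope is reported as 0
MIN_SLOPE_POINTS = 10


def perturbation_sweep(
    model: MetabolicModel,
    exchange_id: str,
    tasks: list[TaskDefinition],
    n_steps: int = DEFAULT_SWEEP_STEPS,
) -> pd.DataFrame:
    """Evaluate every task while pinning one exchange across its range.

    Returns a steps x tasks table indexed by the pinned flux value;
    infeasible grid points are NaN.  The input model is not mutated.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    r = model.reaction(exchange_id)
    lb, ub = r.lower_bound, r.upper_bound
    if lb == ub:
        warnings.warn(
            f"exchange {exchange_id!r} is already fixed; single-point sweep",
            stacklevel=2,
        )
        grid = np.array([lb])
    else:
        grid = np.linspace(lb, ub, n_steps)
    work = model.copy()
    out = np.full((len(grid), len(tasks)), np.nan)
    for i, v in enumerate(grid):
        work.reaction(exchange_id).lower_bound = float(v)
        work.reaction(exchange_id).upper_bound = float(v)
        for j, t in enumerate(tasks):
            score, ok = evaluate_task_full(work, t)
            if ok:
                out[i, j] = score
    return pd.DataFrame(out, index=grid, columns=[t.id for t in tasks])


def response_slope(
    sweep: pd.DataFrame, min_points: int = MIN_SLOPE_POINTS
) -> pd.Series:
    """Per-task least-squares slope after min-max rescaling both axes.

    Tasks with fewer than ``min_points`` feasible points or a constant
    response score 0.
    """
    x_raw = sweep.index.to_numpy(dtype=float)
    slopes = {}
    for tid in sweep.columns:
        y_raw = sweep[tid].to_numpy(dtype=float)
        ok = np.isfinite(y_raw)
        x, y = x_raw[ok], y_raw[ok]
        if len(x) < max(min_points, 2) or np.ptp(x) == 0 or np.ptp(y) == 0:
            slopes[tid] = 0.0
            continue
        xs = (x - x.min()) / np.ptp(x)
        ys = (y - y.min()) / np.ptp(y)
        slopes[tid] = float(np.polyfit(xs, ys, 1)[0])
    return pd.Series(slopes, name="slope")


@dataclass
class SensitivityCube:
    """Task x metabolite x patient response slopes."""

    values: np.ndarray  # shape (n_tasks, n_metabolites, n_patients)
    task_ids: list[str]
    metabolite_ids: list[str]
    patient_ids: list[str]
    feasible_counts: np.ndarray | None = None

    def __post_init__(self):
        expected = (len(self.task_ids), len(self.metabolite_ids), len(self.patient_ids))
        if self.values.shape != expected:
            raise ValueError(
                f"cube shape {self.values.shape} does not match labels {expected}"
            )


def build_cube(per_patient_slopes: dict[str, dict[str, pd.Series]]) -> SensitivityCube:
    """Assemble per-patient {metabolite -> slope-per-task} into a cube.

    All patients must share identical task and metabolite axes.
    """
    patient_ids = list(per_patient_slopes.keys())
    if not patient_ids:
        raise ValueError("no patients")
    first = per_patient_slopes[patient_ids[0]]
    metabolite_ids = list(first.keys())
    if not metabolite_ids:
        raise ValueError("no metabolites")
    task_ids = list(first[metabolite_ids[0]].index)
    values = np.full((len(task_ids), len(metabolite_ids), len(patient_ids)), np.nan)
    for pk, pid in enumerate(patient_ids):
        sweeps = per_patient_slopes[pid]
        if list(sweeps.keys()) != metabolite_ids:
            raise ValueError(f"patient {pid!r}: metabolite axis mismatch")
        for mk, mid in enumerate(metabolite_ids):
            s = sweeps[mid]
            if list(s.index) != task_ids:
                raise ValueError(f"patient {pid!r}, metabolite {mid!r}: task axis mismatch")
            values[:, mk, pk] = s.to_numpy(dtype=float)
    return SensitivityCube(values, task_ids, metabolite_ids, patient_ids)


def flatten_cube(cube: SensitivityCube) -> pd.DataFrame:
    """Patients x (tasks * metabolites) matrix, task-major column order.

    Column ``<task>|<metabolite>``; missing cube cells stay missing.
    """
    n_t, n_m, n_p = cube.values.shape
    flat = cube.values.reshape(n_t * n_m, n_p).T  # task-major, metabolite-minor
    columns = [f"{t}|{m}" for t in cube.task_ids for m in cube.metabolite_ids]
    return pd.DataFrame(flat, index=cube.patient_ids, columns=columns)


def unflatten_cube(flat: pd.DataFrame, task_ids: list[str], metabolite_ids: list[str]) -> SensitivityCube:
    """Inverse of :func:`flatten_cube` (exact round-trip)."""
    n_t, n_m = len(task_ids), len(metabolite_ids)
    if flat.shape[1] != n_t * n_m:
        raise ValueError("column count does not match task x metabolite axes")
    values = flat.to_numpy(dtype=float).T.reshape(n_t, n_m, flat.shape[0])
    return SensitivityCube(values, task_ids, metabolite_ids, list(flat.index))


@dataclass
class PlsdaResult:
    scores: np.ndarray  # patients x components
    x_loadings: np.ndarray  # features x components
    x_weights: np.ndarray  # features x components
    y_loadings: np.ndarray  # groups x components
    explained_y_variance: np.ndarray  # per component, fractions of label variance
    group_labels: list[str]
    feature_names: list[str]
    classes: list[str]

    def feature_ranking(self, n_components: int | None = None) -> pd.Series:
        """Features ranked by summed |loading| over the first K components."""
        k = n_components or self.x_loadings.shape[1]
        weight = np.abs(self.x_loadings[:, :k]).sum(axis=1)
        return pd.Series(weight, index=self.feature_names).sort_values(ascending=False)


def plsda(
    X,
    labels,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PlsdaResult:
    """NIPALS PLS-DA of a feature matrix against one-hot group labels.

    Columns of X are z-scored; zero-variance features are dropped with
    a warning.  Successive score vectors are mutually orthogonal.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        feature_names = [f"f{j}" for j in range(Xm.shape[1])]
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 groups")
    if len(labels) != Xm.shape[0]:
        raise ValueError("label count must match row count")

    sd = Xm.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=2
        )
        Xm = Xm[:, keep]
        feature_names = [f for f, k in zip(feature_names, keep) if k]
        sd = sd[keep]
    Xc = (Xm - Xm.mean(axis=0)) / sd

    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, classes.index(l)] = 1.0
    Y = Y - Y.mean(axis=0)
    ss_y_total = float((Y**2).sum())

    n, p = Xc.shape
    n_components = min(n_components, p, n - 1)
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    W = np.zeros((p, n_components))
    Q = np.zeros((len(classes), n_components))
    evy = np.zeros(n_components)

    Xr, Yr = Xc.copy(), Y.copy()
    for a in range(n_components):
        u = Yr[:, int(np.argmax((Yr**2).sum(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xr.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            t = Xr @ w_new
            q = Yr.T @ t / (t @ t)
            u_new = Yr @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                u = u_new
                break
            w, u = w_new, u_new
        t = Xr @ w
        tt = float(t @ t)
        if tt == 0:
            T, P, W, Q, evy = T[:, :a], P[:, :a], W[:, :a], Q[:, :a], evy[:a]
            break
        p_load = Xr.T @ t / tt
        q = Yr.T @ t / tt
        ss_before = float((Yr**2).sum())
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q)
        ss_after = float((Yr**2).sum())
        T[:, a] = t
        P[:, a] = p_load
        W[:, a] = w
        Q[:, a] = q
        evy[a] = (ss_before - ss_after) / ss_y_total if ss_y_total > 0 else 0.0

    return PlsdaResult(
        scores=T,
        x_loadings=P,
        x_weights=W,
        y_loadings=Q,
        explained_y_variance=np.clip(evy, 0.0, 1.0),
        group_labels=labels,
        feature_names=feature_names,
        classes=classes,
    )


def pca_check(matrix: np.ndarray, origin_labels) -> tuple[np.ndarray, float]:
    """2-component PCA scores plus silhouette over origin labels.

    Used to verify that pooled trio sample clouds separate by
    model-of-origin when patient ratios differ.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(origin_labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 origin labels")
    if X.shape[0] < 2:
        raise ValueError("need at least as many samples as components")
    scores = PCA(n_components=2, svd_solver="full").fit_transform(X - X.mean(axis=0))
    sil = float(silhouette_score(scores, labels))
    return scores, sil
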