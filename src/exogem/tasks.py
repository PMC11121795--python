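"""Metabolic task evaluation and rank-change task selection.

A task asks whether (and how strongly) a model can turn a set of
substrates into a set of products.  Evaluation augments the model's LP
with temporary uptake columns (one per substrate, bounded by the stated
maximum uptake) and sink columns (one per product, with the stated
minimum production as a lower bound), then maximizes total sink flux.
The input model is never mutated.

By default the patient-specific exchange bounds stay active during
evaluation, so tasks probe the patient's constrained capability; pass
``closed_exchanges=True`` for the convention where exchange uptake is
shut off and the task uptakes are the only supply.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
import scipy.sparse as sp

from .model import MetabolicModel, find_exchange_reactions

__all__ = [
    "TaskDefinition",
    "TaskActivityMatrix",
    "evaluate_task",
    "evaluate_task_full",
    "evaluate_task_matrix",
    "compute_group_ranks",
    "select_by_rank_shift",
    "rank_change_filter",
    "load_tasks",
    "save_tasks",
]

#: default substrate uptake cap when a task file omits one
DEFAULT_MAX_UPTAKE = 10.0
#: cap on temporary sink columns (keeps the LP bounded)
SINK_CAP = 1e4


@dataclass
class TaskDefinition:
    id: str
    substrates: list[tuple[str, float]]  # (metabolite id, max uptake flux)
    products: list[tuple[str, float]]  # (metabolite id, min production flux)
    description: str = ""

    def __post_init__(self):
        if not self.products:
            raise ValueError(f"task {self.id!r}: products must be non-empty")
        self.substrates = [(m, float(u)) for m, u in self.substrates]
        self.products = [(m, float(u)) for m, u in self.products]
        for m, u in self.products:
            if u < 0:
                raise ValueError(f"task {self.id!r}: negative min production for {m!r}")


@dataclass
class TaskActivityMatrix:
    """Task x patient activity scores with infeasibility flags."""

    values: pd.DataFrame  # index: task ids, columns: patient ids
    feasible: pd.DataFrame  # same shape, boolean
    group_labels: dict[str, str] = field(default_factory=dict)
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def task_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t")


def _check_metabolites(model: MetabolicModel, task: TaskDefinition) -> None:
    known = set(model.metabolite_ids)
    for m, _ in task.substrates + task.products:
        if m not in known:
            raise KeyError(f"task {task.id!r}: unknown metabolite {m!r}")


def evaluate_task_full(
    model: MetabolicModel,
    task: TaskDefinition,
    closed_exchanges: bool = False,
) -> tuple[float, bool]:
    """Evaluate one task; returns (score, feasible).

    Infeasible task LPs score 0 with ``feasible=False``.
    """
    _check_metabolites(model, task)
    n = len(model.reactions)
    n_up = len(task.substrates)
    n_sink = len(task.products)

    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    if closed_exchanges:
        for rid in find_exchange_reactions(model):
            j = model.index_of(rid)
            lb[j] = max(lb[j], 0.0)  # no uptake through native exchanges
            ub[j] = max(ub[j], 0.0)

    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    extra_lb, extra_ub = [], []
    for k, (m, max_up) in enumerate(task.substrates):
        rows.append(met_index[m])
        cols.append(k)
        vals.append(1.0)  # uptake column produces the substrate
        extra_lb.append(0.0)
        extra_ub.append(max_up)
    for k, (m, min_prod) in enumerate(task.products):
        rows.append(met_index[m])
        cols.append(n_up + k)
        vals.append(-1.0)  # sink column consumes the product
        extra_lb.append(min_prod)
        extra_ub.append(SINK_CAP)
    extra = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), n_up + n_sink)
    )
    A_eq = sp.hstack([model.S, extra], format="csc")
    b_eq = np.zeros(len(model.metabolites))

    c = np.zeros(n + n_up + n_sink)
    c[n + n_up :] = -1.0  # maximize total sink flux
    bounds = list(zip(lb, ub)) + list(zip(extra_lb, extra_ub))
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        return 0.0, False
    if res.status != 0:
        raise RuntimeError(
            f"task {task.id!r}: LP solver failed with status {res.status}"
        )
    return float(-res.fun), True


def evaluate_task(
    model: MetabolicModel, task: TaskDefinition, closed_exchanges: bool = False
) -> float:
    """Task score: maximum total product sink flux (0 when infeasible)."""
    score, _ = evaluate_task_full(model, task, closed_exchanges=closed_exchanges)
    return score


def evaluate_task_matrix(
    models: dict[str, MetabolicModel],
    tasks: list[TaskDefinition],
    group_labels: dict[str, str] | None = None,
    closed_exchanges: bool = False,
) -> TaskActivityMatrix:
    """Evaluate every task against every patient model.

    Per-cell errors are recorded and the run continues; errored cells
    score 0 and are flagged infeasible.
    """
    if not models or not tasks:
        raise ValueError("need at least one model and one task")
    task_ids = [t.id for t in tasks]
    patient_ids = list(models.keys())
    values = pd.DataFrame(0.0, index=task_ids, columns=patient_ids)
    feas = pd.DataFrame(False, index=task_ids, columns=patient_ids)
    errors: dict[tuple[str, str], str] = {}
    for pid, m in models.items():
        for t in tasks:
            try:
                score, ok = evaluate_task_full(m, t, closed_exchanges=closed_exchanges)
            except Exception as exc:  # per-cell failure must not kill the run
                errors[(t.id, pid)] = str(exc)
                score, ok = 0.0, False
            values.loc[t.id, pid] = score
            feas.loc[t.id, pid] = ok
    return TaskActivityMatrix(
        values=values,
        feasible=feas,
        group_labels=dict(group_labels or {}),
        errors=errors,
    )


def compute_group_ranks(
    matrix: TaskActivityMatrix, group_order: list[str]
) -> pd.DataFrame:
    """Per-group task ranks (rank 1 = highest standardized activity).

    Each task row is z-scored over all patients once; groups are then
    ranked on their mean standardized activity.  Ties break by task
    order.  Groups with fewer than 2 patients fall back to centered
    values (a warning is emitted).
    """
    vals = matrix.values
    labels = matrix.group_labels
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    z = vals.sub(mean, axis=0)
    nz = sd > 0
    z.loc[nz] = z.loc[nz].div(sd[nz], axis=0)

    ranks = {}
    for g in group_order:
        members = [p for p in matrix.patient_ids if labels.get(p) == g]
        if not members:
            raise ValueError(f"group {g!r} has no patients")
        if len(members) < 2:
            warnings.warn(f"group {g!r} has < 2 patients", stacklevel=3)
        gmean = z[members].mean(axis=1).to_numpy()
        order = np.argsort(-gmean, kind="stable")
        r = np.empty(len(order), dtype=int)
        r[order] = np.arange(1, len(order) + 1)
        ranks[g] = r
    return pd.DataFrame(ranks, index=matrix.task_ids)


def rank_change_filter(
    matrix: TaskActivityMatrix,
    group_order: list[str],
    min_shift: int = 10,
) -> list[str]:
    """Tasks whose activity rank shifts consistently across groups.

    A task is selected when the rank difference between the first and
    last group is at least ``min_shift`` (inclusive) and the rank
    trajectory across ``group_order`` is monotone (non-strict).
    """
    if len(group_order) < 2:
        raise ValueError("need at least 2 groups")
    ranks = compute_group_ranks(matrix, group_order)
    return select_by_rank_shift(ranks, group_order, min_shift)


def select_by_rank_shift(
    ranks: pd.DataFrame, group_order: list[str], min_shift: int
) -> list[str]:
    """Apply the shift/monotonicity selection rule to a rank table.

    A task passes when |rank_first - rank_last| >= min_shift (inclusive)
    and the rank trajectory across ``group_order`` is monotone
    (non-strict).
    """
    if min_shift < 0:
        raise ValueError("min_shift must be >= 0")
    selected = []
    for tid in ranks.index:
        traj = ranks.loc[tid, group_order].to_numpy()
        if abs(int(traj[0]) - int(traj[-1])) < min_shift:
            continue
        diffs = np.diff(traj)
        if np.all(diffs >= 0) or np.all(diffs <= 0):
            selected.append(tid)
    return selected


# ---------------------------------------------------------------------------
# Task file I/O
# ---------------------------------------------------------------------------

def load_tasks(path: str) -> list[TaskDefinition]:
    """Load tasks from JSON (list of records) or TSV (role rows).

    TSV columns: task_id, role ("substrate"|"product"), metabolite,
    flux (max uptake for substrates, min production for products;
    substrates default to 10 when blank).
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            docs = json.load(fh)
        out = []
        for d in docs:
            out.append(
                TaskDefinition(
                    id=d["id"],
                    substrates=[
                        (s["metabolite"], s.get("max_uptake", DEFAULT_MAX_UPTAKE))
                        for s in d.get("substrates", [])
                    ],
                    products=[
                        (p["metabolite"], p.get("min_production", 0.0))
                        for p in d["products"]
                    ],
                    description=d.get("description", ""),
                )
            )
        return out
    df = pd.read_csv(path, sep="\t")
    out = []
    for tid, grp in df.groupby("task_id", sort=False):
        subs, prods = [], []
        for _, row in grp.iterrows():
            flux = row.get("flux")
            if row["role"] == "substrate":
                subs.append(
                    (row["metabolite"], DEFAULT_MAX_UPTAKE if pd.isna(flux) else float(flux))
                )
            elif row["role"] == "product":
                prods.append((row["metabolite"], 0.0 if pd.isna(flux) else float(flux)))
            else:
                raise ValueError(f"task {tid!r}: unknown role {row['role']!r}")
        out.append(TaskDefinition(id=str(tid), substrates=subs, products=prods))
    return out


def save_tasks(tasks: list[TaskDefinition], path: str) -> None:
    docs = [
        {
            "id": t.id,
            "description": t.description,
            "substrates": [{"metabolite": m, "max_uptake": u} for m, u in t.substrates],
            "products": [{"metabolite": m, "min_production": u} for m, u in t.products],
        }
        for t in tasks
    ]
    with open(path, "w") as fh:
        json.dump(docs, fh, indent=1)
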