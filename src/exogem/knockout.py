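"""Essentiality and synthetic-lethality scanning.

Reaction deletions are simulated by zeroing bounds; post-deletion
biomass is predicted by one of three predictors:

* ``fba``   — re-solve the LP (default);
* ``room``  — minimal number of significant flux changes relative to a
  wild-type reference (LP relaxation by default, exact MILP optional);
* ``resos`` — resample the deleted model with saved density-exploration
  stopping parameters and read biomass off the central solution.

Candidate pruning follows the flux-carrying heuristic of fast
synthetic-lethality screens: only reactions active in a minimal-L1
(parsimonious) optimum are scanned, with exchanges and the objective
excluded by default.

Gene-level essentiality maps to reactions through gene-reaction rules
with OR meaning redundancy (all disjuncts must be essential) and AND
meaning dependency (any essential conjunct makes the reaction
essential).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog, milp, LinearConstraint, Bounds

from .model import (
    FluxVector,
    InfeasibleModelError,
    MetabolicModel,
    delete_reactions,
    fba,
    find_exchange_reactions,
)
from .sampling import SamplingParameters, sample_adaptive

__all__ = [
    "ContingencyTable",
    "KnockoutConfig",
    "prune_candidates",
    "essentiality_scan",
    "synthetic_lethal_scan",
    "room_reference_flux",
    "map_gene_to_reaction_essentiality",
    "prediction_ratio",
]

FLUX_ACTIVE_TOL = 1e-9


@dataclass
class ContingencyTable:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


def prediction_ratio(table: ContingencyTable) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if table.total == 0:
        raise ValueError("contingency table is empty")
    return (table.TP + table.TN) / table.total


@dataclass
class KnockoutConfig:
    viability_fraction: float = 0.05
    exclude: tuple[str, ...] = ("exchanges", "objective")
    predictor: str = "fba"
    # ROOM predictor settings
    room_delta: float = 0.03
    room_epsilon: float = 0.001
    room_exact: bool = False
    # density-based predictor settings
    resos_params: SamplingParameters | None = None
    resos_batch: int = 200
    resos_max_points: int = 2000
    resos_thinning: int = 5
    resos_use_mean: bool = False  # mean of retained instead of central solution
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.viability_fraction < 1.0:
            raise ValueError("viability_fraction must lie in (0, 1)")
        if self.predictor not in ("fba", "room", "resos"):
            raise ValueError(f"unknown predictor {self.predictor!r}")


def prune_candidates(
    model: MetabolicModel, config: KnockoutConfig | None = None
) -> list[str]:
    """Reactions carrying flux in a minimal-L1-norm FBA optimum.

    The objective is pinned to its optimum, total |v| is minimized
    (v = p - n splitting), and reactions with |v| > 1e-9 survive.
    Exchange reactions and the objective are then removed per config.
    """
    config = config or KnockoutConfig()
    opt = fba(model).objective_value  # raises on infeasibility
    n = len(model.reactions)
    lb, ub = model.lower_bounds, model.upper_bounds
    j_obj = model.index_of(model.objective_id)

    # variables: p (positive part), q (negative part); v = p - q
    c = np.ones(2 * n)
    if len(model.metabolites) > 0:
        A_eq = sp.hstack([model.S, -model.S], format="csc")
        b_eq = np.zeros(len(model.metabolites))
    else:
        A_eq, b_eq = None, None
    pl = np.maximum(lb, 0.0)
    pu = np.maximum(ub, 0.0)
    ql = np.maximum(-ub, 0.0)
    qu = np.maximum(-lb, 0.0)
    # pin the objective at its optimum (tiny slack for LP tolerance)
    slack = 1e-9 * max(1.0, abs(opt))
    A_pin = sp.csc_matrix(
        (np.array([1.0, -1.0]), (np.array([0, 0]), np.array([j_obj, n + j_obj]))),
        shape=(1, 2 * n),
    )
    res = linprog(
        c,
        A_eq=sp.vstack([A_eq, A_pin]) if A_eq is not None else A_pin,
        b_eq=np.concatenate([b_eq, [opt]]) if b_eq is not None else np.array([opt]),
        A_ub=None,
        b_ub=None,
        bounds=list(zip(np.concatenate([pl, ql]), np.concatenate([pu, qu]))),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"parsimonious LP failed with status {res.status}")
    v = res.x[:n] - res.x[n:]

    active = {model.reaction_ids[j] for j in range(n) if abs(v[j]) > FLUX_ACTIVE_TOL}
    excluded = set()
    if "exchanges" in config.exclude:
        excluded |= set(find_exchange_reactions(model))
    if "objective" in config.exclude:
        excluded.add(model.objective_id)
    return [rid for rid in model.reaction_ids if rid in active and rid not in excluded]


def _predict_biomass(
    model: MetabolicModel, deleted_ids: list[str], config: KnockoutConfig,
    wild_type: FluxVector,
) -> float:
    """Post-deletion biomass under the configured predictor."""
    if config.predictor == "fba":
        try:
            return fba(delete_reactions(model, deleted_ids)).objective_value
        except InfeasibleModelError:
            return 0.0
    if config.predictor == "room":
        v = room_reference_flux(
            model,
            deleted_ids,
            wild_type,
            delta=config.room_delta,
            epsilon=config.room_epsilon,
            exact=config.room_exact,
        )
        return v.values[model.objective_id]
    # density-based predictor
    if config.resos_params is None:
        raise ValueError("resos predictor requires saved resos_params")
    deleted = delete_reactions(model, deleted_ids)
    try:
        sset = sample_adaptive(
            deleted,
            config.resos_params,
            batch=config.resos_batch,
            max_points=config.resos_max_points,
            seed=config.seed,
            thinning=config.resos_thinning,
        )
    except InfeasibleModelError:
        return 0.0
    result = sset.meta.get("resos")
    j = deleted.index_of(deleted.objective_id)
    if result is None:
        return float(sset.matrix[:, j].mean())
    if config.resos_use_mean:
        return float(sset.matrix[result.retained_indices, j].mean())
    return float(sset.matrix[result.central_index, j])


def essentiality_scan(
    model: MetabolicModel,
    config: KnockoutConfig | None = None,
    candidates: list[str] | None = None,
) -> dict[str, str]:
    """Classify each candidate reaction as essential / non-essential.

    A reaction is essential when predicted post-deletion biomass falls
    below ``viability_fraction`` x wild-type optimum.  Predictor
    failures are recorded as ``"error"`` and the scan continues.
    """
    config = config or KnockoutConfig()
    wt = fba(model)
    if wt.objective_value <= 0:
        raise ValueError("wild-type biomass optimum must be positive")
    threshold = config.viability_fraction * wt.objective_value
    if candidates is None:
        candidates = prune_candidates(model, config)
    out = {}
    for rid in candidates:
        try:
            bm = _predict_biomass(model, [rid], config, wt)
            out[rid] = "essential" if bm < threshold else "non-essential"
        except Exception as exc:
            out[rid] = "error"
    return out


def synthetic_lethal_scan(
    model: MetabolicModel,
    config: KnockoutConfig | None = None,
    candidates: list[str] | None = None,
    essentiality: dict[str, str] | None = None,
    exhaustive: bool = False,
) -> list[tuple[str, str]]:
    """Unordered reaction pairs whose joint deletion kills viability.

    By default the two-stage candidate expansion of fast
    synthetic-lethality screens is used: each non-essential candidate i
    is deleted and reactions that become flux-carrying in the rerouted
    parsimonious optimum are paired with i (this is what catches
    parallel redundant routes, which carry no flux in the wild-type
    optimum).  ``exhaustive=True`` tests every pair of non-excluded,
    non-essential reactions instead.  A reported pair is lethal jointly
    but neither member is lethal alone.
    """
    config = config or KnockoutConfig()
    wt = fba(model)
    threshold = config.viability_fraction * wt.objective_value
    if candidates is None:
        candidates = prune_candidates(model, config)
    if essentiality is None:
        essentiality = essentiality_scan(model, config, candidates)
    essentiality = dict(essentiality)

    excluded = set()
    if "exchanges" in config.exclude:
        excluded |= set(find_exchange_reactions(model))
    if "objective" in config.exclude:
        excluded.add(model.objective_id)

    def is_essential(rid: str) -> bool:
        if rid not in essentiality:
            bm = _predict_biomass(model, [rid], config, wt)
            essentiality[rid] = "essential" if bm < threshold else "non-essential"
        return essentiality[rid] == "essential"

    viable = [r for r in candidates if essentiality.get(r) == "non-essential"]
    if exhaustive:
        universe = [
            r for r in model.reaction_ids if r not in excluded and not is_essential(r)
        ]
        to_test = {
            tuple(sorted((universe[i], universe[j])))
            for i in range(len(universe))
            for j in range(i + 1, len(universe))
        }
    else:
        to_test = set()
        for i in viable:
            for j in viable:
                if j > i:
                    to_test.add((i, j))
            # reactions rerouted through after deleting i
            try:
                rerouted = prune_candidates(delete_reactions(model, [i]), config)
            except InfeasibleModelError:
                continue
            for j in rerouted:
                if j != i and j not in excluded and not is_essential(j):
                    to_test.add(tuple(sorted((i, j))))

    pairs = []
    for a, b in sorted(to_test):
        try:
            bm = _predict_biomass(model, [a, b], config, wt)
        except Exception:
            continue
        if bm < threshold:
            pairs.append((a, b))
    return pairs


def room_reference_flux(
    model: MetabolicModel,
    deleted_ids: list[str],
    wild_type_flux: FluxVector,
    delta: float = 0.03,
    epsilon: float = 0.001,
    exact: bool = False,
) -> FluxVector:
    """Post-deletion flux minimizing the number of significant changes.

    A reaction change is significant when its flux leaves the band
    ``wild_type +- (delta * |wild_type| + epsilon)``.  Binary change
    indicators are relaxed to [0, 1] by default; ``exact=True`` solves
    the MILP.  An infeasible deleted model reports zero flux (biomass 0).
    """
    n = len(model.reactions)
    deleted = delete_reactions(model, deleted_ids)
    lb, ub = deleted.lower_bounds, deleted.upper_bounds
    w = wild_type_flux.as_array(model.reaction_ids)
    wu = w + delta * np.abs(w) + epsilon
    wl = w - delta * np.abs(w) - epsilon

    # variables: v (n), y (n); minimize sum y
    c = np.concatenate([np.zeros(n), np.ones(n)])
    # v_j - y_j (ub_j - wu_j) <= wu_j   (upper escape only when y_j = 1)
    # -v_j - y_j (wl_j - lb_j) <= -wl_j (lower escape only when y_j = 1)
    eye = sp.identity(n, format="csc")
    up = sp.hstack([eye, -sp.diags(np.maximum(ub - wu, 0.0))], format="csc")
    dn = sp.hstack([-eye, -sp.diags(np.maximum(wl - lb, 0.0))], format="csc")
    A_ub = sp.vstack([up, dn], format="csc")
    b_ub = np.concatenate([wu, -wl])
    if len(model.metabolites) > 0:
        A_eq = sp.hstack([deleted.S, sp.csc_matrix((len(model.metabolites), n))], format="csc")
        b_eq = np.zeros(len(model.metabolites))
    else:
        A_eq, b_eq = None, None
    var_lb = np.concatenate([lb, np.zeros(n)])
    var_ub = np.concatenate([ub, np.ones(n)])

    if exact:
        constraints = [LinearConstraint(A_ub, -np.inf, b_ub)]
        if A_eq is not None:
            constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
        integrality = np.concatenate([np.zeros(n), np.ones(n)])
        res = milp(
            c=c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(var_lb, var_ub),
        )
        if res.status != 0 or res.x is None:
            return FluxVector(
                values={r: 0.0 for r in model.reaction_ids}, objective_value=0.0
            )
        v = res.x[:n]
    else:
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=list(zip(var_lb, var_ub)),
            method="highs",
        )
        if res.status == 2:
            return FluxVector(
                values={r: 0.0 for r in model.reaction_ids}, objective_value=0.0
            )
        if res.status != 0:
            raise RuntimeError(f"ROOM LP failed with status {res.status}")
        v = res.x[:n]
    j_obj = model.index_of(model.objective_id)
    return FluxVector(
        values=dict(zip(model.reaction_ids, v.tolist())),
        objective_value=float(v[j_obj]),
    )


# ---------------------------------------------------------------------------
# Gene -> reaction essentiality mapping
# ---------------------------------------------------------------------------

def _tokenize_gpr(rule: str) -> list[str]:
    out = []
    token = ""
    for ch in rule:
        if ch in "()":
            if token:
                out.append(token)
                token = ""
            out.append(ch)
        elif ch.isspace():
            if token:
                out.append(token)
                token = ""
        else:
            token += ch
    if token:
        out.append(token)
    return out


class _GPRParser:
    """Recursive-descent parser evaluating essentiality directly.

    Semantics: an OR of genes is essential only when *all* disjuncts are
    essential (redundancy); an AND is essential when *any* conjunct is
    essential (dependency).  Nested expressions recurse with the same
    rules.
    """

    def __init__(self, tokens: list[str], essential: set[str]):
        self.tokens = tokens
        self.pos = 0
        self.essential = essential

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> bool:
        value = self.expr()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r}")
        return value

    def expr(self) -> bool:  # OR level
        value = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            rhs = self.term()
            value = value and rhs  # all OR branches must be essential
        return value

    def term(self) -> bool:  # AND level
        value = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            rhs = self.factor()
            value = value or rhs  # any AND branch essential suffices
        return value

    def factor(self) -> bool:
        tok = self.next()
        if tok == "(":
            value = self.expr()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses")
            return value
        if tok is None or tok in (")", "and", "or"):
            raise ValueError(f"unexpected token {tok!r}")
        return tok in self.essential


def map_gene_to_reaction_essentiality(
    gpr_rules: dict[str, str], essential_genes
) -> set[str]:
    """Essential reactions implied by essential genes via GPR rules.

    Reactions with empty rules are never essential by this mapping.
    Raises ``ValueError`` naming the reaction on an unparseable rule.
    """
    essential = set(essential_genes)
    out = set()
    for rid, rule in gpr_rules.items():
        if not rule or not rule.strip():
            continue
        try:
            if _GPRParser(_tokenize_gpr(rule), essential).parse():
                out.add(rid)
        except ValueError as exc:
            raise ValueError(f"reaction {rid!r}: unparseable GPR rule: {exc}") from exc
    return out
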