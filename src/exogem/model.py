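"""Core representation of constraint-based metabolic models.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S``
(metabolites x reactions), per-reaction flux bounds, an objective
reaction and gene-reaction rules.  Flux balance analysis (FBA) and its
variants are solved as linear programs with scipy's HiGHS backend:

    maximize  c . v   subject to   S v = 0,  lb <= v <= ub

Sign convention for exchange reactions: negative flux = uptake,
positive flux = secretion.
"""

from __future__ import annotations

import copy as _copy
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "Metabolite",
    "MetabolicModel",
    "FluxVector",
    "ModelValidationError",
    "InfeasibleModelError",
    "UnboundedModelError",
    "load_model",
    "write_model",
    "find_exchange_reactions",
    "fba",
    "fva",
    "set_biomass_floor",
    "delete_reactions",
    "validation_report",
]

#: absolute feasibility tolerance on S.v for accepted flux vectors
STEADY_STATE_TOL = 1e-6
#: slack allowed outside [lb, ub] for accepted flux vectors
BOUND_TOL = 1e-9


class ModelValidationError(ValueError):
    """A model file or in-memory model violates a structural invariant."""


class InfeasibleModelError(RuntimeError):
    """The LP for this model has no feasible point."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


class UnboundedModelError(RuntimeError):
    """The LP objective is unbounded in the optimization direction."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""
    gene_reaction_rule: str = ""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class FluxVector:
    """One steady-state flux distribution over a model's reactions."""

    values: dict[str, float]
    objective_value: float

    def as_array(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.values[r] for r in reaction_ids], dtype=float)


class MetabolicModel:
    """A genome-scale metabolic model.

    Parameters
    ----------
    reactions, metabolites
        Ordered reaction and metabolite records.
    objective_id
        Reaction id of the (biomass) objective.
    """

    def __init__(
        self,
        reactions: list[Reaction],
        metabolites: list[Metabolite],
        objective_id: str,
        id: str = "model",
    ):
        self.reactions = list(reactions)
        self.metabolites = list(metabolites)
        self.objective_id = objective_id
        self.id = id
        self._validate()
        self._build_matrix()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        for r in self.reactions:
            if not np.isfinite(r.lower_bound) and r.lower_bound != -np.inf:
                raise ModelValidationError(f"reaction {r.id!r}: bad lower bound")
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            for m in r.stoichiometry:
                if m not in met_ids:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: unknown metabolite {m!r}"
                    )
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def _build_matrix(self) -> None:
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoichiometry.items():
                rows.append(self._met_index[m])
                cols.append(j)
                vals.append(float(coef))
        self.S = sp.csc_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    # -- accessors ----------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model") from None

    def index_of(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model") from None

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions], dtype=float)

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions], dtype=float)

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        r = self.reaction(rid)
        if lb > ub:
            raise ModelValidationError(f"reaction {rid!r}: lb {lb} > ub {ub}")
        r.lower_bound = float(lb)
        r.upper_bound = float(ub)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            [_copy.deepcopy(r) for r in self.reactions],
            [_copy.deepcopy(m) for m in self.metabolites],
            self.objective_id,
            id=self.id,
        )

    def digest(self) -> str:
        """Content hash covering structure, bounds and objective."""
        payload = {
            "reactions": [
                [
                    r.id,
                    sorted((m, repr(c)) for m, c in r.stoichiometry.items()),
                    repr(r.lower_bound),
                    repr(r.upper_bound),
                    r.gene_reaction_rule,
                ]
                for r in self.reactions
            ],
            "metabolites": [[m.id, m.compartment] for m in self.metabolites],
            "objective": self.objective_id,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id!r}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _inf(x, default):
    if x is None:
        return default
    return float(x)


def load_model(path: str, format: str | None = None) -> MetabolicModel:
    """Load a model from COBRA-dialect JSON or SBML L3/FBC.

    ``format`` is ``"json"`` or ``"sbml"``; when ``None`` it is inferred
    from the file extension (``.json`` vs anything else).
    """
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    if format == "json":
        return _load_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _load_json(path: str) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", ""),
        )
        for m in doc.get("metabolites", [])
    ]
    rxns = []
    objective_id = None
    for rec in doc.get("reactions", []):
        rid = rec.get("id")
        if rid is None:
            raise ModelValidationError("reaction record without an id")
        if "metabolites" not in rec:
            raise ModelValidationError(
                f"reaction {rid!r}: missing stoichiometry ('metabolites')"
            )
        if "lower_bound" not in rec or "upper_bound" not in rec:
            raise ModelValidationError(f"reaction {rid!r}: missing bounds")
        stoich = {m: float(c) for m, c in rec["metabolites"].items()}
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(rec["lower_bound"]),
                upper_bound=float(rec["upper_bound"]),
                name=rec.get("name", ""),
                gene_reaction_rule=rec.get("gene_reaction_rule", ""),
            )
        )
        if rec.get("objective_coefficient", 0):
            objective_id = rid
    if objective_id is None:
        raise ModelValidationError("no reaction has a nonzero objective_coefficient")
    return MetabolicModel(rxns, mets, objective_id, id=doc.get("id", "model"))


def _load_sbml(path: str) -> MetabolicModel:
    # SBML parsing is delegated to COBRApy (libsbml underneath); the
    # result is converted into the light-weight representation used here.
    import cobra.io

    cm = cobra.io.read_sbml_model(path)
    mets = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cm.metabolites
    ]
    objective_id = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective_id = r.id
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            name=r.name or "",
            gene_reaction_rule=r.gene_reaction_rule or "",
        )
        for r in cm.reactions
    ]
    if objective_id is None:
        raise ModelValidationError("SBML model declares no objective reaction")
    return MetabolicModel(rxns, mets, objective_id, id=cm.id or "model")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    """Write a model as COBRA-dialect JSON (default) or SBML."""
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    if format == "json":
        doc = {
            "id": model.id,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in model.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "metabolites": dict(sorted(r.stoichiometry.items())),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gene_reaction_rule": r.gene_reaction_rule,
                    "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
                }
                for r in model.reactions
            ],
            "genes": [],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif format == "sbml":
        import cobra
        import cobra.io

        cm = cobra.Model(model.id)
        cm.add_metabolites(
            [
                cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
                for m in model.metabolites
            ]
        )
        crxns = []
        for r in model.reactions:
            cr = cobra.Reaction(
                r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
            )
            crxns.append(cr)
        cm.add_reactions(crxns)
        for r in model.reactions:
            cr = cm.reactions.get_by_id(r.id)
            cr.add_metabolites(
                {cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
            )
            cr.gene_reaction_rule = r.gene_reaction_rule
        cm.objective = cm.reactions.get_by_id(model.objective_id)
        cobra.io.write_sbml_model(cm, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Analysis primitives
# ---------------------------------------------------------------------------

def find_exchange_reactions(model: MetabolicModel) -> list[str]:
    """Boundary reactions: exactly one metabolite in the stoichiometry.

    Order follows the model's reaction order.
    """
    return [r.id for r in model.reactions if len(r.stoichiometry) == 1]


def _solve_lp(model: MetabolicModel, c: np.ndarray, sense: str):
    """Solve max/min c.v subject to S v = 0 and bounds; return OptimizeResult."""
    n = len(model.reactions)
    lb, ub = model.lower_bounds, model.upper_bounds
    sign = -1.0 if sense == "max" else 1.0
    if len(model.metabolites) > 0:
        A_eq = model.S
        b_eq = np.zeros(len(model.metabolites))
    else:
        A_eq, b_eq = None, None
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res, sign


def fba(model: MetabolicModel, sense: str = "max") -> FluxVector:
    """Flux balance analysis: optimize the objective reaction's flux.

    Raises :class:`InfeasibleModelError` / :class:`UnboundedModelError`
    with the solver status attached when the LP is not solvable.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.index_of(model.objective_id)] = 1.0
    res, sign = _solve_lp(model, c, sense)
    if res.status == 2:
        raise InfeasibleModelError(
            f"model {model.id!r} is infeasible (solver status {res.status})",
            status=res.status,
        )
    if res.status == 3:
        raise UnboundedModelError(
            f"objective of model {model.id!r} is unbounded for sense={sense!r}"
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failed with status {res.status}: {res.message}")
    v = np.asarray(res.x, dtype=float)
    return FluxVector(
        values=dict(zip(model.reaction_ids, v.tolist())),
        objective_value=float(-res.fun if sense == "max" else res.fun),
    )


def optimize_objective(model: MetabolicModel, c: np.ndarray, sense: str = "max") -> np.ndarray:
    """Optimize an arbitrary linear objective over the flux polytope."""
    res, _ = _solve_lp(model, c, sense)
    if res.status == 2:
        raise InfeasibleModelError(
            f"model {model.id!r} is infeasible", status=res.status
        )
    if res.status == 3:
        raise UnboundedModelError("objective unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return np.asarray(res.x, dtype=float)


def fva(model: MetabolicModel, reaction_ids: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: attainable [min, max] flux per reaction."""
    rids = reaction_ids if reaction_ids is not None else model.reaction_ids
    n = len(model.reactions)
    out = {}
    for rid in rids:
        c = np.zeros(n)
        c[model.index_of(rid)] = 1.0
        lo = optimize_objective(model, c, "min")[model.index_of(rid)]
        hi = optimize_objective(model, c, "max")[model.index_of(rid)]
        out[rid] = (float(lo), float(hi))
    return out


def set_biomass_floor(model: MetabolicModel, fraction: float) -> MetabolicModel:
    """Return a copy whose objective lower bound enforces viability.

    The objective reaction's lower bound is set to
    ``fraction * FBA optimum``; ``fraction=0`` leaves bounds untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = model.copy()
    if fraction == 0.0:
        return out
    opt = fba(model).objective_value
    r = out.reaction(out.objective_id)
    r.lower_bound = fraction * opt
    if r.lower_bound > r.upper_bound:  # numerically degenerate optimum
        r.lower_bound = r.upper_bound
    return out


def delete_reactions(model: MetabolicModel, ids) -> MetabolicModel:
    """Return a copy with lb = ub = 0 for each named reaction.

    Deletion keeps the matrix shape (no structural removal) so sampled
    matrices remain comparable across knockouts.
    """
    out = model.copy()
    for rid in ids:
        r = out.reaction(rid)  # raises KeyError naming the id
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    return out


def validation_report(model: MetabolicModel) -> str:
    """Plain-text structural summary of a model."""
    n_ex = len(find_exchange_reactions(model))
    n_rev = sum(1 for r in model.reactions if r.lower_bound < 0 < r.upper_bound)
    n_blocked = sum(
        1 for r in model.reactions if r.lower_bound == r.upper_bound == 0.0
    )
    n_gpr = sum(1 for r in model.reactions if r.gene_reaction_rule.strip())
    lines = [
        f"model: {model.id}",
        f"reactions: {len(model.reactions)}",
        f"metabolites: {len(model.metabolites)}",
        f"exchange reactions: {n_ex}",
        f"reversible reactions: {n_rev}",
        f"zero-bounded reactions: {n_blocked}",
        f"reactions with gene rules: {n_gpr}",
        f"objective: {model.objective_id}",
        f"digest: {model.digest()}",
    ]
    try:
        opt = fba(model).objective_value
        lines.append(f"FBA optimum: {opt:.6g}")
    except (InfeasibleModelError, UnboundedModelError) as exc:
        lines.append(f"FBA: {exc.__class__.__name__}")
    return "\n".join(lines) + "\n"


def check_flux_feasible(model: MetabolicModel, v: np.ndarray) -> bool:
    """True when |S.v| <= 1e-6 and bounds hold to 1e-9 slack."""
    v = np.asarray(v, dtype=float)
    if len(model.metabolites) > 0:
        if np.max(np.abs(model.S @ v)) > STEADY_STATE_TOL:
            return False
    lb, ub = model.lower_bounds, model.upper_bounds
    return bool(np.all(v >= lb - BOUND_TOL) and np.all(v <= ub + BOUND_TOL))
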