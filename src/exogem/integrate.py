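"""Integration of relative plasma-metabolome data into a baseline model.

Measured metabolite concentrations enter the model as ratios against a
control group (min / mean / max control statistics, giving three ratio
vectors per patient).  Each mapped exchange reaction's baseline bounds
— the envelope of density-retained baseline samples — are rescaled by
the patient ratio:

    bound_patient = bound_baseline * (C_patient / C_control)

Exchanges whose baseline envelope is identically zero are opened to
(-10, +10) before rescaling.  Three models per patient (one per control
statistic) are sampled and fused; the density-exploration filter on the
fused cloud yields the consensus patient-specific model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicModel, fba, InfeasibleModelError
from .resos import ResosResult, run_resos
from .sampling import FluxSampleSet, SamplingParameters

__all__ = [
    "PatientCohort",
    "ControlStats",
    "BaselineProfile",
    "compute_control_stats",
    "baseline_profile",
    "compute_ratios",
    "rescale_boundary",
    "rescale_bounds",
    "build_patient_trio",
    "build_consensus_model",
    "ZERO_FLUX_BOUND",
]

#: bounds substituted for exchanges with an identically-zero baseline envelope
ZERO_FLUX_BOUND = 10.0
#: replacement for zero control statistics in ratio denominators
CONTROL_EPS = 1e-6

TRIO_STATS = ("min", "mean", "max")


@dataclass
class PatientCohort:
    """Patient and control concentration tables plus model mapping."""

    patient_table: pd.DataFrame  # patients x metabolites
    control_table: pd.DataFrame  # controls x metabolites
    metabolite_map: dict[str, str]  # metabolite name -> exchange reaction id
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        shared = [c for c in self.patient_table.columns if c in self.control_table.columns]
        if not shared:
            raise ValueError("patient and control tables share no metabolite columns")
        if (self.patient_table[shared] < 0).any().any():
            raise ValueError("negative patient concentrations")
        if (self.control_table[shared] < 0).any().any():
            raise ValueError("negative control concentrations")

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.patient_table.columns if c in self.control_table.columns]

    @property
    def patients(self) -> list[str]:
        return [str(p) for p in self.patient_table.index]

    def validate_against(self, model: MetabolicModel) -> None:
        rids = set(model.reaction_ids)
        for met, rid in self.metabolite_map.items():
            if rid not in rids:
                raise ValueError(
                    f"metabolite {met!r} maps to unknown exchange {rid!r}"
                )

    def to_tsv(self, patient_path: str, control_path: str, map_path: str | None = None) -> None:
        self.patient_table.to_csv(patient_path, sep="\t")
        self.control_table.to_csv(control_path, sep="\t")
        if map_path is not None:
            pd.Series(self.metabolite_map, name="exchange_id").rename_axis(
                "metabolite"
            ).to_csv(map_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        patient_path: str,
        control_path: str,
        map_path: str,
        group_labels: dict[str, str] | None = None,
    ) -> "PatientCohort":
        pt = pd.read_csv(patient_path, sep="\t", index_col=0)
        ct = pd.read_csv(control_path, sep="\t", index_col=0)
        mp = pd.read_csv(map_path, sep="\t", index_col=0)["exchange_id"].to_dict()
        return cls(pt, ct, mp, group_labels or {})


@dataclass
class ControlStats:
    """Per-metabolite min / mean / max over the control group."""

    table: pd.DataFrame  # index: metabolites; columns: min, mean, max

    def __post_init__(self):
        t = self.table
        if not ((t["min"] <= t["mean"] + 1e-12) & (t["mean"] <= t["max"] + 1e-12)).all():
            raise ValueError("control stats must satisfy min <= mean <= max")

    def stat(self, which: str) -> pd.Series:
        return self.table[which]


def compute_control_stats(control_table: pd.DataFrame) -> ControlStats:
    return ControlStats(
        pd.DataFrame(
            {
                "min": control_table.min(axis=0),
                "mean": control_table.mean(axis=0),
                "max": control_table.max(axis=0),
            }
        )
    )


@dataclass
class BaselineProfile:
    """Per-reaction flux envelope of the density-retained baseline samples."""

    lower: pd.Series  # index: reaction ids
    upper: pd.Series
    resos_params: SamplingParameters

    def __post_init__(self):
        if not (self.lower <= self.upper + 1e-12).all():
            raise ValueError("profile must satisfy lower <= upper")

    def bounds(self, rid: str) -> tuple[float, float]:
        return float(self.lower[rid]), float(self.upper[rid])

    def to_json(self, path: str) -> None:
        import json

        doc = {
            "lower": self.lower.to_dict(),
            "upper": self.upper.to_dict(),
            "resos_params": self.resos_params.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "BaselineProfile":
        import json

        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            lower=pd.Series(doc["lower"]),
            upper=pd.Series(doc["upper"]),
            resos_params=SamplingParameters.from_dict(doc["resos_params"]),
        )


def baseline_profile(
    model: MetabolicModel, samples: FluxSampleSet, resos: ResosResult
) -> BaselineProfile:
    """Min/max flux per reaction over the density-retained samples."""
    idx = np.asarray(resos.retained_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty retained set")
    if samples.reaction_ids != model.reaction_ids:
        raise ValueError("sample reaction ordering does not match the model")
    retained = samples.matrix[idx]
    return BaselineProfile(
        lower=pd.Series(retained.min(axis=0), index=samples.reaction_ids),
        upper=pd.Series(retained.max(axis=0), index=samples.reaction_ids),
        resos_params=resos.params,
    )


def compute_ratios(
    cohort: PatientCohort, stats: ControlStats, patient: str
) -> dict[str, pd.Series]:
    """Patient / control concentration ratios for each control statistic."""
    if patient not in cohort.patient_table.index:
        raise KeyError(f"unknown patient {patient!r}")
    mets = cohort.metabolites
    conc = cohort.patient_table.loc[patient, mets].astype(float)
    if (conc < 0).any():
        raise ValueError(f"negative concentration for patient {patient!r}")
    out = {}
    for which in TRIO_STATS:
        denom = stats.stat(which).reindex(mets).astype(float)
        if denom.isna().any():
            missing = list(denom.index[denom.isna()])
            raise ValueError(f"control stats missing for metabolites {missing}")
        zero = denom == 0.0
        if zero.any():
            warnings.warn(
                f"control {which} is zero for {list(denom.index[zero])}; "
                f"substituting epsilon {CONTROL_EPS}",
                stacklevel=2,
            )
            denom = denom.mask(zero, CONTROL_EPS)
        out[which] = conc / denom
    return out


def rescale_boundary(baseline_bound: float, ratio: float, audit: bool = False) -> float:
    """Rescale one nonzero baseline bound by a concentration ratio.

    The rescaling reduces algebraically to ``bound * ratio``; with
    ``audit=True`` the unreduced expression
    ``b + (b/b) * b * (ratio - 1)`` is evaluated as well and both forms
    must agree to 1e-12.
    """
    if not np.isfinite(baseline_bound) or not np.isfinite(ratio):
        raise ValueError("inputs must be finite")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    value = baseline_bound * ratio
    if audit and baseline_bound != 0.0:
        literal = baseline_bound + (baseline_bound / baseline_bound) * baseline_bound * (
            ratio - 1.0
        )
        if abs(literal - value) > 1e-12 * max(1.0, abs(value)):
            raise AssertionError("audit mismatch between literal and reduced forms")
    return value


def rescale_bounds(
    lower: float, upper: float, ratio: float
) -> tuple[float, float, bool]:
    """Rescale an exchange's (lower, upper) baseline envelope.

    A (0, 0) envelope is replaced by (-10, +10) before rescaling.  If
    rescaling ever inverts the pair the bounds are swapped and the third
    element of the returned tuple flags it.
    """
    if lower == 0.0 and upper == 0.0:
        lower, upper = -ZERO_FLUX_BOUND, ZERO_FLUX_BOUND
    lo = rescale_boundary(lower, ratio)
    hi = rescale_boundary(upper, ratio)
    swapped = False
    if lo > hi:
        lo, hi = hi, lo
        swapped = True
    return lo, hi, swapped


def apply_profile(
    model: MetabolicModel,
    profile: BaselineProfile,
    reaction_ids: list[str] | None = None,
) -> MetabolicModel:
    """Copy of ``model`` constrained to the baseline envelope.

    ``reaction_ids`` restricts the constraint to a subset (e.g. the
    exchange reactions); by default every reaction is constrained.
    """
    out = model.copy()
    subset = set(reaction_ids) if reaction_ids is not None else None
    for r in out.reactions:
        if subset is not None and r.id not in subset:
            continue
        lo, hi = profile.bounds(r.id)
        r.lower_bound, r.upper_bound = lo, hi
    return out


def build_patient_trio(
    model: MetabolicModel,
    profile: BaselineProfile,
    cohort: PatientCohort,
    stats: ControlStats,
    patient: str,
) -> dict[str, MetabolicModel]:
    """Three baseline-constrained models with patient-rescaled exchanges.

    One model per control statistic ("min", "mean", "max").  Following
    the protocol, the density envelope is imposed on the *exchange*
    reactions only (internal reactions keep the base model's bounds);
    mapped exchanges are then rescaled by the patient ratio.  Rescaled
    bounds are clamped back into the model's own bounds for that
    reaction — a patient cannot exceed the network's physical
    capabilities; an empty intersection pins the exchange at the
    nearest model bound.  Unmapped measured metabolites are warned
    about and leave bounds untouched.  Models that end up
    FBA-infeasible are flagged via the ``feasible`` attribute.
    """
    cohort.validate_against(model)
    ratios = compute_ratios(cohort, stats, patient)
    unmapped = [m for m in cohort.metabolites if m not in cohort.metabolite_map]
    if unmapped:
        warnings.warn(
            f"measured metabolites without exchange mapping (bounds untouched): "
            f"{unmapped}",
            stacklevel=2,
        )
    from .model import find_exchange_reactions

    exchanges = find_exchange_reactions(model)
    trio = {}
    for which in TRIO_STATS:
        m = apply_profile(model, profile, reaction_ids=exchanges)
        m.id = f"{model.id}__{patient}__{which}"
        for met, rid in cohort.metabolite_map.items():
            if met not in ratios[which].index:
                continue
            r = m.reaction(rid)
            lo, hi, swapped = rescale_bounds(
                r.lower_bound, r.upper_bound, float(ratios[which][met])
            )
            if swapped:
                warnings.warn(
                    f"bounds swapped after rescaling for {rid!r} "
                    f"(patient {patient!r}, stat {which!r})",
                    stacklevel=2,
                )
            mlo = model.reaction(rid).lower_bound
            mhi = model.reaction(rid).upper_bound
            lo2, hi2 = max(lo, mlo), min(hi, mhi)
            if lo2 > hi2:  # rescaled window left the feasible range entirely
                pin = mlo if hi < mlo else mhi
                lo2 = hi2 = pin
            r.lower_bound, r.upper_bound = lo2, hi2
        try:
            fba(m)
            m.feasible = True
        except InfeasibleModelError:
            m.feasible = False
            warnings.warn(
                f"patient {patient!r} {which!r}-model is infeasible", stacklevel=2
            )
        trio[which] = m
    return trio


def relax_infeasible_exchanges(
    model: MetabolicModel,
    exchange_ids: list[str],
    margin: float = 1e-6,
) -> tuple[MetabolicModel, float]:
    """Minimally widen exchange windows until the model is feasible.

    Independently rescaled exchange windows can be jointly infeasible
    through network coupling.  This solves an elastic LP: slack
    variables on the named exchanges' bounds are penalized L1, and the
    optimal slacks (plus a tiny margin) are folded back into the
    bounds.  Returns the repaired copy and the total slack used (0 when
    the model was already feasible).
    """
    import scipy.sparse as sp
    from scipy.optimize import linprog

    try:
        fba(model)
        return model.copy(), 0.0
    except InfeasibleModelError:
        pass
    n = len(model.reactions)
    idx = [model.index_of(r) for r in exchange_ids]
    k = len(idx)
    lb, ub = model.lower_bounds, model.upper_bounds
    # variables: v (n), s_lo (k), s_hi (k); minimize total slack
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    rows = np.arange(k)
    pick = sp.csc_matrix((np.ones(k), (rows, idx)), shape=(k, n))
    # v_j - s_hi_j <= ub_j ; -v_j - s_lo_j <= -lb_j   (for relaxed exchanges)
    A_ub = sp.vstack(
        [
            sp.hstack([pick, sp.csc_matrix((k, k)), -sp.identity(k)]),
            sp.hstack([-pick, -sp.identity(k), sp.csc_matrix((k, k))]),
        ],
        format="csc",
    )
    b_ub = np.concatenate([ub[idx], -lb[idx]])
    A_eq = sp.hstack([model.S, sp.csc_matrix((len(model.metabolites), 2 * k))], format="csc")
    b_eq = np.zeros(len(model.metabolites))
    var_lb = np.concatenate([lb, np.zeros(2 * k)])
    var_ub = np.concatenate([ub, np.full(2 * k, np.inf)])
    var_lb[idx] = -np.inf
    var_ub[idx] = np.inf
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=list(zip(var_lb, var_ub)), method="highs",
    )
    if res.status != 0:
        raise InfeasibleModelError(
            f"model {model.id!r} cannot be repaired by exchange relaxation",
            status=res.status,
        )
    s_lo = res.x[n : n + k]
    s_hi = res.x[n + k :]
    out = model.copy()
    for j, rid in enumerate(exchange_ids):
        r = out.reaction(rid)
        if s_lo[j] > 0:
            r.lower_bound -= s_lo[j] + margin
        if s_hi[j] > 0:
            r.upper_bound += s_hi[j] + margin
    return out, float(s_lo.sum() + s_hi.sum())


def build_consensus_model(
    model: MetabolicModel,
    trio_samples: dict[str, FluxSampleSet] | list[FluxSampleSet],
    method: str = "continuous",
    percentile: int | None = None,
) -> tuple[MetabolicModel, ResosResult]:
    """Fuse the trio sample clouds and constrain a consensus model.

    The three sample sets are concatenated, the density filter runs on
    the fusion, and the consensus model's per-reaction bounds become
    the min/max envelope of the retained fused solutions.  Passing
    ``percentile`` reuses a threshold saved from the baseline run
    instead of re-deriving the inflection on the fused cloud.
    """
    sets = list(trio_samples.values()) if isinstance(trio_samples, dict) else list(trio_samples)
    if not sets:
        raise ValueError("no sample sets given")
    rids = sets[0].reaction_ids
    for s in sets[1:]:
        if s.reaction_ids != rids:
            raise ValueError("reaction ordering differs between trio sample sets")
    if rids != model.reaction_ids:
        raise ValueError("sample reaction ordering does not match the model")
    fused = FluxSampleSet(
        matrix=np.vstack([s.matrix for s in sets]),
        reaction_ids=rids,
        seed=sets[0].seed,
        model_digest=model.digest(),
    )
    if percentile is None:
        _, result = run_resos(fused, method=method)
    else:
        from .resos import filter_at_percentile, score_solutions

        scores = score_solutions(fused, method=method)
        result = filter_at_percentile(fused, scores, percentile)
    retained = fused.matrix[result.retained_indices]
    out = model.copy()
    out.id = f"{model.id}__consensus"
    for j, r in enumerate(out.reactions):
        r.lower_bound = float(retained[:, j].min())
        r.upper_bound = float(retained[:, j].max())
    return out, result
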