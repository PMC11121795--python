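"""Synthetic fixtures: a hand-authored toy metabolic network and
simulated patient cohorts with planted group structure.

The toy network has 22 reactions over 18 metabolites:

* 8 exchange reactions (``EX_*``) — the "measurable" metabolites;
* an uptake-to-biomass backbone ``T_a/T_o -> V1 -> V2a|V2b -> BIOMASS``;
* a parallel redundant pair ``V2a``/``V2b`` (a synthetic-lethal pair:
  either alone suffices, losing both kills biomass);
* a dead-end transporter ``T_de`` that can never carry flux (its
  substrate is never produced), for candidate-pruning tests;
* side routes ``V3`` (alternative substrate to secretion) and ``V4``
  (overflow) that give the flux polytope interior volume.

The fixture ships as versioned JSON package data; :func:`make_toy_model`
loads it so code and file cannot drift.

Cohorts are simulated as lognormal control baselines with
multiplicative fold-change effects planted on metabolite subsets per
patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .integrate import PatientCohort
from .model import MetabolicModel, Metabolite, Reaction, load_model

__all__ = [
    "CohortSpec",
    "GroupEffect",
    "make_toy_model",
    "build_toy_model",
    "toy_metabolite_map",
    "toy_tasks",
    "simulate_cohort",
]

_UPT = 10.0
_BIG = 1000.0


def build_toy_model() -> MetabolicModel:
    """Construct the toy network in code (source of the shipped fixture)."""
    mets = []
    for mid in ["a", "o", "n", "r", "p", "q", "s", "de"]:
        mets.append(Metabolite(f"{mid}_e", name=f"met_{mid} (extracellular)", compartment="e"))
        mets.append(Metabolite(f"{mid}_c", name=f"met_{mid} (cytosol)", compartment="c"))
    mets.append(Metabolite("b_c", name="precursor b", compartment="c"))
    mets.append(Metabolite("c_c", name="precursor c", compartment="c"))

    def ex(mid, lb, ub):
        return Reaction(
            id=f"EX_{mid}",
            stoichiometry={f"{mid}_e": -1.0},
            lower_bound=lb,
            upper_bound=ub,
            name=f"{mid} exchange",
        )

    def tr(mid, src, dst, lb, ub, gpr=""):
        return Reaction(
            id=f"T_{mid}",
            stoichiometry={src: -1.0, dst: 1.0},
            lower_bound=lb,
            upper_bound=ub,
            name=f"{mid} transport",
            gene_reaction_rule=gpr,
        )

    rxns = [
        # exchanges: uptake substrates (negative flux = uptake) ...
        ex("a", -_UPT, 0.0),
        ex("o", -_UPT, 0.0),
        ex("n", -_UPT, 0.0),
        ex("r", -_UPT, 0.0),
        # ... and secreted products
        ex("p", 0.0, _BIG),
        ex("q", 0.0, _BIG),
        ex("s", 0.0, _BIG),
        ex("de", 0.0, _BIG),
        tr("a", "a_e", "a_c", 0.0, _UPT, "gta1 and gta2"),
        tr("o", "o_e", "o_c", 0.0, _UPT, "gto1 or gto2"),
        tr("n", "n_e", "n_c", 0.0, _UPT, "gtn"),
        tr("r", "r_e", "r_c", 0.0, _UPT),
        tr("p", "p_c", "p_e", 0.0, _BIG),
        tr("q", "q_c", "q_e", 0.0, _BIG),
        tr("s", "s_c", "s_e", 0.0, _BIG),
        tr("de", "de_c", "de_e", 0.0, _BIG),  # dead end: de_c is never produced
        Reaction(
            id="V1",
            stoichiometry={"a_c": -1.0, "o_c": -1.0, "b_c": 1.0, "p_c": 1.0},
            lower_bound=0.0,
            upper_bound=_BIG,
            name="backbone synthesis",
            gene_reaction_rule="g1",
        ),
        Reaction(
            id="V2a",
            stoichiometry={"b_c": -1.0, "c_c": 1.0},
            lower_bound=0.0,
            upper_bound=_BIG,
            name="conversion route a",
            gene_reaction_rule="g2a",
        ),
        Reaction(
            id="V2b",
            stoichiometry={"b_c": -1.0, "c_c": 1.0},
            lower_bound=0.0,
            upper_bound=_BIG,
            name="conversion route b",
            gene_reaction_rule="g2b",
        ),
        Reaction(
            id="V3",
            stoichiometry={"r_c": -1.0, "q_c": 1.0},
            lower_bound=0.0,
            upper_bound=_BIG,
            name="side route",
        ),
        Reaction(
            id="V4",
            stoichiometry={"a_c": -1.0, "p_c": 1.0},
            lower_bound=0.0,
            upper_bound=_BIG,
            name="overflow",
        ),
        Reaction(
            id="BIOMASS",
            stoichiometry={"c_c": -1.0, "n_c": -1.0, "s_c": 1.0},
            lower_bound=0.0,
            upper_bound=_BIG,
            name="biomass",
        ),
    ]
    return MetabolicModel(rxns, mets, objective_id="BIOMASS", id="toy22")


def make_toy_model() -> MetabolicModel:
    """Load the shipped 22-reaction toy fixture."""
    with resources.as_file(
        resources.files("exogem").joinpath("data/toy_model.json")
    ) as p:
        return load_model(str(p), format="json")


def toy_metabolite_map() -> dict[str, str]:
    """Measured-metabolite name -> exchange reaction id for the fixture."""
    return {f"met_{m}": f"EX_{m}" for m in ["a", "o", "n", "r", "p", "q", "s", "de"]}


def toy_tasks() -> list:
    """Ten example substrate->product tasks for the toy fixture."""
    from .tasks import TaskDefinition

    t = TaskDefinition
    return [
        t("backbone_product", [("a_c", 10.0), ("o_c", 10.0)], [("b_c", 0.0)],
          "b from cytosolic a + o"),
        t("conversion", [("b_c", 10.0)], [("c_c", 0.0)], "b to c via either route"),
        t("biomass_precursor", [("a_c", 10.0), ("o_c", 10.0)], [("c_c", 0.0)],
          "c from cytosolic a + o"),
        t("overflow_secretion", [("a_c", 10.0)], [("p_e", 0.0)],
          "extracellular p from cytosolic a"),
        t("side_route", [("r_c", 10.0)], [("q_c", 0.0)], "q from cytosolic r"),
        t("nitrogen_import", [("n_e", 10.0)], [("n_c", 0.0)], "n transport capacity"),
        t("s_production", [("c_c", 5.0), ("n_c", 5.0)], [("s_c", 0.0)],
          "s via the biomass reaction"),
        t("dead_end_product", [("a_c", 10.0)], [("de_c", 0.0)],
          "unreachable product (always 0)"),
        t("q_from_external_r", [("r_e", 10.0)], [("q_e", 0.0)],
          "full side pathway capacity"),
        t("p_from_external_a", [("a_e", 10.0)], [("p_e", 0.0)],
          "full overflow pathway capacity"),
    ]


@dataclass
class GroupEffect:
    """Multiplicative fold change planted on a metabolite subset."""

    metabolites: list[str]
    fold_change: float

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")


@dataclass
class CohortSpec:
    """Recipe for a synthetic patient cohort with planted group structure."""

    n_groups: int = 4
    patients_per_group: int = 6
    n_controls: int = 20
    n_metabolites: int = 8
    control_log_mean: float | list[float] = 0.0
    control_log_sd: float | list[float] = 0.25
    effects: dict[str, GroupEffect | list[GroupEffect]] = field(default_factory=dict)
    metabolite_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_groups, self.patients_per_group, self.n_controls, self.n_metabolites) < 1:
            raise ValueError("all counts must be >= 1")
        names = self.metabolite_names or [f"met_{i}" for i in range(self.n_metabolites)]
        if len(names) != self.n_metabolites:
            raise ValueError("metabolite_names length must equal n_metabolites")
        self.metabolite_names = names
        self.effects = {
            g: list(e) if isinstance(e, (list, tuple)) else [e]
            for g, e in self.effects.items()
        }
        for label, effs in self.effects.items():
            for eff in effs:
                unknown = set(eff.metabolites) - set(names)
                if unknown:
                    raise ValueError(
                        f"group {label!r} effect on unknown metabolites {unknown}"
                    )

    @property
    def group_names(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_groups)]


def simulate_cohort(
    spec: CohortSpec, metabolite_map: dict[str, str] | None = None
) -> PatientCohort:
    """Simulate a cohort: lognormal controls, multiplicative group effects.

    Patient concentrations are independent draws from the control
    distribution times the group's fold change on its affected
    metabolites.  A fixed seed yields bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.metabolite_names
    mu = np.broadcast_to(np.asarray(spec.control_log_mean, float), (spec.n_metabolites,))
    sd = np.broadcast_to(np.asarray(spec.control_log_sd, float), (spec.n_metabolites,))

    control = rng.lognormal(mu, sd, size=(spec.n_controls, spec.n_metabolites))
    control_table = pd.DataFrame(
        control, index=[f"control_{i}" for i in range(spec.n_controls)], columns=names
    )

    rows, labels = [], {}
    index = []
    for g in spec.group_names:
        fold = np.ones(spec.n_metabolites)
        for eff in spec.effects.get(g, []):
            for m in eff.metabolites:
                fold[names.index(m)] *= eff.fold_change
        for k in range(spec.patients_per_group):
            pid = f"patient_{g}{k}"
            base = rng.lognormal(mu, sd)
            rows.append(base * fold)
            index.append(pid)
            labels[pid] = g
    patient_table = pd.DataFrame(rows, index=index, columns=names)

    return PatientCohort(
        patient_table=patient_table,
        control_table=control_table,
        metabolite_map=dict(metabolite_map or {}),
        group_labels=labels,
    )
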