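"""End-to-end orchestration: baseline -> patient trios -> consensus ->
tasks -> stratification, with optional validation and sensitivity
stages.  All randomness flows from a single master seed.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .integrate import (
    BaselineProfile,
    PatientCohort,
    baseline_profile,
    build_consensus_model,
    build_patient_trio,
    compute_control_stats,
    relax_infeasible_exchanges,
)
from .model import InfeasibleModelError, MetabolicModel, fba, set_biomass_floor
from .resos import run_resos
from .sampling import FluxSampleSet, sample_fluxes
from .stratify import cluster_group_contributions, hierarchical_cluster, row_standardize
from .tasks import TaskDefinition, evaluate_task_matrix, rank_change_filter

__all__ = ["RunManifest", "CohortPipelineResult", "run_cohort_pipeline", "run_pipeline"]


@dataclass
class RunManifest:
    command: str
    config_digest: str
    model_digest: str
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)
    stages_completed: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)
        for p in self.outputs:
            if not os.path.exists(p):
                raise RuntimeError(f"manifest lists missing output {p!r}")


@dataclass
class CohortPipelineResult:
    baseline: BaselineProfile
    consensus_models: dict[str, MetabolicModel]
    trio_samples: dict[str, dict[str, FluxSampleSet]]
    activity: object  # TaskActivityMatrix
    cluster_assignment: object | None = None
    group_contributions: pd.DataFrame | None = None
    selected_tasks: list[str] | None = None


def run_cohort_pipeline(
    model: MetabolicModel,
    cohort: PatientCohort,
    tasks: list[TaskDefinition],
    seed: int = 0,
    n_baseline: int = 2000,
    n_patient: int = 600,
    thinning: int = 5,
    biomass_floor: float = 0.5,
    n_clusters: int | None = None,
    min_rank_shift: int | None = None,
) -> CohortPipelineResult:
    """Run the core protocol on an in-memory model + cohort.

    Step 1: constrain biomass to ``biomass_floor`` of its optimum,
    sample the baseline, and keep the density-retained flux envelope.
    Step 2: per patient, rescale mapped exchange bounds by the
    min/mean/max control ratios and sample each trio model.
    Step 3: fuse each trio's samples into a consensus model.
    Step 4: evaluate tasks on consensus models and cluster patients.
    """
    base = set_biomass_floor(model, biomass_floor)
    baseline_samples = sample_fluxes(base, n_baseline, seed=seed, thinning=thinning)
    _, base_resos = run_resos(baseline_samples)
    profile = baseline_profile(base, baseline_samples, base_resos)

    stats = compute_control_stats(cohort.control_table[cohort.metabolites])
    consensus: dict[str, MetabolicModel] = {}
    trio_samples: dict[str, dict[str, FluxSampleSet]] = {}
    rng = np.random.default_rng(seed)
    for patient in cohort.patients:
        trio = build_patient_trio(base, profile, cohort, stats, patient)
        samples = {}
        mapped = sorted(set(cohort.metabolite_map.values()))
        for which, pm in trio.items():
            sub_seed = int(rng.integers(2**31 - 1))
            if not getattr(pm, "feasible", True):
                # jointly infeasible rescaled windows: widen the mapped
                # exchange windows by the minimal elastic-LP slack
                pm, _ = relax_infeasible_exchanges(pm, mapped)
            samples[which] = sample_fluxes(
                pm, n_patient, seed=sub_seed, thinning=thinning
            )
        if not samples:
            raise RuntimeError(
                f"all trio models for patient {patient!r} are infeasible"
            )
        # reuse the baseline's saved threshold for case-specific clouds
        cmodel, _ = build_consensus_model(
            base, samples, percentile=base_resos.percentile
        )
        cmodel.id = f"{model.id}__{patient}"
        consensus[patient] = cmodel
        trio_samples[patient] = samples

    activity = evaluate_task_matrix(consensus, tasks, group_labels=cohort.group_labels)

    assignment = None
    contributions = None
    selected = None
    groups = sorted(set(cohort.group_labels.values()))
    if n_clusters is None:
        n_clusters = max(2, len(groups))
    if len(cohort.patients) >= 2:
        standardized, _ = row_standardize(activity.values)
        assignment = hierarchical_cluster(standardized, axis="columns", k=n_clusters)
        if cohort.group_labels:
            contributions = cluster_group_contributions(
                assignment, cohort.group_labels, groups=groups
            )
    if min_rank_shift is not None and len(groups) >= 2:
        selected = rank_change_filter(activity, groups, min_shift=min_rank_shift)

    return CohortPipelineResult(
        baseline=profile,
        consensus_models=consensus,
        trio_samples=trio_samples,
        activity=activity,
        cluster_assignment=assignment,
        group_contributions=contributions,
        selected_tasks=selected,
    )


def _config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: dict, out_dir: str, seed: int | None = None) -> RunManifest:
    """Config-driven pipeline run writing TSV/JSON artifacts + manifest.

    Schema violations raise before any computation.  See the README for
    the config layout.
    """
    from .model import load_model, write_model
    from .synthetic import (
        CohortSpec,
        GroupEffect,
        make_toy_model,
        simulate_cohort,
        toy_metabolite_map,
        toy_tasks,
    )
    from .tasks import load_tasks

    # -- pre-flight validation ---------------------------------------
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key in ("model", "cohort"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    model_ref = config["model"]
    if model_ref != "toy" and not os.path.exists(model_ref):
        raise FileNotFoundError(f"model path {model_ref!r} does not exist")
    seed = int(config.get("seed", 0) if seed is None else seed)
    os.makedirs(out_dir, exist_ok=True)

    manifest = RunManifest(
        command="run",
        config_digest=_config_digest(config),
        model_digest="",
        seed=seed,
        version=__version__,
        started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )

    model = make_toy_model() if model_ref == "toy" else load_model(model_ref)
    manifest.model_digest = model.digest()

    cconf = config["cohort"]
    if "synth" in cconf:
        sc = dict(cconf["synth"])
        effects = {
            g: GroupEffect(metabolites=e["metabolites"], fold_change=e["fold_change"])
            for g, e in sc.pop("effects", {}).items()
        }
        spec = CohortSpec(seed=seed, effects=effects, **sc)
        mmap = cconf.get("metabolite_map") or toy_metabolite_map()
        if isinstance(mmap, str):
            mmap = pd.read_csv(mmap, sep="\t", index_col=0)["exchange_id"].to_dict()
        cohort = simulate_cohort(spec, metabolite_map=mmap)
    else:
        cohort = PatientCohort.from_tsv(
            cconf["patients"], cconf["controls"], cconf["map"],
            group_labels=cconf.get("group_labels", {}),
        )

    tref = config.get("tasks", "toy")
    tasks = toy_tasks() if tref == "toy" else load_tasks(tref)

    samp = config.get("sampling", {})
    result = run_cohort_pipeline(
        model,
        cohort,
        tasks,
        seed=seed,
        n_baseline=int(samp.get("n_baseline", 2000)),
        n_patient=int(samp.get("n_patient", 600)),
        thinning=int(samp.get("thinning", 5)),
        biomass_floor=float(config.get("biomass_floor", 0.5)),
        min_rank_shift=config.get("min_rank_shift"),
    )

    # -- artifacts ----------------------------------------------------
    def _out(name):
        p = os.path.join(out_dir, name)
        manifest.outputs.append(p)
        return p

    cohort.to_tsv(_out("patients.tsv"), _out("controls.tsv"), _out("metabolite_map.tsv"))
    result.baseline.to_json(_out("baseline_profile.json"))
    manifest.stages_completed.append("baseline")
    for pid, cm in result.consensus_models.items():
        write_model(cm, _out(f"consensus_{pid}.json"))
    manifest.stages_completed.append("consensus")
    result.activity.to_tsv(_out("task_activity.tsv"))
    manifest.stages_completed.append("tasks")
    if result.cluster_assignment is not None:
        result.cluster_assignment.to_json(_out("clusters.json"))
        if result.group_contributions is not None:
            result.group_contributions.to_csv(_out("group_contributions.tsv"), sep="\t")
        manifest.stages_completed.append("stratify")
    if result.selected_tasks is not None:
        with open(_out("selected_tasks.json"), "w") as fh:
            json.dump(result.selected_tasks, fh, indent=1)

    manifest.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return manifest
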