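import numpy as np
import pandas as pd
import pytest

from exogem.integrate import (
    BaselineProfile,
    PatientCohort,
    ZERO_FLUX_BOUND,
    apply_profile,
    baseline_profile,
    build_consensus_model,
    build_patient_trio,
    compute_control_stats,
    compute_ratios,
    relax_infeasible_exchanges,
    rescale_boundary,
    rescale_bounds,
)
from exogem.model import fba, find_exchange_reactions
from exogem.sampling import FluxSampleSet, sample_fluxes
from exogem.synthetic import toy_metabolite_map


def _cohort(patients, controls, mmap=None):
    return PatientCohort(
        patient_table=pd.DataFrame(patients).T
        if isinstance(patients, dict)
        else patients,
        control_table=pd.DataFrame(controls).T
        if isinstance(controls, dict)
        else controls,
        metabolite_map=mmap or {},
    )


@pytest.fixture(scope="module")
def profile(floored_model, baseline_samples, baseline_resos):
    _, result = baseline_resos
    return baseline_profile(floored_model, baseline_samples, result)


class TestControlStats:
    def test_min_mean_max(self):
        ct = pd.DataFrame({"m1": [1.0, 2.0, 3.0], "m2": [2.0, 2.0, 2.0]})
        stats = compute_control_stats(ct)
        assert stats.table.loc["m1", "min"] == 1.0
        assert stats.table.loc["m1", "mean"] == 2.0
        assert stats.table.loc["m1", "max"] == 3.0

    def test_ordering_invariant_enforced(self):
        bad = pd.DataFrame({"min": [3.0], "mean": [2.0], "max": [1.0]}, index=["m"])
        from exogem.integrate import ControlStats

        with pytest.raises(ValueError):
            ControlStats(bad)


class TestComputeRatios:
    def _simple(self):
        pt = pd.DataFrame({"m": [4.0]}, index=["p1"])
        ct = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["c1", "c2", "c3"])
        return PatientCohort(pt, ct, {})

    def test_min_mean_max_ratios(self):
        cohort = self._simple()
        stats = compute_control_stats(cohort.control_table)
        ratios = compute_ratios(cohort, stats, "p1")
        assert ratios["min"]["m"] == pytest.approx(4.0)
        assert ratios["mean"]["m"] == pytest.approx(2.0)
        assert ratios["max"]["m"] == pytest.approx(4.0 / 3.0)

    def test_patient_at_control_mean_gives_one(self):
        pt = pd.DataFrame({"m": [2.0]}, index=["p1"])
        ct = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        cohort = PatientCohort(pt, ct, {})
        stats = compute_control_stats(ct)
        assert compute_ratios(cohort, stats, "p1")["mean"]["m"] == pytest.approx(1.0)

    def test_degenerate_control_spread(self):
        pt = pd.DataFrame({"m": [2.0]}, index=["p1"])
        ct = pd.DataFrame({"m": [2.0, 2.0, 2.0]})
        cohort = PatientCohort(pt, ct, {})
        ratios = compute_ratios(cohort, compute_control_stats(ct), "p1")
        for which in ("min", "mean", "max"):
            assert ratios[which]["m"] == pytest.approx(1.0)

    def test_zero_control_epsilon_with_warning(self):
        pt = pd.DataFrame({"m": [2.0]}, index=["p1"])
        ct = pd.DataFrame({"m": [0.0, 0.0]})
        cohort = PatientCohort(pt, ct, {})
        with pytest.warns(UserWarning, match="epsilon"):
            ratios = compute_ratios(cohort, compute_control_stats(ct), "p1")
        assert ratios["mean"]["m"] == pytest.approx(2.0 / 1e-6)

    def test_unknown_patient(self):
        cohort = self._simple()
        with pytest.raises(KeyError):
            compute_ratios(cohort, compute_control_stats(cohort.control_table), "zz")

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            PatientCohort(
                pd.DataFrame({"m": [-1.0]}, index=["p1"]),
                pd.DataFrame({"m": [1.0]}),
                {},
            )


class TestRescaleBoundary:
    def test_ratio_one_is_identity(self):
        assert rescale_boundary(-5.0, 1.0) == -5.0
        assert rescale_boundary(7.25, 1.0) == 7.25

    def test_doubling(self):
        assert rescale_boundary(-5.0, 2.0) == -10.0

    def test_audit_agrees_with_reduced_form(self):
        for b in (-5.0, 3.2, 0.7):
            for r in (0.1, 1.0, 2.5):
                assert rescale_boundary(b, r, audit=True) == pytest.approx(
                    b * r, abs=1e-12
                )

    def test_homogeneity(self):
        for b in (-4.0, 2.0):
            for r in (0.5, 3.0):
                assert rescale_boundary(b, r) == pytest.approx(
                    r * rescale_boundary(b, 1.0)
                )

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            rescale_boundary(1.0, -0.1)

    def test_zero_baseline_pair_substitution(self):
        lo, hi, swapped = rescale_bounds(0.0, 0.0, 1.0)
        assert (lo, hi) == (-ZERO_FLUX_BOUND, ZERO_FLUX_BOUND)
        assert not swapped
        lo2, hi2, _ = rescale_bounds(0.0, 0.0, 2.0)
        assert (lo2, hi2) == (-2 * ZERO_FLUX_BOUND, 2 * ZERO_FLUX_BOUND)


class TestBaselineProfile:
    def test_matches_brute_force_min_max(self, floored_model, baseline_samples, baseline_resos):
        _, result = baseline_resos
        prof = baseline_profile(floored_model, baseline_samples, result)
        retained = baseline_samples.matrix[result.retained_indices]
        for j, rid in enumerate(baseline_samples.reaction_ids):
            assert prof.lower[rid] == pytest.approx(retained[:, j].min())
            assert prof.upper[rid] == pytest.approx(retained[:, j].max())

    def test_profile_within_model_bounds(self, floored_model, profile):
        lb = floored_model.lower_bounds
        ub = floored_model.upper_bounds
        for j, rid in enumerate(floored_model.reaction_ids):
            assert profile.lower[rid] >= lb[j] - 1e-9
            assert profile.upper[rid] <= ub[j] + 1e-9

    def test_constant_column_collapses(self, floored_model):
        matrix = np.tile(
            fba(floored_model).as_array(floored_model.reaction_ids), (12, 1)
        )
        s = FluxSampleSet(matrix, floored_model.reaction_ids)
        from exogem.resos import DensityScores, filter_at_percentile, ResosResult

        sc = DensityScores(
            totals=np.arange(12.0), normalized=np.arange(12.0) / 66.0,
            method="continuous",
        )
        result = filter_at_percentile(s, sc, 100)
        prof = baseline_profile(floored_model, s, result)
        assert (prof.lower == prof.upper).all()

    def test_json_round_trip(self, profile, tmp_path):
        p = tmp_path / "prof.json"
        profile.to_json(str(p))
        again = BaselineProfile.from_json(str(p))
        assert np.allclose(again.lower.values, profile.lower.values)
        assert again.resos_params == profile.resos_params


class TestBuildPatientTrio:
    def _unit_cohort(self, value=1.0):
        mmap = toy_metabolite_map()
        names = list(mmap.keys())
        pt = pd.DataFrame([[value] * len(names)], index=["p1"], columns=names)
        ct = pd.DataFrame([[1.0] * len(names)] * 3, columns=names)
        return PatientCohort(pt, ct, mmap)

    def test_all_ratios_one_equals_baseline_constrained(self, floored_model, profile):
        cohort = self._unit_cohort(1.0)
        stats = compute_control_stats(cohort.control_table)
        trio = build_patient_trio(floored_model, profile, cohort, stats, "p1")
        exchanges = find_exchange_reactions(floored_model)
        reference = apply_profile(floored_model, profile, reaction_ids=exchanges)
        for which, m in trio.items():
            for rid in exchanges:
                r0, r1 = reference.reaction(rid), m.reaction(rid)
                # zero-envelope exchanges are opened to (-10, 10) by the rule
                if r0.lower_bound == 0.0 and r0.upper_bound == 0.0:
                    continue
                assert r1.lower_bound == pytest.approx(r0.lower_bound)
                assert r1.upper_bound == pytest.approx(r0.upper_bound)

    def test_doubled_metabolite_doubles_mapped_bounds(self, floored_model, profile):
        mmap = {"met_q": "EX_q"}  # secretion exchange, far from model bounds
        pt = pd.DataFrame([[2.0]], index=["p1"], columns=["met_q"])
        ct = pd.DataFrame([[1.0]] * 3, columns=["met_q"])
        cohort = PatientCohort(pt, ct, mmap)
        stats = compute_control_stats(ct)
        trio = build_patient_trio(floored_model, profile, cohort, stats, "p1")
        lo, hi = profile.bounds("EX_q")
        for m in trio.values():
            r = m.reaction("EX_q")
            assert r.lower_bound == pytest.approx(2 * lo)
            assert r.upper_bound == pytest.approx(2 * hi)

    def test_unmapped_metabolite_warns_and_leaves_bounds(self, floored_model, profile):
        mmap = {"met_q": "EX_q"}
        pt = pd.DataFrame([[1.0, 5.0]], index=["p1"], columns=["met_q", "met_x"])
        ct = pd.DataFrame([[1.0, 1.0]] * 3, columns=["met_q", "met_x"])
        cohort = PatientCohort(pt, ct, mmap)
        stats = compute_control_stats(ct)
        with pytest.warns(UserWarning, match="without exchange mapping"):
            trio = build_patient_trio(floored_model, profile, cohort, stats, "p1")
        lo, hi = profile.bounds("EX_a")
        assert trio["mean"].reaction("EX_a").lower_bound == pytest.approx(lo)

    def test_unknown_mapping_rejected(self, floored_model, profile):
        cohort = self._unit_cohort()
        cohort.metabolite_map["met_a"] = "EX_missing"
        stats = compute_control_stats(cohort.control_table)
        with pytest.raises(ValueError, match="EX_missing"):
            build_patient_trio(floored_model, profile, cohort, stats, "p1")


class TestConsensusModel:
    def test_identical_sets_reproduce_profile_envelope(
        self, floored_model, baseline_samples, baseline_resos
    ):
        _, result = baseline_resos
        trio = {k: baseline_samples for k in ("min", "mean", "max")}
        consensus, fres = build_consensus_model(
            floored_model, trio, percentile=result.percentile
        )
        retained = np.vstack([baseline_samples.matrix] * 3)[fres.retained_indices]
        for j, rid in enumerate(floored_model.reaction_ids):
            assert consensus.reaction(rid).lower_bound == pytest.approx(
                retained[:, j].min()
            )
            assert consensus.reaction(rid).upper_bound == pytest.approx(
                retained[:, j].max()
            )

    def test_envelope_matches_brute_force(self, floored_model):
        rng = np.random.default_rng(8)
        sets = []
        base = sample_fluxes(floored_model, 80, seed=3, thinning=2)
        for k in range(3):
            sets.append(
                FluxSampleSet(
                    base.matrix[rng.permutation(80)], base.reaction_ids
                )
            )
        consensus, result = build_consensus_model(floored_model, sets, percentile=50)
        fused = np.vstack([s.matrix for s in sets])
        retained = fused[result.retained_indices]
        assert consensus.reaction("V1").lower_bound == pytest.approx(
            retained[:, floored_model.index_of("V1")].min()
        )

    def test_central_feasible_in_consensus(self, floored_model, baseline_samples, baseline_resos):
        _, result = baseline_resos
        trio = {k: baseline_samples for k in ("min", "mean", "max")}
        consensus, fres = build_consensus_model(
            floored_model, trio, percentile=result.percentile
        )
        fused = np.vstack([baseline_samples.matrix] * 3)
        central = fused[fres.central_index]
        lb = consensus.lower_bounds
        ub = consensus.upper_bounds
        assert np.all(central >= lb - 1e-9) and np.all(central <= ub + 1e-9)

    def test_reaction_order_mismatch_rejected(self, floored_model, baseline_samples):
        shuffled = FluxSampleSet(
            baseline_samples.matrix, list(reversed(baseline_samples.reaction_ids))
        )
        with pytest.raises(ValueError, match="ordering"):
            build_consensus_model(floored_model, [baseline_samples, shuffled])


class TestRelaxation:
    def test_feasible_model_zero_slack(self, floored_model):
        repaired, slack = relax_infeasible_exchanges(
            floored_model, find_exchange_reactions(floored_model)
        )
        assert slack == 0.0
        assert repaired.digest() == floored_model.digest()

    def test_repairs_conflicting_windows(self, floored_model):
        broken = floored_model.copy()
        # force more secretion of p than any feasible uptake of a allows
        broken.set_bounds("EX_p", 15.0, 20.0)
        with pytest.raises(Exception):
            fba(broken)
        repaired, slack = relax_infeasible_exchanges(
            broken, find_exchange_reactions(broken)
        )
        assert slack > 0
        fba(repaired)  # feasible now
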