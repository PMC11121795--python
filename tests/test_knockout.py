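import itertools

import numpy as np
import pytest

from exogem.knockout import (
    ContingencyTable,
    KnockoutConfig,
    essentiality_scan,
    map_gene_to_reaction_essentiality,
    prediction_ratio,
    prune_candidates,
    room_reference_flux,
    synthetic_lethal_scan,
)
from exogem.model import (
    InfeasibleModelError,
    delete_reactions,
    fba,
    find_exchange_reactions,
)


def exhaustive_essentials(model, fraction=0.05, exclude_exchanges=True):
    """Oracle: re-solve the LP for every candidate deletion."""
    wt = fba(model).objective_value
    excluded = set(find_exchange_reactions(model)) if exclude_exchanges else set()
    excluded.add(model.objective_id)
    out = set()
    for rid in model.reaction_ids:
        if rid in excluded:
            continue
        try:
            bm = fba(delete_reactions(model, [rid])).objective_value
        except InfeasibleModelError:
            bm = 0.0
        if bm < fraction * wt:
            out.add(rid)
    return out


def exhaustive_sl_pairs(model, fraction=0.05):
    """Oracle: test every non-excluded, non-essential pair by re-solve."""
    wt = fba(model).objective_value
    excluded = set(find_exchange_reactions(model)) | {model.objective_id}
    essentials = exhaustive_essentials(model, fraction)
    viable = [
        r for r in model.reaction_ids if r not in excluded and r not in essentials
    ]
    pairs = set()
    for a, b in itertools.combinations(viable, 2):
        try:
            bm = fba(delete_reactions(model, [a, b])).objective_value
        except InfeasibleModelError:
            bm = 0.0
        if bm < fraction * wt:
            pairs.add(tuple(sorted((a, b))))
    return pairs


class TestContingency:
    def test_symmetric(self):
        assert prediction_ratio(ContingencyTable(1, 1, 1, 1)) == 0.5

    def test_perfect(self):
        assert prediction_ratio(ContingencyTable(10, 5, 0, 0)) == 1.0

    def test_direct_arithmetic(self):
        assert prediction_ratio(ContingencyTable(2500, 0, 83, 0)) == pytest.approx(
            2500 / 2583
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prediction_ratio(ContingencyTable(0, 0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_partition_counts(self, toy_model):
        # TP+TN+FP+FN must equal the evaluated set size
        predicted = essentiality_scan(toy_model)
        truth = exhaustive_essentials(toy_model)
        tp = sum(1 for r, v in predicted.items() if v == "essential" and r in truth)
        fp = sum(1 for r, v in predicted.items() if v == "essential" and r not in truth)
        fn = sum(1 for r, v in predicted.items() if v == "non-essential" and r in truth)
        tn = sum(
            1 for r, v in predicted.items() if v == "non-essential" and r not in truth
        )
        assert tp + fp + fn + tn == len(predicted)


class TestPruneCandidates:
    def test_excludes_dead_end(self, toy_model):
        assert "T_de" not in prune_candidates(toy_model)

    def test_excludes_exchanges_and_objective(self, toy_model):
        cands = prune_candidates(toy_model)
        assert not any(c.startswith("EX_") for c in cands)
        assert "BIOMASS" not in cands

    def test_candidates_carry_flux(self, toy_model):
        # every candidate must be active in some optimal flux pattern
        cands = prune_candidates(toy_model)
        assert set(cands) >= {"V1", "T_a", "T_o", "T_n"}

    def test_infeasible_rejected(self, toy_model):
        m = toy_model.copy()
        m.reaction("T_de").lower_bound = 1.0
        m.reaction("T_de").upper_bound = 1.0
        with pytest.raises(InfeasibleModelError):
            prune_candidates(m)


class TestEssentialityScan:
    def test_matches_exhaustive_oracle(self, toy_model):
        predicted = essentiality_scan(toy_model)
        truth = exhaustive_essentials(toy_model)
        for rid, verdict in predicted.items():
            assert (verdict == "essential") == (rid in truth), rid

    def test_backbone_essential_under_all_predictors(self, toy_model, baseline_resos):
        _, result = baseline_resos
        for predictor in ("fba", "room", "resos"):
            config = KnockoutConfig(
                predictor=predictor, resos_params=result.params, seed=3
            )
            scan = essentiality_scan(toy_model, config, candidates=["V1"])
            assert scan["V1"] == "essential", predictor

    def test_parallel_route_non_essential(self, toy_model):
        scan = essentiality_scan(toy_model, candidates=["V2a", "V2b"])
        assert scan == {"V2a": "non-essential", "V2b": "non-essential"}

    def test_zero_flux_dead_end_non_essential(self, toy_model):
        scan = essentiality_scan(toy_model, candidates=["T_de"])
        assert scan["T_de"] == "non-essential"

    def test_nonpositive_wild_type_rejected(self, toy_model):
        dead = delete_reactions(toy_model, ["V1"])
        with pytest.raises(ValueError):
            essentiality_scan(dead)


class TestSyntheticLethals:
    def test_pair_scan_matches_exhaustive_oracle(self, toy_model):
        assert set(synthetic_lethal_scan(toy_model)) == exhaustive_sl_pairs(toy_model)

    def test_exhaustive_flag_agrees(self, toy_model):
        assert set(synthetic_lethal_scan(toy_model, exhaustive=True)) == (
            exhaustive_sl_pairs(toy_model)
        )

    def test_parallel_pair_reported(self, toy_model):
        assert ("V2a", "V2b") in synthetic_lethal_scan(toy_model)

    def test_no_pair_contains_essential(self, toy_model):
        essentials = exhaustive_essentials(toy_model)
        for a, b in synthetic_lethal_scan(toy_model):
            assert a not in essentials and b not in essentials

    def test_empty_candidates_empty_pairs(self, toy_model):
        assert synthetic_lethal_scan(toy_model, candidates=[]) == []


def count_out_of_band(model, v, wild_type, delta=0.03, epsilon=0.001):
    w = wild_type.as_array(model.reaction_ids)
    wu = w + delta * np.abs(w) + epsilon
    wl = w - delta * np.abs(w) - epsilon
    return int(np.sum((v > wu + 1e-6) | (v < wl - 1e-6)))


def min_changes_oracle(model, deleted_ids, wild_type, delta=0.03, epsilon=0.001):
    """Independent oracle: smallest k such that allowing k reactions out of
    band admits a feasible flux (subset enumeration + plain feasibility LP)."""
    from scipy.optimize import linprog

    deleted = delete_reactions(model, deleted_ids)
    n = len(model.reactions)
    w = wild_type.as_array(model.reaction_ids)
    wu = w + delta * np.abs(w) + epsilon
    wl = w - delta * np.abs(w) - epsilon
    lb, ub = deleted.lower_bounds, deleted.upper_bounds

    def feasible_with_free(free):
        lo = np.where(np.isin(np.arange(n), free), lb, np.maximum(lb, wl))
        hi = np.where(np.isin(np.arange(n), free), ub, np.minimum(ub, wu))
        if np.any(lo > hi):
            return False
        res = linprog(
            np.zeros(n),
            A_eq=deleted.S,
            b_eq=np.zeros(len(model.metabolites)),
            bounds=list(zip(lo, hi)),
            method="highs",
        )
        return res.status == 0

    for k in range(0, 4):
        for free in itertools.combinations(range(n), k):
            if feasible_with_free(np.array(free, dtype=int)):
                return k
    return None


class TestRoom:
    def test_no_deletion_keeps_wild_type(self, toy_model):
        wt = fba(toy_model)
        v = room_reference_flux(toy_model, [], wt)
        arr = np.array([v.values[r] for r in toy_model.reaction_ids])
        assert count_out_of_band(toy_model, arr, wt) == 0

    def test_delete_zero_flux_reaction(self, toy_model):
        wt = fba(toy_model)
        v = room_reference_flux(toy_model, ["T_de"], wt)
        arr = np.array([v.values[r] for r in toy_model.reaction_ids])
        assert count_out_of_band(toy_model, arr, wt) == 0
        assert v.objective_value == pytest.approx(wt.objective_value, rel=1e-4)

    def test_reroute_matches_enumeration_oracle(self, toy_model):
        # deleting the active parallel route forces a reroute through the
        # other; the number of significant changes must match the oracle
        wt = fba(toy_model)
        active = "V2a" if abs(wt.values["V2a"]) > abs(wt.values["V2b"]) else "V2b"
        expected_k = min_changes_oracle(toy_model, [active], wt)
        assert expected_k is not None
        v = room_reference_flux(toy_model, [active], wt, exact=True)
        arr = np.array([v.values[r] for r in toy_model.reaction_ids])
        assert count_out_of_band(toy_model, arr, wt) == expected_k

    def test_lp_relaxation_bounds_exact_count(self, toy_model):
        wt = fba(toy_model)
        active = "V2a" if abs(wt.values["V2a"]) > abs(wt.values["V2b"]) else "V2b"
        exact = room_reference_flux(toy_model, [active], wt, exact=True)
        relaxed = room_reference_flux(toy_model, [active], wt, exact=False)
        arr_e = np.array([exact.values[r] for r in toy_model.reaction_ids])
        arr_r = np.array([relaxed.values[r] for r in toy_model.reaction_ids])
        # the relaxation may move more reactions, never fewer than optimal
        assert count_out_of_band(toy_model, arr_r, wt) >= count_out_of_band(
            toy_model, arr_e, wt
        )

    def test_infeasible_deletion_reports_zero_biomass(self, toy_model):
        wt = fba(toy_model)
        m = toy_model.copy()
        m.reaction("BIOMASS").lower_bound = 1.0  # forced biomass, then cut V1
        v = room_reference_flux(m, ["V1"], wt)
        assert v.objective_value == 0.0


class TestGPRMapping:
    def test_rule_single_gene(self):
        assert map_gene_to_reaction_essentiality({"R1": "g1"}, {"g1"}) == {"R1"}
        assert map_gene_to_reaction_essentiality({"R1": "g1"}, {"g2"}) == set()

    def test_rule_or_requires_all(self):
        rules = {"R1": "g1 or g2"}
        assert map_gene_to_reaction_essentiality(rules, {"g1"}) == set()
        assert map_gene_to_reaction_essentiality(rules, {"g1", "g2"}) == {"R1"}

    def test_rule_and_requires_any(self):
        rules = {"R1": "g1 and g2"}
        assert map_gene_to_reaction_essentiality(rules, {"g1"}) == {"R1"}
        assert map_gene_to_reaction_essentiality(rules, set()) == set()

    def test_nested_expression(self):
        rules = {"R1": "(g1 and g2) or g3"}
        # OR: both disjuncts must be essential; (g1 and g2) essential iff
        # g1 or g2 essential
        assert map_gene_to_reaction_essentiality(rules, {"g1", "g3"}) == {"R1"}
        assert map_gene_to_reaction_essentiality(rules, {"g3"}) == set()
        assert map_gene_to_reaction_essentiality(rules, {"g1"}) == set()

    def test_empty_rule_never_essential(self):
        assert map_gene_to_reaction_essentiality({"R1": ""}, {"g1"}) == set()

    def test_unparseable_rule_names_reaction(self):
        with pytest.raises(ValueError, match="R9"):
            map_gene_to_reaction_essentiality({"R9": "g1 or (g2"}, {"g1"})

    def test_toy_model_rules(self, toy_model):
        rules = {r.id: r.gene_reaction_rule for r in toy_model.reactions}
        essential = map_gene_to_reaction_essentiality(rules, {"gta1", "g2a"})
        assert "T_a" in essential  # AND rule: one essential conjunct suffices
        assert "V2a" in essential
        assert "T_o" not in essential  # OR rule: needs both


class TestResosPredictor:
    def test_agrees_with_fba_on_strict_infeasibility(self, toy_model, baseline_resos):
        # the sole biomass feeder: deleted model has biomass identically 0,
        # both predictors must call it essential
        _, result = baseline_resos
        fba_scan = essentiality_scan(toy_model, candidates=["V1", "T_n"])
        resos_scan = essentiality_scan(
            toy_model,
            KnockoutConfig(predictor="resos", resos_params=result.params, seed=5),
            candidates=["V1", "T_n"],
        )
        for rid in ("V1", "T_n"):
            assert fba_scan[rid] == "essential"
            assert resos_scan[rid] == "essential"


class TestKnockoutConfig:
    def test_viability_fraction_validated(self):
        with pytest.raises(ValueError):
            KnockoutConfig(viability_fraction=0.0)
        with pytest.raises(ValueError):
            KnockoutConfig(viability_fraction=1.0)

    def test_unknown_predictor(self):
        with pytest.raises(ValueError):
            KnockoutConfig(predictor="magic")
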