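import math

import numpy as np
import pytest
from scipy import stats

from cgemkit.extraction import ExtractionResult
from cgemkit.flux_core import FluxState
from cgemkit.model_io import MetabolicModel, Reaction
from cgemkit.pattern_metrics import bland_altman, disagreement_matrix, jaccard_subsystem


def two_subsystem_model():
    reactions = [
        Reaction(rid, 0, 10, {}, subsystem="s1") for rid in ["a", "b", "c", "d"]
    ] + [Reaction("x", 0, 10, {}, subsystem="s2")]
    return MetabolicModel("m2", [], reactions)


def result(model, kept, sample_id="s"):
    return ExtractionResult(
        sample_id=sample_id,
        algorithm="gimme",
        kept_reactions=frozenset(kept),
        context_model=model.submodel(kept),
        parent_model_id=model.model_id,
        parent_genes=frozenset(),
    )


def state(values, model_id="m"):
    reactions = tuple(values)
    return FluxState(
        model_id=model_id,
        reactions=reactions,
        flux=np.array([values[r] for r in reactions], dtype=float),
        objective_value=0.0,
        objective_reaction=None,
    )


class TestJaccard:
    def test_identical_kept_sets_score_one(self):
        model = two_subsystem_model()
        a = result(model, ["a", "b", "x"], "s_a")
        rep = jaccard_subsystem(a, result(model, ["a", "b", "x"], "s_b"), model)
        assert rep.mean_index == pytest.approx(1.0)
        assert all(v == 1.0 for v in rep.per_subsystem.values())

    def test_disjoint_kept_sets_score_zero(self):
        model = two_subsystem_model()
        rep = jaccard_subsystem(
            result(model, ["a", "x"], "s_a"), result(model, ["b"], "s_b"), model
        )
        assert rep.mean_index == pytest.approx(0.0)

    def test_hand_computed_two_subsystem_fixture(self):
        # s1: {a,b,c} vs {b,c,d} -> 2/4 = 0.5 ; s2: {x} vs {x} -> 1 ; mean 0.75
        model = two_subsystem_model()
        rep = jaccard_subsystem(
            result(model, ["a", "b", "c", "x"], "s_a"),
            result(model, ["b", "c", "d", "x"], "s_b"),
            model,
        )
        assert rep.per_subsystem == pytest.approx({"s1": 0.5, "s2": 1.0})
        assert rep.mean_index == pytest.approx(0.75)

    def test_symmetry_identity_and_range_on_random_sets(self):
        model = two_subsystem_model()
        rng = np.random.default_rng(0)
        ids = model.reaction_ids
        for _ in range(50):
            ka = [r for r in ids if rng.random() > 0.4]
            kb = [r for r in ids if rng.random() > 0.4]
            ab = jaccard_subsystem(result(model, ka, "a"),
                                   result(model, kb, "b"), model)
            ba = jaccard_subsystem(result(model, kb, "b"),
                                   result(model, ka, "a"), model)
            if not math.isnan(ab.mean_index):
                assert ab.mean_index == pytest.approx(ba.mean_index)
                assert 0.0 <= ab.mean_index <= 1.0
            aa = jaccard_subsystem(result(model, ka, "a"),
                                   result(model, ka, "a"), model)
            if ka:
                assert aa.mean_index == pytest.approx(1.0)

    def test_mismatched_parent_models_rejected(self):
        model = two_subsystem_model()
        other = MetabolicModel("other", [], [Reaction("a", 0, 1, {})])
        a = result(model, ["a"])
        b = ExtractionResult("s", "gimme", frozenset(["a"]),
                             other.submodel(["a"]), "other", frozenset())
        with pytest.raises(ValueError, match="parent"):
            jaccard_subsystem(a, b, model)


class TestBlandAltman:
    def test_identical_states_agree_perfectly(self):
        a = state({"r1": 1.0, "r2": 2.0, "r3": 3.0}, "a")
        res = bland_altman(a, state({"r1": 1.0, "r2": 2.0, "r3": 3.0}, "b"))
        assert res.mean_difference == 0.0
        assert res.sd_difference == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.p_value == 1.0

    def test_constant_shift(self):
        values_a = {f"r{i}": float(i) for i in range(100)}
        values_b = {f"r{i}": float(i) - 1.0 for i in range(100)}
        res = bland_altman(state(values_a, "a"), state(values_b, "b"))
        assert res.mean_difference == pytest.approx(1.0)
        assert res.sd_difference == pytest.approx(0.0)
        assert res.p_value == 0.0

    def test_gaussian_differences_match_textbook_formulas(self):
        rng = np.random.default_rng(123)
        base = rng.normal(0, 5, size=1000)
        d = rng.normal(0.5, 1.0, size=1000)
        a = {f"r{i}": float(base[i] + d[i]) for i in range(1000)}
        b = {f"r{i}": float(base[i]) for i in range(1000)}
        res = bland_altman(state(a, "a"), state(b, "b"))
        assert res.mean_difference == pytest.approx(np.mean(d))
        assert res.sd_difference == pytest.approx(np.std(d, ddof=1))
        assert res.loa_low == pytest.approx(np.mean(d) - 1.96 * np.std(d, ddof=1))
        assert res.loa_high == pytest.approx(np.mean(d) + 1.96 * np.std(d, ddof=1))
        t = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(1000))
        want_p = 2 * stats.t.sf(abs(t), df=999)
        assert res.p_value == pytest.approx(want_p, rel=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = {f"r{i}": float(v) for i, v in enumerate(rng.normal(0, 2, 50))}
        b = {f"r{i}": float(v) for i, v in enumerate(rng.normal(1, 2, 50))}
        ab = bland_altman(state(a, "a"), state(b, "b"))
        ba = bland_altman(state(b, "b"), state(a, "a"))
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)
        assert ab.sd_difference == pytest.approx(ba.sd_difference)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_union_alignment_imputes_zero_for_absent_reactions(self):
        a = state({"r1": 1.0, "r2": 2.0, "r3": 1.0}, "a")
        b = state({"r1": 1.0, "r4": 4.0, "r5": 1.0}, "b")
        res = bland_altman(a, b)
        assert res.n_pairs == 5  # union of reactions, absent ones at zero flux

    def test_intersection_with_too_few_pairs_errors(self):
        a = state({"r1": 1.0, "r2": 2.0, "r3": 1.0}, "a")
        b = state({"r1": 1.0, "r4": 4.0, "r5": 1.0}, "b")
        with pytest.raises(ValueError, match="at least 3"):
            bland_altman(a, b, alignment="intersection")

    def test_percent_mode_drops_zero_mean_pairs(self):
        a = state({"r1": 1.0, "r2": -2.0, "r3": 3.0, "r4": 4.0}, "a")
        b = state({"r1": 3.0, "r2": 2.0, "r3": 1.0, "r4": 2.0}, "b")
        res = bland_altman(a, b, mode="percent")
        assert res.n_dropped == 1  # r2 has mean 0
        assert res.n_pairs == 3


class TestDisagreementMatrix:
    def test_identical_states_never_disagree(self):
        values = {f"r{i}": float(i) for i in range(10)}
        pct, table = disagreement_matrix(
            [state(values, f"s{k}") for k in range(4)]
        )
        assert pct == 0.0
        assert len(table) == 6

    def test_two_states_give_all_or_nothing(self):
        a = state({f"r{i}": float(i) for i in range(10)}, "a")
        b = state({f"r{i}": float(i) + 0.5 for i in range(10)}, "b")
        pct, _ = disagreement_matrix([a, b])
        assert pct in (0.0, 100.0)

    def test_planted_shift_detected_in_most_pairs(self):
        rng = np.random.default_rng(11)
        states = []
        for g, shift in enumerate([0.0, 2.0]):
            for k in range(4):
                values = {
                    f"r{i}": float(rng.normal(shift if i < 50 else 0.0, 0.05))
                    for i in range(100)
                }
                states.append(state(values, f"g{g}_s{k}"))
        pct, table = disagreement_matrix(states)
        cross = table[
            table.a.str.split("_").str[0] != table.b.str.split("_").str[0]
        ]
        assert (cross.p_value < 0.05).mean() == 1.0
        assert pct >= 50.0

    def test_needs_at_least_two_states(self):
        with pytest.raises(ValueError):
            disagreement_matrix([state({"r1": 1.0}, "a")])
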