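import numpy as np
import pytest

from cgemkit.extraction import (
    CoreInconsistentError,
    ExtractionConfig,
    core_from_activity,
    extract,
    fastcore,
    gimme,
    imat,
    init_extract,
)
from cgemkit.flux_core import fastcc, fba
from cgemkit.model_io import MetabolicModel, Reaction
from cgemkit.omics_mapping import ReactionActivity, map_expression, preprocess
from cgemkit.synthetic_data import SimulationDesign, random_network, simulate_expression

from _oracles import (
    oracle_gimme_inconsistency,
    oracle_imat_agreement,
    oracle_init_best_weight,
)
from conftest import activity, uniform_activity

EPS = 1e-4


def parallel_routes():
    """Two alternative routes a -> b feeding one objective exchange."""
    return MetabolicModel(
        "parallel", ["a", "b"],
        [
            Reaction("EX_a", -10, 0, {"a": -1.0}),
            Reaction("r_hi", 0, 10, {"a": -1.0, "b": 1.0}),
            Reaction("r_lo", 0, 10, {"a": -1.0, "b": 1.0}),
            Reaction("EX_b", 0, 10, {"b": -1.0}),
        ],
        objective_reaction="EX_b",
    )


class TestGimme:
    def test_all_expressed_keeps_everything(self, chain_model):
        res = gimme(chain_model, uniform_activity(chain_model),
                    ExtractionConfig(algorithm="gimme"))
        assert res.kept_reactions == frozenset(chain_model.reaction_ids)

    def test_penalized_parallel_route_excluded(self):
        model = parallel_routes()
        act = activity({"r_hi": 0.9, "r_lo": 0.0, "EX_a": None, "EX_b": None})
        cfg = ExtractionConfig(algorithm="gimme", biomass_fraction=0.9)
        res = gimme(model, act, cfg)
        assert "r_lo" not in res.kept_reactions
        assert "r_hi" in res.kept_reactions
        state = fba(res.context_model)
        assert state.objective_value >= 0.9 * res.diagnostics["z_star"] - 1e-6

    def test_stage2_objective_matches_independent_lp(self):
        for seed in range(4):
            rng = np.random.default_rng(500 + seed)
            net = random_network(rng, n_reactions=10)
            cons = fastcc(net, epsilon=EPS).consistent_reactions
            sub = net.submodel(cons, model_id="net")
            obj = next(
                (r.reaction_id for r in sub.reactions
                 if r.reaction_id.startswith("EX_")
                 and fba(sub, objective=r.reaction_id,
                         parsimonious=False).objective_value > 0.5),
                None,
            )
            if obj is None:
                continue
            sub.objective_reaction = obj
            a = {rid: float(rng.random()) for rid in sub.reaction_ids}
            cfg = ExtractionConfig(algorithm="gimme", epsilon_active=EPS,
                                   biomass_fraction=0.8)
            res = gimme(sub, activity(a), cfg)
            t = res.diagnostics["threshold"]
            weights = {r: t - v for r, v in a.items() if v < t}
            want = oracle_gimme_inconsistency(sub, weights, obj, 0.8)
            assert res.diagnostics["inconsistency"] == pytest.approx(want, abs=1e-6)


class TestIMAT:
    def test_conflict_free_high_pathway_fully_satisfied(self, chain_model):
        # every reaction equally expressed: high set = whole chain, low empty
        act = activity({"r1": 1.0, "r2": 1.0, "EX_a": 1.0, "EX_b": 1.0})
        res = imat(chain_model, act, ExtractionConfig(algorithm="imat"))
        assert res.diagnostics["agreement"] == (
            res.diagnostics["n_high"] + res.diagnostics["n_low"]
        )
        assert {"r1", "r2"} <= res.kept_reactions

    def test_coupled_high_low_pair_sacrifices_one(self, chain_model):
        # r1 high but stoichiometrically coupled 1:1 to low r2
        act = activity({"r1": 1.0, "r2": 0.0, "EX_a": 0.5, "EX_b": 0.5})
        res = imat(chain_model, act, ExtractionConfig(algorithm="imat"))
        total = res.diagnostics["n_high"] + res.diagnostics["n_low"]
        assert total == 2
        assert res.diagnostics["agreement"] == total - 1

    def test_no_classified_reactions_keeps_model_unchanged(self, chain_model):
        res = imat(chain_model, activity({r: None for r in chain_model.reaction_ids}),
                   ExtractionConfig(algorithm="imat"))
        assert res.diagnostics["agreement"] == 0
        assert res.kept_reactions == frozenset(chain_model.reaction_ids)

    def test_agreement_matches_exhaustive_enumeration(self):
        for seed in range(4):
            rng = np.random.default_rng(600 + seed)
            net = random_network(rng, n_reactions=10)
            cons = fastcc(net, epsilon=EPS).consistent_reactions
            if len(cons) < 5:
                continue
            sub = net.submodel(cons, model_id="net")
            a = {rid: float(rng.random()) for rid in sub.reaction_ids}
            res = imat(sub, activity(a), ExtractionConfig(algorithm="imat",
                                                          epsilon_active=EPS))
            qh = res.diagnostics["threshold_high"]
            ql = res.diagnostics["threshold_low"]
            high = {r for r, v in a.items() if v >= qh}
            low = {r for r, v in a.items() if v <= ql} - high
            assert res.diagnostics["agreement"] == oracle_imat_agreement(
                sub, high, low, EPS
            )


class TestINIT:
    def test_all_positive_weights_keep_all(self, chain_model):
        res = init_extract(chain_model,
                           activity({"r1": 0.9, "r2": 0.8, "EX_a": 0.7, "EX_b": 1.0}),
                           ExtractionConfig(algorithm="init",
                                            expression_threshold=0.0))
        assert res.kept_reactions == frozenset(chain_model.reaction_ids)

    def test_negative_weight_bypass_excluded(self):
        model = parallel_routes()
        act = activity({"r_hi": 0.9, "r_lo": 0.0, "EX_a": None, "EX_b": None})
        res = init_extract(model, act, ExtractionConfig(algorithm="init"))
        assert "r_lo" not in res.kept_reactions
        assert "r_hi" in res.kept_reactions

    def test_all_missing_degenerates_to_protected_closure(self, chain_model):
        act = activity({r: None for r in chain_model.reaction_ids})
        res = init_extract(chain_model, act, ExtractionConfig(algorithm="init"))
        assert res.kept_reactions == frozenset()

    def test_total_weight_matches_exhaustive_enumeration(self):
        for seed in range(3):
            rng = np.random.default_rng(700 + seed)
            net = random_network(rng, n_reactions=10)
            cons = fastcc(net, epsilon=EPS).consistent_reactions
            if len(cons) < 5:
                continue
            sub = net.submodel(cons, model_id="net")
            a = {rid: float(rng.random()) for rid in sub.reaction_ids}
            res = init_extract(sub, activity(a),
                               ExtractionConfig(algorithm="init",
                                                epsilon_active=EPS))
            t = res.diagnostics["threshold"]
            weights = {r: v - t for r, v in a.items() if v != t}
            want = oracle_init_best_weight(sub, weights, EPS)
            assert res.diagnostics["total_weight"] == pytest.approx(want, abs=1e-6)


class TestFastcore:
    def test_core_everything_keeps_everything(self, chain_model):
        res = fastcore(chain_model, set(chain_model.reaction_ids),
                       ExtractionConfig(algorithm="fastcore"))
        assert res.kept_reactions == frozenset(chain_model.reaction_ids)

    def test_chain_middle_forces_whole_chain(self, chain_model):
        res = fastcore(chain_model, {"r1"},
                       ExtractionConfig(algorithm="fastcore"))
        assert res.kept_reactions == frozenset(chain_model.reaction_ids)

    def test_output_contains_core_and_is_consistent(self):
        for seed in range(6):
            rng = np.random.default_rng(800 + seed)
            net = random_network(rng, n_reactions=12)
            cons = fastcc(net, epsilon=EPS).consistent_reactions
            if len(cons) < 3:
                continue
            sub = net.submodel(cons, model_id="net")
            core = set(sorted(cons)[:3])
            res = fastcore(sub, core,
                           ExtractionConfig(algorithm="fastcore",
                                            epsilon_active=EPS))
            assert core <= res.kept_reactions
            again = fastcc(res.context_model, epsilon=EPS)
            assert not again.removed_reactions

    def test_enlarging_core_never_shrinks_output(self, toy_model):
        cfg = ExtractionConfig(algorithm="fastcore")
        small = fastcore(toy_model, {"GAPD"}, cfg)
        large = fastcore(toy_model, {"GAPD", "PDHm", "G6PDH2r"}, cfg)
        assert len(large.kept_reactions) >= len(small.kept_reactions)

    def test_inconsistent_core_reaction_named_in_error(self):
        model = MetabolicModel(
            "deadend", ["a", "b"],
            [
                Reaction("EX_a", -10, 10, {"a": -1.0}),
                Reaction("r_dead", 0, 10, {"a": -1.0, "b": 1.0}),
            ],
        )
        with pytest.raises(CoreInconsistentError, match="r_dead"):
            fastcore(model, {"r_dead"}, ExtractionConfig(algorithm="fastcore"))

    def test_unknown_core_reaction_rejected(self, chain_model):
        with pytest.raises(KeyError, match="nope"):
            fastcore(chain_model, {"nope"}, ExtractionConfig(algorithm="fastcore"))


class TestCrossAlgorithmInvariants:
    @pytest.fixture()
    def toy_profiles(self, toy_model):
        matrix, meta, _ = simulate_expression(
            toy_model, SimulationDesign(seed=9, n_groups=2, n_samples_per_group=2)
        )
        return preprocess(matrix, dict(zip(meta["column"], meta["sample"])))

    @pytest.mark.parametrize("algorithm", ["gimme", "imat", "init", "fastcore"])
    def test_protected_kept_consistent_and_viable(
        self, toy_model, protected, toy_profiles, algorithm
    ):
        cfg = ExtractionConfig(algorithm=algorithm, protected=protected)
        for profile in toy_profiles[:2]:
            res = extract(toy_model, map_expression(toy_model, profile), cfg)
            assert protected <= res.kept_reactions
            assert not fastcc(res.context_model,
                              epsilon=cfg.epsilon_active).removed_reactions
            assert fba(res.context_model).objective_value > 0

    def test_gimme_init_larger_than_imat_fastcore_on_average(
        self, toy_model, protected
    ):
        matrix, meta, _ = simulate_expression(
            toy_model, SimulationDesign(seed=21, n_groups=4, n_samples_per_group=3)
        )
        profiles = preprocess(matrix, dict(zip(meta["column"], meta["sample"])))
        sizes = {}
        for algorithm in ["gimme", "imat", "init", "fastcore"]:
            cfg = ExtractionConfig(algorithm=algorithm, protected=protected)
            sizes[algorithm] = np.mean([
                len(extract(toy_model, map_expression(toy_model, p), cfg).kept_reactions)
                for p in profiles
            ])
        assert (sizes["gimme"] + sizes["init"]) / 2 >= (
            sizes["imat"] + sizes["fastcore"]
        ) / 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExtractionConfig(algorithm="unknown")
        with pytest.raises(ValueError):
            ExtractionConfig(low_quantile=0.8, high_quantile=0.2)
        with pytest.raises(ValueError):
            ExtractionConfig(biomass_fraction=0.0)

    def test_core_from_activity_uses_core_quantile(self, toy_model):
        a = {rid: i / 39 for i, rid in enumerate(toy_model.reaction_ids)}
        cfg = ExtractionConfig(algorithm="fastcore", core_quantile=0.75)
        core = core_from_activity(toy_model, activity(a), cfg)
        assert 0 < len(core) <= len(a)
        assert len(core) == pytest.approx(0.25 * len(a), abs=2)
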