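import numpy as np
import pytest
from scipy import stats as sstats

from earmotion.nas import (
    BoolDim,
    ChoiceDim,
    IntDim,
    LambdaDomain,
    NasResult,
    ObjectiveVector,
    SearchSpace,
    Surrogate,
    batch_suggest,
    config_key,
    decode_vector,
    dominates,
    encode_config,
    nas_search,
    sample_candidates,
    tcn_search_space,
    ucb_select,
)


@pytest.fixture()
def toy_space():
    return SearchSpace(dims=[IntDim("a", 0, 3), IntDim("b", 0, 3), BoolDim("c")])


def toy_evaluator(cfg, seed):
    v = (cfg["a"] - 2) ** 2 + (cfg["b"] - 1) ** 2 + (0.5 if cfg["c"] else 0.0)
    return ObjectiveVector(v, -0.1, -0.1, 0.2)


class TestEncoding:
    def test_round_trip_identity(self, toy_space):
        for cfg in toy_space.enumerate():
            assert decode_vector(encode_config(cfg, toy_space), toy_space) == cfg

    def test_distinct_configs_distinct_vectors(self, toy_space):
        vecs = {tuple(encode_config(c, toy_space)) for c in toy_space.enumerate()}
        assert len(vecs) == len(toy_space.enumerate())

    def test_tcn_bounds_map_to_unit_interval(self):
        space = tcn_search_space()
        lo = space.canonicalize(
            {"n_filters": 2, "kernel": 2, "n_layers": 3, "use_residual": False,
             **{f"dilation_{i}": 1 for i in range(8)}}
        )
        hi = dict(lo, n_filters=64)
        assert encode_config(lo, space)[0] == 0.0
        assert encode_config(hi, space)[0] == 1.0

    def test_out_of_space_config_rejected(self, toy_space):
        with pytest.raises(ValueError):
            encode_config({"a": 9, "b": 0, "c": False}, toy_space)


class TestSampling:
    def test_seed_reproducible(self, toy_space):
        assert sample_candidates(toy_space, 5, seed=3) == sample_candidates(toy_space, 5, seed=3)

    def test_all_samples_valid(self):
        space = tcn_search_space()
        for cfg in sample_candidates(space, 1000, seed=1):
            assert space.is_valid(cfg)

    def test_choice_marginal_uniform(self):
        space = SearchSpace(dims=[ChoiceDim("x", ("p", "q", "r"))])
        draws = [c["x"] for c in sample_candidates(space, 3000, seed=2)]
        counts = [draws.count(v) for v in ("p", "q", "r")]
        _, p = sstats.chisquare(counts)
        assert p > 0.01


class TestUcb:
    def _fit(self, toy_space, n=5):
        sur = Surrogate(toy_space, seed=0)
        lam = LambdaDomain().reference()
        for cfg in toy_space.enumerate()[:n]:
            sur.add(cfg, toy_evaluator(cfg, 0).composite(lam))
        sur.fit()
        return sur

    def test_beta_zero_is_posterior_mean_argmax(self, toy_space):
        sur = self._fit(toy_space)
        cands = toy_space.enumerate()
        pick = ucb_select(sur, cands, beta_ucb=0.0)
        mu, _ = sur.predict(cands)
        assert config_key(pick) == config_key(cands[int(np.argmax(mu))])

    def test_matches_brute_force_acquisition(self, toy_space):
        sur = self._fit(toy_space)
        cands = toy_space.enumerate()
        beta = 4.0
        mu, sigma = sur.predict(cands)
        expected = cands[int(np.argmax(mu + np.sqrt(beta) * sigma))]
        assert config_key(ucb_select(sur, cands, beta)) == config_key(expected)

    def test_huge_sigma_point_wins_under_large_beta(self, toy_space):
        sur = self._fit(toy_space, n=3)
        cands = toy_space.enumerate()
        mu, sigma = sur.predict(cands)
        far = cands[int(np.argmax(sigma))]
        pick = ucb_select(sur, cands, beta_ucb=1e6)
        _, s_pick = sur.predict([pick])
        assert s_pick[0] == pytest.approx(sigma.max(), rel=1e-9)


class TestBatch:
    def test_batch_size_one_equals_ucb_select(self, toy_space):
        sur = TestUcb()._fit(toy_space)
        cands = toy_space.enumerate()
        assert config_key(batch_suggest(sur, cands, 1)[0]) == config_key(ucb_select(sur, cands))

    def test_hallucination_matches_manual_constant_liar(self, toy_space):
        sur = TestUcb()._fit(toy_space)
        cands = toy_space.enumerate()
        picks = batch_suggest(sur, cands, 3, "hallucination")
        # manual trace of the constant-liar loop
        lier = Surrogate(toy_space, seed=sur.seed)
        lier.set_observations([decode_vector(x, toy_space) for x in sur.X], sur.y)
        remaining = list(cands)
        for expected in picks:
            choice = ucb_select(lier, remaining)
            assert config_key(choice) == config_key(expected)
            remaining = [c for c in remaining if config_key(c) != config_key(choice)]
            mu, _ = lier.predict([choice])
            lier.add(choice, -float(mu[0]))

    def test_members_distinct_both_strategies(self, toy_space):
        sur = TestUcb()._fit(toy_space)
        cands = toy_space.enumerate()
        for strategy in ("hallucination", "kmeans"):
            picks = batch_suggest(sur, cands, 4, strategy)
            assert len({config_key(p) for p in picks}) == 4

    def test_oversized_batch_rejected(self, toy_space):
        sur = TestUcb()._fit(toy_space)
        with pytest.raises(ValueError):
            batch_suggest(sur, toy_space.enumerate()[:3], 5)


class TestSearch:
    def test_exhaustive_budget_matches_brute_force(self, toy_space):
        res = nas_search(toy_space, toy_evaluator, iterations=32, seed=3, n_candidates=64)
        lam = LambdaDomain().reference()
        brute = min(toy_evaluator(c, 0).composite(lam) for c in toy_space.enumerate())
        assert res.incumbent_objectives.composite(lam) == pytest.approx(brute)
        assert len(res.trace) == 32  # dedup exhausted the space exactly

    def test_incumbent_monotone_and_feasible(self, toy_space):
        res = nas_search(toy_space, toy_evaluator, iterations=20, seed=5, n_candidates=64)
        lam = LambdaDomain().reference()
        best = np.inf
        path = []
        for rec in res.trace:
            o = ObjectiveVector(*rec["objectives"])
            if o.feasible:
                best = min(best, o.composite(lam))
            path.append(best)
        assert all(a >= b for a, b in zip(path, path[1:]))
        assert res.incumbent_objectives.feasible

    def test_pareto_set_is_non_dominated(self, toy_space):
        def multi_eval(cfg, seed):
            return ObjectiveVector(
                (cfg["a"] - 2) ** 2, -cfg["b"] / 3.0, -0.1, 0.1 * cfg["a"]
            )

        res = nas_search(toy_space, multi_eval, iterations=32, seed=1, n_candidates=64)
        for _, o in res.pareto_set:
            assert not any(dominates(o2, o) for _, o2 in res.pareto_set if o2 is not o)

    def test_infeasible_space_reports_no_feasible_model(self, toy_space):
        def always_over_budget(cfg, seed):
            return ObjectiveVector(0.1, np.inf, -0.1, 0.5)

        res = nas_search(toy_space, always_over_budget, iterations=10, seed=0, n_candidates=32)
        assert not res.feasible_found
        assert res.incumbent is None

    def test_tightening_budget_never_improves_best_error(self, toy_space):
        # accuracy improves with b, but SRAM usage grows with b too; a tighter
        # budget can only exclude accurate configs, never add new ones
        def eval_with_budget(budget):
            def ev(cfg, seed):
                sram = 0.2 + 0.1 * cfg["b"]
                f_sram = -sram / budget if sram <= budget else np.inf
                return ObjectiveVector(1.0 / (1 + cfg["b"]), -0.1, f_sram, 0.2)

            return ev

        loose = nas_search(toy_space, eval_with_budget(1.0), iterations=32, seed=2, n_candidates=64)
        tight = nas_search(toy_space, eval_with_budget(0.45), iterations=32, seed=2, n_candidates=64)
        best_err = lambda res: min(o.f_error for _, o in res.pareto_set)
        assert best_err(tight) >= best_err(loose)
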