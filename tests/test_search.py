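import math

import numpy as np
import pytest

from scanbma import (
    ModelScorer,
    PriorEdgeMatrix,
    RegressionData,
    ScanOptions,
    build_lagged_design,
    fit_target,
    guelzim_prior,
    model_weights,
    prescreen,
    refine_inclusion,
    scan,
)
from scanbma.bma_core import g_prior_two_log_odds, inclusion_probabilities, r_squared
from scanbma.search import BMAResult
from scanbma.simulate import SimulationConfig, gold_standard_from_network, simulate_dataset
from scanbma.transform import transform_pipeline

from .conftest import make_regression
from .oracles import enumerate_window


def flat_prior(data, target="T", p0=0.5):
    return PriorEdgeMatrix(data.candidate_ids, [target], np.full((data.p, 1), p0))


class TestScanOptions:
    def test_validation(self):
        with pytest.raises(ValueError, match="occam_c"):
            ScanOptions(occam_c=1.0)
        with pytest.raises(ValueError, match="nvar"):
            ScanOptions(nvar=0)
        with pytest.raises(ValueError, match="g must"):
            ScanOptions(g=-3.0)
        with pytest.raises(ValueError, match="backend"):
            ScanOptions(score="aic")

    def test_window_width_is_two_log_c(self):
        assert ScanOptions(occam_c=100.0).window_width == pytest.approx(2 * math.log(100))


class TestPrescreen:
    def test_nvar_all_keeps_everything(self, rng):
        data = make_regression(rng, 20, 6)
        priors = flat_prior(data)
        kept = prescreen(data, priors, "T", "all", g=20.0)
        assert sorted(kept) == sorted(data.candidate_ids)

    def test_dominant_candidate_ranks_first(self, rng):
        data = make_regression(rng, 25, 5)
        data = RegressionData(
            data.X[:, 3] + 1e-3 * rng.standard_normal(25), data.X, data.candidate_ids
        )
        kept = prescreen(data, flat_prior(data), "T", 2, g=25.0)
        assert kept[0] == data.candidate_ids[3]

    def test_matches_single_model_scoring_oracle(self, rng):
        data = make_regression(rng, 30, 30, signal_cols=(2, 11, 25), coef=0.8)
        pi = rng.uniform(0.05, 0.95, size=(30, 1))
        priors = PriorEdgeMatrix(data.candidate_ids, ["T"], pi)
        kept = prescreen(data, priors, "T", 10, g=30.0)
        # oracle: score every single-predictor model directly
        scores = []
        for h, gene in enumerate(data.candidate_ids):
            plo = 2.0 * math.log(pi[h, 0] / (1 - pi[h, 0]))
            s = g_prior_two_log_odds(r_squared(data, (h,)), 1, data.n, 30.0, plo)
            scores.append((-s, -pi[h, 0], gene))
        expected = [g for *_, g in sorted(scores)[:10]]
        assert kept == expected

    def test_prior_breaks_ties(self, rng):
        # two identical columns: identical R^2, the higher prior wins
        x = rng.standard_normal(20)
        data = RegressionData(rng.standard_normal(20), np.stack([x, x], axis=1), ["a", "b"])
        priors = PriorEdgeMatrix(["a", "b"], ["T"], np.array([[0.2], [0.6]]))
        assert prescreen(data, priors, "T", 1, g=10.0) == ["b"]


class TestScan:
    def test_single_strong_predictor_drops_null(self, rng):
        x = rng.standard_normal((40, 1))
        data = RegressionData(x[:, 0] + 0.05 * rng.standard_normal(40), x, ["a"])
        scorer = ModelScorer(data)
        window = scan(scorer, g=40.0, opts=ScanOptions(occam_c=100.0))
        assert [m.key for m in window] == [(0,)]

    def test_tight_window_keeps_only_the_best(self, rng):
        data = make_regression(rng, 30, 4, signal_cols=(0,), coef=2.0, noise=0.3)
        scorer = ModelScorer(data)
        window = scan(scorer, g=30.0, opts=ScanOptions(occam_c=1.0 + 1e-9))
        assert len(window) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        data = make_regression(rng, 30, 10, signal_cols=(0, 4), coef=0.7)
        scorer = ModelScorer(data, rng.normal(0, 1, size=10))
        opts = ScanOptions(occam_c=100.0)
        found = {m.key for m in scan(scorer, 30.0, opts)}
        expected = enumerate_window(ModelScorer(data, scorer.prior_log_odds), 30.0, 100.0)
        assert found == expected

    def test_window_guarantee(self, rng):
        data = make_regression(rng, 25, 8, signal_cols=(1, 5))
        scorer = ModelScorer(data)
        opts = ScanOptions(occam_c=20.0)
        window = scan(scorer, 25.0, opts)
        best = max(m.two_log_odds for m in window)
        assert all(m.two_log_odds >= best - opts.window_width for m in window)
        # the best returned model is the global best over everything evaluated
        evaluated_best = max(scorer.score(k, 25.0).two_log_odds for k in scorer._r2)
        assert best == pytest.approx(evaluated_best, abs=0)

    def test_growing_c_never_shrinks_the_window(self, rng):
        data = make_regression(rng, 25, 7, signal_cols=(0,))
        sets = []
        for c in (5.0, 50.0, 500.0):
            scorer = ModelScorer(data)
            sets.append({m.key for m in scan(scorer, 25.0, ScanOptions(occam_c=c))})
        assert sets[0] <= sets[1] <= sets[2]

    def test_deterministic(self, rng):
        data = make_regression(rng, 20, 6, signal_cols=(2,))
        runs = [scan(ModelScorer(data), 20.0, ScanOptions()) for _ in range(2)]
        assert [m.key for m in runs[0]] == [m.key for m in runs[1]]
        assert [m.two_log_odds for m in runs[0]] == [m.two_log_odds for m in runs[1]]


class TestRefinement:
    @staticmethod
    def result_for(data, g, opts=None):
        opts = opts or ScanOptions()
        scorer = ModelScorer(data)
        models = scan(scorer, g, opts)
        weights = model_weights(models)
        incl = inclusion_probabilities(models, weights, data.p)
        res = BMAResult(
            target="T", candidates=data.candidate_ids, window_models=models,
            weights=weights, g=g, inclusion=incl, refined_inclusion=incl,
        )
        return res, scorer

    def test_equal_scores_give_half(self):
        # two identical columns -> dropping the included one from the best
        # model and swapping in its twin leaves the score unchanged
        x = np.array([0.3, -1.2, 0.8, 1.5, -0.7, 0.1, 2.0, -0.4, 0.9, -1.1])
        y = x + np.array([0.05, -0.02, 0.04, -0.03, 0.01, 0.02, -0.05, 0.03, -0.01, 0.04])
        data = RegressionData(y, np.stack([x, np.linspace(-1, 1, 10)], axis=1), ["a", "b"])
        scorer = ModelScorer(data)
        best = scorer.score((0,), 10.0)
        res = BMAResult(
            target="T", candidates=["a", "b"], window_models=[best],
            weights=np.array([1.0]), g=10.0, inclusion=np.array([1.0, 0.0]),
            refined_inclusion=np.array([1.0, 0.0]),
        )
        refined = refine_inclusion(res, scorer, 10.0)
        # candidate 'a': O = exp((s_best - s_without_a)/2)
        delta = best.two_log_odds - scorer.score((), 10.0).two_log_odds
        o = math.exp(delta / 2)
        assert refined[0] == pytest.approx(o / (1 + o))
        # candidate 'b': O = exp((s_best - s_with_b)/2), refined = 1/(1+O)
        delta_b = best.two_log_odds - scorer.score((0, 1), 10.0).two_log_odds
        assert refined[1] == pytest.approx(1.0 / (1.0 + math.exp(delta_b / 2)))

    def test_two_log_99_gap_gives_one_percent(self):
        # algebra of the printed formula: score gap 2*log(99) -> 1/(1+99)
        o = math.exp(2 * math.log(99) / 2)
        assert 1.0 / (1.0 + o) == pytest.approx(0.01)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        data = make_regression(rng, 30, 6, signal_cols=(0, 1), coef=2.0, noise=0.2)
        res, scorer = self.result_for(data, 30.0)
        refined = refine_inclusion(res, scorer)
        assert np.all(refined > 0.0) and np.all(refined < 1.0)

    def test_refinement_orders_saturated_groups(self, rng):
        data = make_regression(rng, 40, 8, signal_cols=(0, 3), coef=1.5, noise=0.3)
        res, scorer = self.result_for(data, 40.0, ScanOptions(occam_c=2.0))
        refined = refine_inclusion(res, scorer)
        raw = res.inclusion
        high = [h for h in range(8) if raw[h] >= 1 - 1e-9]
        low = [h for h in range(8) if raw[h] <= 1e-9]
        for h in high:
            assert 0.5 <= refined[h] < 1.0
        for h in low:
            assert 0.0 < refined[h] <= 0.5
        # distinct refined values within a saturated group: a strict ordering
        assert len({round(float(refined[h]), 12) for h in low}) == len(low)


class TestFitTarget:
    @staticmethod
    def transformed_sim(seed=11, **kw):
        net, ts = simulate_dataset(SimulationConfig(seed=seed, **kw))
        return net, transform_pipeline(ts)

    def test_recovers_strong_parent(self):
        net, ts = self.transformed_sim(seed=11)
        priors = guelzim_prior(ts.gene_ids, ts.gene_ids)
        # pick a target with at least one true parent
        target = next(t for (r, t) in sorted(net.edges))
        parents = set(net.parents(target))
        res = fit_target(ts, target, priors, ScanOptions())
        probs = res.edge_probabilities()
        top = max(probs, key=probs.get)
        assert top in parents

    def test_zero_variance_target_yields_no_edges(self, rng):
        from scanbma import ExpressionTimeSeries

        values = rng.standard_normal((3, 5, 4))
        values[0] = 0.0
        ts = ExpressionTimeSeries(["a", "b", "c"], np.arange(5.0), list("wxyz"), values)
        priors = guelzim_prior(ts.gene_ids, ts.gene_ids)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = fit_target(ts, "a", priors, ScanOptions(g=10.0))
        assert [m.key for m in res.window_models] == [()]
        assert np.all(res.refined_inclusion < 0.5)

    def test_nvar_all_equals_nvar_p(self):
        net, ts = self.transformed_sim(seed=12)
        priors = guelzim_prior(ts.gene_ids, ts.gene_ids)
        a = fit_target(ts, ts.gene_ids[0], priors, ScanOptions(nvar="all"))
        b = fit_target(ts, ts.gene_ids[0], priors, ScanOptions(nvar=9))
        assert a.edge_probabilities() == b.edge_probabilities()
        assert a.g == b.g

    def test_window_models_respect_the_window(self):
        net, ts = self.transformed_sim(seed=13)
        priors = guelzim_prior(ts.gene_ids, ts.gene_ids)
        opts = ScanOptions()
        res = fit_target(ts, ts.gene_ids[2], priors, opts)
        best = max(m.two_log_odds for m in res.window_models)
        assert all(m.two_log_odds >= best - opts.window_width for m in res.window_models)

    def test_bit_identical_reruns(self):
        net, ts = self.transformed_sim(seed=14)
        priors = guelzim_prior(ts.gene_ids, ts.gene_ids)
        r1 = fit_target(ts, ts.gene_ids[1], priors, ScanOptions())
        r2 = fit_target(ts, ts.gene_ids[1], priors, ScanOptions())
        assert r1.g == r2.g
        np.testing.assert_array_equal(r1.refined_inclusion, r2.refined_inclusion)
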