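import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, norm

from nest import (
    GoldStandard,
    ValidationError,
    auto_negatives,
    degradation_experiment,
    inject_noise,
    logistic_confounder_test,
    rank_sum_z,
    roc_auc,
)
from conftest import random_instance


def pair_count_auc(scores, positives, negatives):
    """Brute-force oracle: fraction of (pos, neg) pairs won, ties 1/2."""
    wins = 0.0
    total = 0
    for p, n in itertools.product(positives, negatives):
        total += 1
        if scores[p] > scores[n]:
            wins += 1
        elif scores[p] == scores[n]:
            wins += 0.5
    return wins / total


def make_gold(scores, positives):
    genes = scores.index if isinstance(scores, pd.Series) else scores.keys()
    return GoldStandard.from_sets(positives, set(genes) - set(positives))


class TestGoldStandard:
    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            GoldStandard.from_sets({"a", "b"}, {"b", "c"})

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            GoldStandard.from_sets(set(), {"a"})

    def test_auto_negatives_are_bottom_ranked(self):
        scores = pd.Series({"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0})
        neg = auto_negatives(scores, positives={"a"})
        assert neg == {"e"}
        assert auto_negatives(scores, positives={"a"}, n=2) == {"e", "d"}


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.7, "n2": 0.1}
        gold = GoldStandard.from_sets({"p1", "p2"}, {"n1", "n2"})
        assert roc_auc(scores, gold).auc == 1.0

    def test_partial_overlap_matches_hand_count(self):
        scores = {"p1": 0.9, "p2": 0.4, "n1": 0.7, "n2": 0.1}
        gold = GoldStandard.from_sets({"p1", "p2"}, {"n1", "n2"})
        # oracle over all 4 pairs: p1>n1, p1>n2, p2<n1, p2>n2 -> 3/4
        assert roc_auc(scores, gold).auc == pytest.approx(3 / 4)

    def test_all_tied_gives_half(self):
        scores = {g: 1.0 for g in "abcd"}
        gold = GoldStandard.from_sets({"a", "b"}, {"c", "d"})
        assert roc_auc(scores, gold).auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for trial in range(30):
            n = int(rng.integers(6, 60))
            raw = rng.normal(size=n)
            if trial % 3 == 0:
                raw = np.round(raw)  # force ties
            genes = [f"g{i}" for i in range(n)]
            scores = dict(zip(genes, raw))
            n_pos = int(rng.integers(1, n))
            positives = set(rng.choice(genes, size=n_pos, replace=False))
            negatives = set(genes) - positives
            gold = GoldStandard.from_sets(positives, negatives)
            assert roc_auc(scores, gold).auc == pytest.approx(
                pair_count_auc(scores, positives, negatives)
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        gold = make_gold(scores, set(scores.index[:10]))
        a1 = roc_auc(scores, gold).auc
        a2 = roc_auc(np.tanh(scores) * 100 + 3, gold).auc
        assert a1 == pytest.approx(a2)

    def test_genes_without_scores_excluded(self):
        scores = pd.Series({"p": 1.0, "n": 0.0, "x": np.nan})
        gold = GoldStandard.from_sets({"p", "x"}, {"n"})
        res = roc_auc(scores, gold)
        assert res.n_positive == 1 and res.auc == 1.0

    def test_no_scored_positives_is_error(self):
        gold = GoldStandard.from_sets({"missing"}, {"n"})
        with pytest.raises(ValidationError):
            roc_auc({"n": 0.0, "other": 1.0}, gold)

    def test_curve_is_monotone_from_zero_to_one(self):
        rng = np.random.default_rng(10)
        scores = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        res = roc_auc(scores, make_gold(scores, set(scores.index[:20])))
        for seq in (res.fpr, res.tpr):
            assert seq[0] == 0.0 and seq[-1] == 1.0
            assert (np.diff(seq) >= 0).all()


class TestRankSumZ:
    def test_complete_separation_matches_exact_formula(self):
        # 20 positives all above 20 negatives: W = sum(21..40) = 610,
        # mean = 20*41/2 = 410, var = 20*20/12*41, continuity correction 0.5
        scores = {f"p{i}": 100 + i for i in range(20)}
        scores |= {f"n{i}": i for i in range(20)}
        gold = GoldStandard.from_sets({f"p{i}" for i in range(20)}, {f"n{i}" for i in range(20)})
        expected = (610 - 410 - 0.5) / np.sqrt(20 * 20 / 12 * 41)
        assert rank_sum_z(scores, gold) == pytest.approx(expected)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        pos = set(scores.index[:12])
        neg = set(scores.index[12:])
        z1 = rank_sum_z(scores, GoldStandard.from_sets(pos, neg))
        z2 = rank_sum_z(scores, GoldStandard.from_sets(neg, pos))
        assert z1 == pytest.approx(-z2)

    def test_null_behavior_is_modest(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(size=1000), index=[f"g{i}" for i in range(1000)])
        gold = make_gold(scores, set(scores.index[:500]))
        assert abs(rank_sum_z(scores, gold)) < 3

    def test_agrees_with_scipy_asymptotic_p(self):
        rng = np.random.default_rng(13)
        pos_vals = rng.normal(0.5, 1, 40)
        neg_vals = rng.normal(0.0, 1, 55)
        scores = {f"p{i}": v for i, v in enumerate(pos_vals)}
        scores |= {f"n{i}": v for i, v in enumerate(neg_vals)}
        gold = GoldStandard.from_sets(set(scores) - set(f"n{i}" for i in range(55)),
                                      {f"n{i}" for i in range(55)})
        z = rank_sum_z(scores, gold)
        p_ours = 2 * norm.sf(abs(z))
        p_scipy = mannwhitneyu(pos_vals, neg_vals, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p_ours == pytest.approx(p_scipy, rel=1e-9)

    def test_direction_agrees_with_auc(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            scores = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
            gold = make_gold(scores, set(scores.index[:15]))
            auc = roc_auc(scores, gold).auc
            z = rank_sum_z(scores, gold)
            if abs(auc - 0.5) > 0.02:  # away from the continuity-correction boundary
                assert (auc > 0.5) == (z > 0)


class TestLogisticConfounderTest:
    def test_recovers_generating_coefficient(self):
        rng = np.random.default_rng(15)
        n = 5000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-x))  # logit(p) = 1 * x
        y = (rng.random(n) < p).astype(int)
        genes = [f"g{i}" for i in range(n)]
        res = logistic_confounder_test(dict(zip(genes, y)), {"x": dict(zip(genes, x))})
        assert 0.8 <= res.table.loc["x", "coef"] <= 1.2
        assert res.table.loc["x", "z"] == pytest.approx(
            res.table.loc["x", "coef"] / res.table.loc["x", "stderr"]
        )

    def test_null_covariate_has_modest_z(self):
        rng = np.random.default_rng(16)
        n = 2000
        x = rng.normal(size=n)
        noise = rng.normal(size=n)  # independent of the outcome
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        genes = [f"g{i}" for i in range(n)]
        res = logistic_confounder_test(
            dict(zip(genes, y)),
            {"signal": dict(zip(genes, x)), "null": dict(zip(genes, noise))},
        )
        assert abs(res.table.loc["null", "z"]) < 3
        assert res.table.loc["signal", "z"] > 3

    def test_constant_covariate_rejected(self):
        genes = [f"g{i}" for i in range(50)]
        y = dict(zip(genes, [0, 1] * 25))
        with pytest.raises(ValidationError, match="constant"):
            logistic_confounder_test(y, {"c": {g: 1.0 for g in genes}})

    def test_fitted_probabilities_exposed(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(400)]
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-x))).astype(int)
        res = logistic_confounder_test(dict(zip(genes, y)), {"x": dict(zip(genes, x))})
        assert len(res.fitted) == 400
        assert ((res.fitted > 0) & (res.fitted < 1)).all()


class TestInjectNoise:
    def test_level_zero_is_identity(self):
        v = pd.Series({"a": 1.0, "b": -2.0, "c": 0.5})
        out = inject_noise(v, 0.0, seed=1)
        pd.testing.assert_series_equal(out, v)

    def test_injected_component_has_requested_sd(self):
        rng = np.random.default_rng(18)
        v = pd.Series(rng.normal(0, 2, size=10_000), index=[f"g{i}" for i in range(10_000)])
        out = inject_noise(v, 1.0, seed=2)
        injected_sd = float(np.std(out - v, ddof=1))
        assert 1.9 <= injected_sd <= 2.1  # base level = sd(v) ~ 2

    def test_determinism(self):
        v = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        pd.testing.assert_series_equal(inject_noise(v, 0.7, seed=5), inject_noise(v, 0.7, seed=5))

    def test_negative_level_rejected(self):
        with pytest.raises(ValidationError):
            inject_noise(pd.Series({"a": 1.0, "b": 2.0}), -0.1, seed=0)


class TestDegradationExperiment:
    def test_level_zero_reduction_is_exactly_zero(self):
        rng = np.random.default_rng(19)
        net, values = random_instance(rng, 60)
        gold = make_gold(values, set(values.index[:20]))
        table = degradation_experiment(net, values, gold, levels=[0.0], n_reps=3, seed=1)
        assert (table["mean_reduction_ratio"] == 0.0).all()

    def test_noise_dominated_limit_drives_auc_to_chance(self):
        rng = np.random.default_rng(20)
        net, _ = random_instance(rng, 200)
        values = pd.Series(np.linspace(-1, 1, 200), index=net.nodes)
        gold = make_gold(values, set(values.sort_values().index[-50:]))
        table = degradation_experiment(net, values, gold, levels=[100.0], n_reps=30, seed=2)
        for _, row in table.iterrows():
            assert row["mean_auc"] == pytest.approx(0.5, abs=0.05)

    def test_output_is_tidy_per_level_per_predictor(self):
        rng = np.random.default_rng(21)
        net, values = random_instance(rng, 40)
        gold = make_gold(values, set(values.index[:10]))
        table = degradation_experiment(net, values, gold, levels=[0.0, 1.0], n_reps=2, seed=3)
        assert set(table["predictor"]) == {"raw", "nest"}
        assert len(table) == 4
        assert set(table.columns) == {"level", "predictor", "mean_auc",
                                      "mean_reduction_ratio", "sd"}
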