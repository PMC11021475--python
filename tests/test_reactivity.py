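"""Reactivity classification rule, percent-reactive, ROC, and benchmarking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import umiskit as uk
from umiskit.reactivity import (
    benchmark_predictors,
    classify_culture,
    classify_table,
    effective_background,
    fold_change_from_log2,
    percent_reactive,
    roc_auc,
    select_response_threshold,
    spearman_predictor,
)


def brute_force_auc(scores, labels) -> float:
    """Concordant-pair fraction over all (positive, negative) pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = concordant = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


class TestEffectiveBackground:
    @pytest.mark.parametrize(
        "alone,apc,expected", [(0.2, 0.5, 0.5), (0.0, 0.0, 0.0), (1.0, 1.0, 1.0)]
    )
    def test_max_rule(self, alone, apc, expected):
        assert effective_background(alone, apc) == expected

    def test_alternative_rules(self):
        assert effective_background(0.2, 0.5, rule="sum") == pytest.approx(0.7)
        assert effective_background(0.2, 0.5, rule="apc") == 0.5

    def test_negative_controls_rejected(self):
        with pytest.raises(ValueError):
            effective_background(-0.1, 0.5)


class TestClassifyCulture:
    def test_reactive_by_41bb(self):
        # 3.0% > 1% and 3.0 >= 2 x 1.2.
        assert classify_culture(3.0, 1.2, 50.0, 40.0) == "reactive"

    def test_not_reactive_when_both_gates_fail(self):
        # 0.8 <= 1%; 150 < 2 x 80.
        assert classify_culture(0.8, 0.1, 150.0, 80.0) == "not_reactive"

    def test_exact_one_percent_is_strict_boundary(self):
        assert classify_culture(1.0, 0.0, 0.0, 0.0) == "not_reactive"

    def test_exact_hundred_pgml_is_strict_boundary(self):
        assert classify_culture(0.0, 0.0, 100.0, 0.0) == "not_reactive"

    def test_zero_background_leaves_absolute_gate(self):
        assert classify_culture(1.01, 0.0, 0.0, 0.0) == "reactive"

    def test_twice_background_is_inclusive(self):
        assert classify_culture(2.4, 1.2, 0.0, 0.0) == "reactive"

    def test_monotone_in_measurements(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p41, pbg, ifng, ibg = rng.uniform(0, 3), rng.uniform(0, 2), rng.uniform(0, 300), rng.uniform(0, 200)
            before = classify_culture(p41, pbg, ifng, ibg)
            after = classify_culture(p41 + rng.uniform(0, 2), pbg, ifng + rng.uniform(0, 100), ibg)
            assert not (before == "reactive" and after == "not_reactive")

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            classify_culture(-0.5, 0.0, 0.0, 0.0)


class TestPercentReactive:
    def _table(self, n_reactive, n_total, sample="UM100"):
        rows = []
        for i in range(n_total):
            reactive = i < n_reactive
            rows.append(
                {
                    "sample_id": sample,
                    "culture_id": f"F{i}",
                    "p41bb": 5.0 if reactive else 0.1,
                    "p41bb_til_alone": 0.1,
                    "p41bb_til_apc": 0.1,
                    "ifng": 0.0,
                    "ifng_til_alone": 1.0,
                    "ifng_til_apc": 1.0,
                }
            )
        return pd.DataFrame(rows)

    def test_eight_of_twentyfour(self):
        classified = classify_table(self._table(8, 24))
        assert percent_reactive(classified, "UM100") == pytest.approx(100 * 8 / 24)

    @pytest.mark.parametrize("k,expected", [(0, 0.0), (24, 100.0)])
    def test_floor_and_ceiling(self, k, expected):
        classified = classify_table(self._table(k, 24))
        assert percent_reactive(classified, "UM100") == expected

    def test_missing_sample_rejected(self):
        classified = classify_table(self._table(1, 4))
        with pytest.raises(ValueError, match="no cultures"):
            percent_reactive(classified, "NOPE")

    def test_equals_indicator_mean(self):
        classified = classify_table(self._table(5, 7))
        assert percent_reactive(classified, "UM100") == pytest.approx(
            100 * classified["reactive"].mean()
        )


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_predictor([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert spearman_predictor([1, 2, 3, 4], [40, 30, 20, 10])[0] == -1.0

    def test_hand_case(self):
        rho, _ = spearman_predictor([1, 2, 3, 4], [10, 30, 20, 40])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_missing(self):
        rho, p = spearman_predictor([1, 2, 3], [5, 5, 5])
        assert np.isnan(rho) and np.isnan(p)


class TestRocAuc:
    def test_perfect_separation(self):
        _, area = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert area == 1.0

    def test_constant_score_uninformative(self):
        _, area = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert area == pytest.approx(0.5)

    def test_toy_case_three_quarters(self):
        _, area = roc_auc([0.3, 0.15, 0.1, 0.2], [1, 1, 0, 0])
        assert area == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice(np.linspace(0, 1, 8), size=n)  # force ties
            _, area = roc_auc(scores, labels)
            assert area == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestBenchmarkPredictors:
    def test_oracle_predictor_scores_perfectly(self):
        outcomes = pd.Series([0.0, 10.0, 40.0, 80.0], index=list("abcd"))
        results = benchmark_predictors({"oracle": outcomes}, outcomes)
        assert results[0].spearman_rho == 1.0
        assert results[0].auc == 1.0

    def test_noise_predictor_near_half_auc(self):
        rng = np.random.default_rng(10)
        outcomes = pd.Series(rng.uniform(0, 100, 100))
        noise = pd.Series(rng.normal(size=100), index=outcomes.index)
        results = benchmark_predictors({"noise": noise}, outcomes)
        assert results[0].auc == pytest.approx(0.5, abs=0.15)

    def test_synthetic_cohort_umis_beats_tmb(self, umis_scores, normalized_cohort, default_config):
        _, _, truth = normalized_cohort
        table = uk.simulate_reactivity(truth.theta, default_config)
        pct = percent_reactive(classify_table(table)).reindex(umis_scores.index)
        results = benchmark_predictors({"umis": umis_scores, "tmb": truth.tmb}, pct)
        by_name = {r.predictor: r for r in results}
        assert by_name["umis"].auc >= 0.8
        assert by_name["tmb"].auc == pytest.approx(0.5, abs=0.15)


class TestResponseThreshold:
    def test_even_and_odd_medians(self):
        scores = pd.Series({"a": 0.2, "b": 0.3, "c": 0.9})
        flags = pd.Series({"a": False, "b": False, "c": True})
        assert select_response_threshold(scores, flags) == pytest.approx(0.25)
        flags_all = pd.Series({"a": False, "b": False, "c": False})
        assert select_response_threshold(scores, flags_all) == pytest.approx(0.3)

    def test_no_nonresponders_rejected(self):
        scores = pd.Series({"a": 0.2})
        with pytest.raises(ValueError, match="no nonresponders"):
            select_response_threshold(scores, pd.Series({"a": True}))


class TestFoldChange:
    def test_reported_fold_pairs(self):
        assert fold_change_from_log2(-1.80) == pytest.approx(3.48, abs=0.005)
        assert fold_change_from_log2(-0.53) == pytest.approx(1.44, abs=0.005)

    def test_sign_symmetric(self):
        assert fold_change_from_log2(0.53) == fold_change_from_log2(-0.53)
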