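"""TF-iDF, mutual information, mRMR and Grubbs selection against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gutage import (FunctionalProfileMatrix, discretize, grubbs_critical_value,
                    grubbs_statistic, grubbs_weighted_select,
                    mutual_information, mrmr_select, tfidf_rank,
                    tfidf_weights, GrubbsWeightedSelector, MrmrSelector,
                    TfidfSelector)

from conftest import random_count_matrix


def brute_force_tfidf(counts):
    """Independent cell-by-cell evaluation of the TF-iDF definition."""
    n_samples, n_features = counts.shape
    out = np.zeros_like(counts, dtype=float)
    for j in range(n_samples):
        total = counts[j].sum()
        for i in range(n_features):
            m = sum(1 for k in range(n_samples) if counts[k, i] > 0)
            if total == 0 or m == 0:
                continue
            out[j, i] = counts[j, i] / total * np.log(n_samples / m)
    return out


class TestTfidf:
    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            matrix = random_count_matrix(rng, 20, 30)
            weights = tfidf_weights(matrix).weights.to_numpy()
            np.testing.assert_allclose(weights,
                                       brute_force_tfidf(matrix.values),
                                       atol=1e-12)

    def test_ubiquitous_feature_weighs_zero(self, small_matrix):
        weights = tfidf_weights(small_matrix).weights
        assert (weights["D"] == 0).all() and (weights["E"] == 0).all()

    def test_hand_computed_two_sample_case(self):
        frame = pd.DataFrame([[4.0, 4.0], [0.0, 4.0]],
                             index=["S1", "S2"], columns=["A", "B"])
        weights = tfidf_weights(FunctionalProfileMatrix(frame)).weights
        assert weights.loc["S1", "A"] == pytest.approx(0.5 * np.log(2))
        assert weights.loc["S1", "B"] == 0.0

    def test_zero_where_count_zero(self, rng):
        matrix = random_count_matrix(rng, 10, 15)
        weights = tfidf_weights(matrix).weights.to_numpy()
        assert (weights[matrix.values == 0] == 0).all()

    def test_single_sample_rejected(self):
        frame = pd.DataFrame([[1.0]], index=["S1"], columns=["A"])
        with pytest.raises(ValueError):
            tfidf_weights(FunctionalProfileMatrix(frame))

    def test_rank_single_occurrence_feature_first(self):
        # feature Z is the whole content of one sample: score ln(n)
        frame = pd.DataFrame(
            [[0.0, 3.0, 3.0], [5.0, 0.0, 0.0], [0.0, 3.0, 3.0],
             [0.0, 3.0, 3.0]],
            index=list("wxyz"), columns=["Z", "P", "Q"])
        ranking = tfidf_rank(FunctionalProfileMatrix(frame), 3)
        assert ranking.features[0] == "Z"
        assert ranking.scores[0] == pytest.approx(np.log(4))

    def test_rank_ignores_everywhere_features(self, small_matrix):
        ranking = tfidf_rank(small_matrix, 10)
        assert "D" not in ranking.features and "E" not in ranking.features

    def test_all_features_everywhere_gives_empty_ranking(self):
        frame = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                             columns=list("WXYZ"))
        assert tfidf_rank(FunctionalProfileMatrix(frame), 2).features == []

    def test_rank_requested_size(self, planted_cohort):
        matrix, _, _ = planted_cohort
        assert len(tfidf_rank(matrix, 10).features) == 10

    def test_rank_invariant_to_sample_scaling(self, rng):
        matrix = random_count_matrix(rng, 12, 25)
        base = tfidf_rank(matrix, 8)
        scaled = matrix.data.copy()
        scaled.iloc[3] *= 7.5
        again = tfidf_rank(FunctionalProfileMatrix(scaled), 8)
        assert base.features == again.features

    def test_scores_non_increasing_and_unique_features(self, rng):
        ranking = tfidf_rank(random_count_matrix(rng, 15, 40), 20)
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))
        assert len(set(ranking.features)) == len(ranking.features)


class TestDiscretize:
    def test_constant_column_maps_to_zero(self):
        out = discretize(np.full((5, 2), 3.0), t=1.0)
        assert (out.values == 0).all()

    def test_single_spike_column(self):
        out = discretize(np.array([[0.0], [0.0], [0.0], [10.0]]), t=1.0)
        np.testing.assert_array_equal(out.values.ravel(), [0, 0, 0, 1])

    def test_codomain(self, rng):
        out = discretize(rng.poisson(5, size=(30, 10)).astype(float), t=1.0)
        assert set(np.unique(out.values)) <= {-1, 0, 1}

    def test_matches_direct_thresholding(self, rng):
        data = rng.normal(10, 4, size=(25, 6))
        out = discretize(data, t=1.0).values
        mu, sd = data.mean(axis=0), data.std(axis=0, ddof=1)
        expected = np.where(data > mu + sd, 1, np.where(data < mu - sd, -1, 0))
        np.testing.assert_array_equal(out, expected)


def brute_force_mi(a, b):
    """Plug-in MI from the explicit 2-way contingency table, base 2."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    total = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            pxy = ((a == va) & (b == vb)).sum() / n
            if pxy == 0:
                continue
            px, py = (a == va).sum() / n, (b == vb).sum() / n
            total += pxy * np.log2(pxy / (px * py))
    return total


class TestMutualInformation:
    def test_constant_vector_gives_zero(self, rng):
        b = rng.integers(-1, 2, size=20)
        assert mutual_information(np.zeros(20), b) == pytest.approx(0.0)

    def test_identical_fair_binary_is_one_bit(self):
        v = [1, 1, -1, -1]
        assert mutual_information(v, v) == pytest.approx(1.0)

    def test_matches_contingency_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(-1, 2, size=50)
            b = rng.integers(-1, 2, size=50)
            assert mutual_information(a, b) == pytest.approx(
                brute_force_mi(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-1, 1), min_size=2, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_symmetric_and_non_negative(self, a, seed):
        b = np.random.default_rng(seed).integers(-1, 2, size=len(a))
        mi_ab = mutual_information(a, b)
        assert mi_ab >= 0.0
        assert mi_ab == pytest.approx(mutual_information(b, a), abs=1e-12)

    def test_zero_for_independent_construction(self):
        # block design: every (a, b) combination equally often
        a = np.repeat([0, 1], 10)
        b = np.tile([0, 1], 10)
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)


def exhaustive_mrmr_step(disc, labels, selected, candidates):
    """Best next feature by explicit evaluation of the difference criterion."""
    best, best_score = None, -np.inf
    for i in sorted(candidates):
        rel = brute_force_mi(disc[:, i], labels)
        if selected:
            red = np.mean([brute_force_mi(disc[:, i], disc[:, j])
                           for j in selected])
            score = rel - red
        else:
            score = rel
        if score > best_score + 1e-12:
            best, best_score = i, score
    return best, best_score


class TestMrmr:
    def test_first_pick_is_argmax_relevance(self, rng):
        for _ in range(20):
            matrix = random_count_matrix(rng, 30, 12)
            labels = rng.choice(["young", "old"], size=30)
            if len(set(labels)) < 2:
                continue
            ranking = mrmr_select(matrix, labels, 1)
            disc = discretize(matrix).values
            rels = [brute_force_mi(disc[:, i], labels)
                    for i in range(disc.shape[1])]
            assert ranking.scores[0] == pytest.approx(max(rels), abs=1e-12)

    def test_greedy_path_matches_exhaustive_evaluator(self, rng):
        for _ in range(8):
            matrix = random_count_matrix(rng, 40, 8)
            labels = np.where(rng.random(40) < 0.5, "young", "old")
            if len(set(labels)) < 2:
                continue
            ranking = mrmr_select(matrix, labels, 3)
            disc = discretize(matrix).values
            cols = {f: i for i, f in enumerate(matrix.feature_ids)}
            selected = []
            for step, feature in enumerate(ranking.features):
                _, oracle_score = exhaustive_mrmr_step(
                    disc, labels, selected,
                    set(cols.values()) - set(selected))
                assert ranking.scores[step] == pytest.approx(oracle_score,
                                                             abs=1e-9)
                selected.append(cols[feature])

    def test_duplicate_of_selected_feature_never_preferred(self):
        # af and dup are identical columns marking 10 of the 20 young
        # samples; g marks the *other* 10 young samples, so it has the same
        # relevance I(x; c) but only mild mutual information with af, while
        # dup carries redundancy I(af; af) = H(af) > 0
        n = 40
        labels = np.repeat(["young", "old"], n // 2)
        f = np.zeros(n); f[:10] = 30.0
        g = np.zeros(n); g[10:20] = 30.0
        frame = pd.DataFrame({"af": f, "dup": f.copy(), "g": g,
                              "noise": np.tile([4.0, 5.0], n // 2)},
                             index=[f"S{i:02d}" for i in range(n)])
        ranking = mrmr_select(FunctionalProfileMatrix(frame), labels, 2)
        assert ranking.features[0] == "af"       # lexicographic among ties
        assert ranking.features[1] == "g"

    def test_trace_records_relevance_and_redundancy(self, rng):
        matrix = random_count_matrix(rng, 30, 10)
        labels = np.where(rng.random(30) < 0.5, "young", "old")
        ranking = mrmr_select(matrix, labels, 4)
        assert ranking.trace is not None and len(ranking.trace) == 4
        disc = discretize(matrix).values
        cols = {f: i for i, f in enumerate(matrix.feature_ids)}
        sel = [cols[f] for f in ranking.features]
        # final-step D and R recomputed exactly
        d = np.mean([brute_force_mi(disc[:, i], labels) for i in sel])
        r = np.mean([[brute_force_mi(disc[:, i], disc[:, j]) for j in sel]
                     for i in sel])
        assert ranking.trace[-1]["relevance_D"] == pytest.approx(d, abs=1e-9)
        assert ranking.trace[-1]["redundancy_R"] == pytest.approx(r, abs=1e-9)

    def test_single_class_rejected(self, rng):
        matrix = random_count_matrix(rng, 10, 5)
        with pytest.raises(ValueError):
            mrmr_select(matrix, ["young"] * 10, 2)

    def test_deterministic(self, rng):
        matrix = random_count_matrix(rng, 30, 15)
        labels = np.where(np.arange(30) % 2 == 0, "young", "old")
        a = mrmr_select(matrix, labels, 5)
        b = mrmr_select(matrix, labels, 5)
        assert a.features == b.features and a.scores == b.scores


class TestGrubbs:
    def test_constant_vector(self):
        g, idx, flag = grubbs_statistic([5.0] * 6)
        assert g == 0.0 and not flag

    def test_hand_computed_example(self):
        g, idx, flag = grubbs_statistic([1.0, 2.0, 3.0, 10.0])
        assert g == pytest.approx(1.4697, abs=1e-4)
        assert idx == 3
        assert flag == (g > grubbs_critical_value(4, 0.05))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            grubbs_statistic([1.0, 2.0])

    def test_critical_value_formula(self):
        # independent evaluation of the t-based critical value at n=10
        n, alpha = 10, 0.05
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_critical_value(n, alpha) == pytest.approx(expected)

    def test_monte_carlo_calibration(self):
        # two-sided test at alpha=0.05 rejects ~5% of normal samples
        rng = np.random.default_rng(42)
        samples = rng.standard_normal((10_000, 20))
        sd = samples.std(axis=1, ddof=1)
        g = (np.abs(samples - samples.mean(axis=1, keepdims=True))
             / sd[:, None]).max(axis=1)
        rate = (g > grubbs_critical_value(20, 0.05)).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_no_outliers_gives_empty_ranking(self):
        frame = pd.DataFrame(np.tile([1.0, 2.0, 3.0, 4.0], (3, 1)).T,
                             index=list("abcd"), columns=list("XYZ"))
        labels = ["young", "young", "old", "old"]
        ranking = grubbs_weighted_select(FunctionalProfileMatrix(frame),
                                         labels, 10)
        assert ranking.features == []

    def test_single_flag_trace(self, rng):
        # features A and B flag sample 0 as an outlier; the classifier sees a
        # clean young/old split on them so the test sample is classified
        # correctly and both features earn weight 1
        n = 12
        labels = np.asarray(["young"] * 6 + ["old"] * 6)
        base = np.ones(n)
        a = base.copy(); a[labels == "young"] = 2.0; a[0] = 60.0
        b = base.copy(); b[labels == "young"] = 2.0; b[0] = 55.0
        frame = pd.DataFrame({"A": a, "B": b,
                              "C": rng.permutation(np.linspace(1, 2, n))},
                             index=[f"S{i}" for i in range(n)])
        ranking = grubbs_weighted_select(FunctionalProfileMatrix(frame),
                                         labels, 10)
        assert set(ranking.features) >= {"A", "B"}
        weights = dict(zip(ranking.features, ranking.scores))
        assert weights["A"] == 1.0 and weights["B"] == 1.0

    def test_top_n_bound(self, planted_cohort):
        matrix, records, _ = planted_cohort
        labels = np.asarray(["young" if r.age <= 40 else "old"
                             for r in records])
        sub = matrix.take_samples(matrix.sample_ids[:30])
        ranking = grubbs_weighted_select(sub, labels[:30], 10)
        assert len(ranking.features) <= 10


class TestSelectorEstimators:
    def test_transform_keeps_ranked_columns(self, planted_cohort):
        matrix, records, _ = planted_cohort
        sel = TfidfSelector(n_features=10).fit(matrix.data)
        out = sel.transform(matrix.data)
        assert out.shape == (matrix.n_samples, 10)
        assert set(sel.get_feature_names_out()) == set(sel.ranking_.features)

    def test_supervised_selectors_require_labels(self, planted_cohort):
        matrix, _, _ = planted_cohort
        with pytest.raises(ValueError):
            MrmrSelector().fit(matrix.data)
        with pytest.raises(ValueError):
            GrubbsWeightedSelector().fit(matrix.data)

    def test_get_set_params_round_trip(self):
        sel = MrmrSelector(n_features=7, threshold=2.0)
        params = sel.get_params()
        assert params["n_features"] == 7
        clone = MrmrSelector().set_params(**params)
        assert clone.get_params() == params
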