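"""Stratification: k-means, silhouette, cross-cohort assignment, group tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from somastrat.datatypes import OutcomeData
from somastrat.simulate import SimConfig, simulate_cohort
from somastrat.stratify import (
    SilhouetteKMeans,
    assign,
    average_silhouette,
    compare_groups,
    group_risk_model,
    kmeans_fit,
    select_k,
    sensitivity_drop,
)


def _wcss(X, labels):
    tot = 0.0
    for g in np.unique(labels):
        pts = X[labels == g]
        tot += ((pts - pts.mean(axis=0)) ** 2).sum()
    return tot


class TestKMeans:
    def test_two_point_masses(self):
        X = np.array([[0.0, 0.0]] * 5 + [[10.0, 10.0]] * 5)
        centroids, labels = kmeans_fit(X, 2, seed=0)
        assert _wcss(X, labels) == pytest.approx(0.0)
        assert len(np.unique(labels)) == 2

    def test_k_one_disallowed(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((5, 2)), 1)

    def test_k_exceeding_rows_disallowed(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((3, 2)), 4)

    def test_six_point_fixture_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2)) * 2
        _, labels = kmeans_fit(X, 2, seed=1, n_restarts=25)
        best = np.inf
        for size in range(1, 6):
            for subset in combinations(range(6), size):
                part = np.zeros(6, int)
                part[list(subset)] = 1
                best = min(best, _wcss(X, part))
        assert _wcss(X, labels) == pytest.approx(best, rel=1e-9)


class TestSilhouette:
    def test_far_separated_clouds_near_one(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(50, 0.1, (20, 3))])
        labels = np.repeat([0, 1], 20)
        assert average_silhouette(X, labels) > 0.9

    def test_four_point_hand_fixture(self):
        # A = {(0,0),(0,1)}, B = {(10,0),(10,1)}: a_i = 1 for all points,
        # b_i = (10 + sqrt(101))/2, s_i = (b-1)/b by symmetry
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        b = (10.0 + np.sqrt(101.0)) / 2.0
        assert average_silhouette(X, labels) == pytest.approx((b - 1) / b, rel=1e-12)

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        labels = rng.integers(0, 3, size=40)
        assert average_silhouette(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-12)

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 2, size=30)
        s = average_silhouette(X, labels)
        assert -1.0 <= s <= 1.0
        perm = rng.permutation(30)
        assert average_silhouette(X[perm], labels[perm]) == pytest.approx(s, abs=1e-12)

    def test_singleton_contributes_zero(self):
        X = np.array([[0.0], [10.0], [10.5]])
        labels = np.array([0, 1, 1])
        # point 0 is a singleton -> s = 0; point 1: a=0.5, b=10;
        # point 2: a=0.5, b=10.5
        expected = (0.0 + (10.0 - 0.5) / 10.0 + (10.5 - 0.5) / 10.5) / 3
        assert average_silhouette(X, labels) == pytest.approx(expected, rel=1e-12)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            average_silhouette(np.zeros((4, 1)), np.zeros(4, int))


class TestSelectK:
    def test_two_planted_groups_select_k2(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(size=250) < 0.38
        X = rng.normal(size=(250, 50))
        X[g] += 1.5
        model = select_k(X, seed=0)
        assert model.k == 2
        assert model.silhouette_by_k[2] == max(model.silhouette_by_k.values())

    def test_three_blobs_select_k3(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)),
                       rng.normal(8, 0.3, (30, 2)),
                       rng.normal([0, 8], 0.3, (30, 2))])
        model = select_k(X, seed=0)
        assert model.k == 3

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        m1 = select_k(X, seed=7)
        m2 = select_k(X, seed=7)
        assert m1.k == m2.k
        assert np.allclose(m1.centroids, m2.centroids)
        assert (m1.labels == m2.labels).all()

    def test_high_risk_group_gets_higher_label(self):
        rng = np.random.default_rng(8)
        g = (rng.uniform(size=200) < 0.4).astype(int)
        X = rng.normal(size=(200, 10))
        X[g == 1] += 2.0
        idx = pd.RangeIndex(200)
        # group with the shift carries all the events
        time = rng.exponential(5, 200)
        cause = np.where((g == 1) & (rng.uniform(size=200) < 0.8), 1, 0)
        oc = OutcomeData(pd.Series(time, index=idx), pd.Series(cause, index=idx))
        model = select_k(pd.DataFrame(X, index=idx), seed=0, outcomes=oc)
        high = model.labels[model.labels == 2].index
        assert (np.asarray(oc.cause)[high] == 1).mean() > \
            (np.asarray(oc.cause)[model.labels[model.labels == 1].index] == 1).mean()

    def test_sklearn_estimator_surface(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        est = SilhouetteKMeans(seed=0).fit(X)
        assert est.get_params()["seed"] == 0
        assert set(est.silhouette_by_k_) == {2, 3, 4, 5, 6}
        assert est.cluster_centers_.shape[1] == 3
        assert len(est.predict(X)) == 40


class TestAssign:
    def test_centroid_assigned_to_itself(self):
        centroids = np.array([[0.0, 0.0], [5.0, 5.0]])
        labels = assign(centroids, centroids)
        assert list(labels) == [1, 2]

    def test_translation_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 3))
        centroids = rng.normal(size=(2, 3))
        l1 = assign(X, centroids)
        shift = np.array([3.0, -1.0, 2.0])
        l2 = assign(X + shift, centroids + shift)
        assert (l1.to_numpy() == l2.to_numpy()).all()

    def test_exact_tie_goes_to_lowest_index(self):
        centroids = np.array([[-1.0], [1.0]])
        labels = assign(np.array([[0.0]]), centroids)
        assert labels.iloc[0] == 1

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            assign(np.zeros((3, 2)), np.zeros((2, 3)))

    def test_self_assignment_reproduces_training_labels(self):
        rng = np.random.default_rng(11)
        g = rng.uniform(size=100) < 0.4
        X = rng.normal(size=(100, 5))
        X[g] += 3.0
        model = select_k(pd.DataFrame(X), seed=0, k_range=(2,))
        back = assign(pd.DataFrame(X), model.centroids)
        assert (back.to_numpy() == model.labels.to_numpy()).all()

    def test_planted_groups_recovered_ari(self):
        # generator-produced two-group structure: adjusted Rand > 0.9
        from sklearn.metrics import adjusted_rand_score
        from somastrat.preprocess import (CohortStandardizer, aggregate_to_proteins,
                                          log2_transform, remove_flagged)
        cfg = SimConfig(n_patients=1000, n_somamers=60, removal_count=4,
                        dup2_count=3, dup3_count=1, n_informative=50,
                        delta=1.5, seed=13)
        coh = simulate_cohort(cfg)
        m = log2_transform(aggregate_to_proteins(remove_flagged(coh.somamer_table)))
        z = CohortStandardizer().fit(m).transform(m)
        panel = z.values[coh.truth["informative_proteins"]]
        model = select_k(panel, seed=0, outcomes=coh.outcomes)
        assert model.k == 2
        assert adjusted_rand_score(coh.truth["group"], model.labels) > 0.9


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=df.index)
        comp = compare_groups(df, labels)
        assert comp.table.loc["v", "statistic"] == pytest.approx(0.0)
        assert comp.table.loc["v", "p"] == pytest.approx(1.0)

    def test_welch_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(0.5, 1.0, 10)
        df = pd.DataFrame({"v": np.concatenate([x, y])})
        labels = pd.Series(np.repeat([1, 2], 10), index=df.index)
        p_welch = compare_groups(df, labels).table.loc["v", "p"]
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += abs(perm[:10].mean() - perm[10:].mean()) >= obs
        p_perm = count / n_perm
        assert abs(p_welch - p_perm) < 0.05

    def test_chi_square_hand_arithmetic(self):
        # 2x2 table (20,10; 10,20) without continuity correction:
        # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2) = 60*300^2/30^4 = 20/3
        vals = np.concatenate([np.zeros(20), np.ones(10), np.zeros(10), np.ones(20)])
        df = pd.DataFrame({"b": vals})
        labels = pd.Series(np.repeat([1, 2], 30), index=df.index)
        comp = compare_groups(df, labels, binary_vars=("b",))
        assert comp.table.loc["b", "test"] == "chi2"
        assert comp.table.loc["b", "statistic"] == pytest.approx(20.0 / 3.0, rel=1e-12)

    def test_empty_group_errors(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(df, pd.Series([1, 1, 1], index=df.index))


class TestGroupRisk:
    def test_nonbinary_labels_rejected(self):
        idx = pd.RangeIndex(6)
        oc = OutcomeData(pd.Series(np.arange(1.0, 7.0), index=idx),
                         pd.Series([1, 1, 2, 0, 1, 2], index=idx))
        with pytest.raises(ValueError, match="binary"):
            group_risk_model(pd.Series([1, 2, 3, 1, 2, 3], index=idx), oc)

    def test_independent_covariate_barely_moves_estimate(self):
        from somastrat.simulate import simulate_competing_events
        rng = np.random.default_rng(14)
        n = 2000
        idx = pd.RangeIndex(n)
        g = pd.Series((rng.uniform(size=n) < 0.4).astype(int) + 1, index=idx)
        oc = simulate_competing_events((g - 1) * np.log(2), SimConfig(seed=0),
                                       rng=rng, index=idx)
        f0 = group_risk_model(g, oc)
        noise = pd.DataFrame({"z": rng.normal(size=n)}, index=idx)
        f1 = group_risk_model(g, oc, adjust=noise)
        assert abs(f0.beta[0] - f1.beta[0]) < 0.05

    def test_missing_adjustment_rejected(self):
        idx = pd.RangeIndex(8)
        oc = OutcomeData(pd.Series(np.arange(1.0, 9.0), index=idx),
                         pd.Series([1, 1, 2, 0, 1, 2, 1, 0], index=idx))
        g = pd.Series([1, 2, 1, 2, 1, 2, 1, 2], index=idx)
        adj = pd.DataFrame({"a": [1.0, np.nan] + [0.5] * 6}, index=idx)
        with pytest.raises(ValueError, match="missing"):
            group_risk_model(g, oc, adjust=adj)


class TestSensitivity:
    def _panel(self, seed=15, n=300, p=12):
        rng = np.random.default_rng(seed)
        g = rng.uniform(size=n) < 0.4
        X = rng.normal(size=(n, p))
        X[g, :8] += 2.0  # informative block; last columns pure noise
        cols = [f"I{j}" for j in range(8)] + [f"N{j}" for j in range(p - 8)]
        return pd.DataFrame(X, columns=cols)

    def test_dropping_nothing_changes_nothing(self):
        panel = self._panel()
        base = select_k(panel, seed=0, k_range=(2,))
        model, nd, nv = sensitivity_drop(panel, [], base, seed=0)
        assert nd == 0 and nv is None

    def test_dropping_noise_protein_is_stable(self):
        panel = self._panel()
        base = select_k(panel, seed=0, k_range=(2,))
        model, nd, nv = sensitivity_drop(panel, ["N0"], base,
                                         matrix_valid=panel, seed=0)
        assert nd <= 0.05 * len(panel)
        assert nv <= 0.05 * len(panel)

    def test_mapping_is_overlap_maximizing_bijection_for_k2(self):
        from somastrat.stratify import _best_label_mapping
        idx = pd.RangeIndex(10)
        base = pd.Series([1] * 6 + [2] * 4, index=idx)
        flipped = pd.Series([2] * 6 + [1] * 4, index=idx)
        mapping = _best_label_mapping(base, flipped, 2)
        assert mapping == {2: 1, 1: 2}

    def test_dropping_everything_errors(self):
        panel = self._panel()
        base = select_k(panel, seed=0, k_range=(2,))
        with pytest.raises(ValueError):
            sensitivity_drop(panel, list(panel.columns), base)
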