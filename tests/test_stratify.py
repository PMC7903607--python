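import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cpa.stratify import (
    ClusterAssignment,
    anova_annotate,
    cluster,
    enrichment,
    pairwise_distances,
    select_k,
    silhouette,
)
from conftest import toy_matrix


def blobs(n, k, sep, d=5, seed=0):
    """k spherical unit-variance Gaussian blobs with pairwise center
    distance exactly `sep` standard deviations."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, n)
    centers = np.zeros((k, d))
    for i in range(k):
        centers[i, i % d] = sep / np.sqrt(2)
    X = centers[labels] + rng.standard_normal((n, d))
    return pd.DataFrame(X, index=[f"p{i}" for i in range(n)]), labels


class TestPairwiseDistances:
    def test_identical_rows_have_zero_distance(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        D = pairwise_distances(df)
        assert D.loc["a", "b"] == 0.0

    def test_three_four_five_triangle(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        D = pairwise_distances(df)
        assert D.loc["a", "b"] == pytest.approx(5.0)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)

    def test_invariant_to_patient_ordering(self):
        df, _ = blobs(30, 2, 5, seed=1)
        D1 = pairwise_distances(df)
        perm = df.sample(frac=1, random_state=0)
        D2 = pairwise_distances(perm)
        pd.testing.assert_frame_equal(D2.loc[D1.index, D1.columns], D1)

    def test_missing_cells_rejected(self):
        m = toy_matrix({"p1": {"A": np.nan, "B": 1.0}, "p2": {"A": 1.0, "B": 2.0}})
        with pytest.raises(ValueError, match="impute"):
            pairwise_distances(m)


class TestCluster:
    def test_two_well_separated_blobs_fully_recovered(self):
        df, truth = blobs(200, 2, 10, seed=1)
        D = pairwise_distances(df)
        a = cluster(D, 2, method="dapwc", seed=0)
        assert adjusted_rand_score(truth, a.labels) == 1.0
        assert set(a.labels) == {1, 2}

    def test_k_equal_n_rejected(self):
        df, _ = blobs(10, 2, 5)
        D = pairwise_distances(df)
        with pytest.raises(ValueError):
            cluster(D, 10)

    def test_backends_agree_on_separated_blobs(self):
        df, _ = blobs(250, 3, 10, seed=7)
        D = pairwise_distances(df)
        a = cluster(D, 3, "dapwc", seed=1)
        b = cluster(D, 3, "kmedoids", seed=1)
        assert adjusted_rand_score(a.labels, b.labels) >= 0.95

    def test_deterministic_for_fixed_seed(self):
        df, _ = blobs(100, 2, 6, seed=2)
        D = pairwise_distances(df)
        a = cluster(D, 2, seed=3)
        b = cluster(D, 2, seed=3)
        assert a.labels.equals(b.labels)

    def test_unknown_method_rejected(self):
        df, _ = blobs(20, 2, 5)
        with pytest.raises(ValueError, match="method"):
            cluster(pairwise_distances(df), 2, method="spectral")


class TestSelectK:
    def test_three_planted_blobs_select_three(self):
        df, _ = blobs(300, 3, 8, seed=2)
        D = pairwise_distances(df)
        best, table = select_k(D, range(2, 7), seed=0)
        assert best.k == 3
        assert table["silhouette"].between(-1, 1).all()

    def test_single_blob_reports_low_silhouette_without_crash(self):
        df, _ = blobs(150, 1, 0, seed=4)
        D = pairwise_distances(df)
        best, table = select_k(D, range(2, 5), seed=0)
        assert table["silhouette"].max() < 0.5


def silhouette_double_loop(labels, D):
    """Literal per-point silhouette for the oracle comparison."""
    labels = np.asarray(labels)
    D = np.asarray(D)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s.mean()


class TestSilhouette:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        X = rng.standard_normal((n, 3))
        labels = rng.integers(1, 4, n)
        while len(set(labels)) < 2:
            labels = rng.integers(1, 4, n)
        D = pairwise_distances(pd.DataFrame(X))
        assert silhouette(labels, D) == pytest.approx(
            silhouette_double_loop(labels, D), abs=1e-12
        )

    def test_two_tight_far_blobs_approach_one(self):
        df, truth = blobs(100, 2, 200, seed=0)
        D = pairwise_distances(df)
        assert silhouette(truth + 1, D) > 0.97

    def test_random_labels_on_structureless_data_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((200, 4)))
        D = pairwise_distances(df)
        si = silhouette(rng.integers(1, 4, 200), D)
        assert abs(si) < 0.1

    def test_singleton_cluster_contributes_zero(self):
        D = pairwise_distances(pd.DataFrame([[0.0], [1.0], [1.1]]))
        si = silhouette(np.array([1, 2, 2]), D)
        oracle = silhouette_double_loop(np.array([1, 2, 2]), D)
        assert si == pytest.approx(oracle)


def assignment_from(labels, index):
    labels = pd.Series(labels, index=index)
    return ClusterAssignment(labels, int(labels.max()), 0.0, "manual")


class TestAnova:
    def test_matches_closed_form_f_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]), np.array([5.0, 6.0, 9.0])]
        values = pd.DataFrame({"A": np.concatenate(groups)}, index=[f"p{i}" for i in range(9)])
        labels = assignment_from([1] * 3 + [2] * 3 + [3] * 3, values.index)
        out = anova_annotate(values, labels)
        k, n = 3, 9
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / (k - 1)) / (ssw / (n - k))
        p = stats.f.sf(F, k - 1, n - k)
        assert out.loc["A", "F"] == pytest.approx(F, abs=1e-10)
        assert out.loc["A", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_constant_data_gives_f_zero_p_one(self):
        values = pd.DataFrame({"A": [2.0] * 6}, index=[f"p{i}" for i in range(6)])
        labels = assignment_from([1, 1, 1, 2, 2, 2], values.index)
        out = anova_annotate(values, labels)
        assert out.loc["A", "F"] == 0.0
        assert out.loc["A", "p_value"] == 1.0

    def test_zero_within_variance_different_means_flagged_degenerate(self):
        values = pd.DataFrame({"A": [1.0] * 3 + [2.0] * 3}, index=[f"p{i}" for i in range(6)])
        labels = assignment_from([1, 1, 1, 2, 2, 2], values.index)
        out = anova_annotate(values, labels)
        assert out.loc["A", "p_value"] == 0.0
        assert bool(out.loc["A", "degenerate"])

    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            {"A": rng.standard_normal(90), "B": rng.standard_normal(90)},
            index=[f"p{i}" for i in range(90)],
        )
        lab = np.array([1] * 30 + [2] * 30 + [3] * 30)
        values.loc[lab == 2, "A"] += 3.0
        out = anova_annotate(values, assignment_from(lab, values.index))
        assert bool(out.loc["A", "significant"])
        assert not bool(out.loc["B", "significant"])


def enrichment_by_enumeration(N, K, eta, kappa):
    """P[at least kappa disease patients in a uniformly drawn size-eta cluster]."""
    hits = total = 0
    for draw in itertools.combinations(range(N), eta):
        total += 1
        hits += sum(1 for x in draw if x < K) >= kappa
    return hits / total


class TestEnrichment:
    def test_kappa_zero_gives_p_one(self):
        assert enrichment(100, 10, 20, 0).p_value == pytest.approx(1.0)

    def test_small_case_exhaustive(self):
        # N=5, K=2, eta=2, kappa=2: 1 favourable of C(5,2)=10 draws
        assert enrichment(5, 2, 2, 2).p_value == pytest.approx(0.1, abs=1e-12)

    def test_non_increasing_in_kappa(self):
        ps = [enrichment(50, 10, 15, k).p_value for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("N", [4, 6, 9])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(N + 1):
            for eta in range(1, N + 1):
                for kappa in range(0, min(K, eta) + 1):
                    expected = enrichment_by_enumeration(N, K, eta, kappa)
                    assert enrichment(N, K, eta, kappa).p_value == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_tail_overlap_identity(self):
        # upper tail from kappa plus lower tail through kappa counts pmf(kappa) twice
        N, K, eta, kappa = 30, 8, 12, 4
        upper = enrichment(N, K, eta, kappa).p_value
        lower = stats.hypergeom.cdf(kappa, N, K, eta)
        pmf = stats.hypergeom.pmf(kappa, N, K, eta)
        assert upper + lower == pytest.approx(1.0 + pmf, abs=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            enrichment(10, 4, 3, 5)  # kappa > min(K, eta)
        with pytest.raises(ValueError):
            enrichment(10, 12, 3, 1)  # K > N

    def test_enriched_flag_below_alpha(self):
        res = enrichment(200, 20, 20, 12)
        assert res.p_value < 0.05 and res.enriched
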