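import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from gutmeta.stats import (
    DistanceMatrix,
    bh_adjust,
    bioenv,
    distance_matrix,
    fisher_association,
    gene_count,
    gower_distances,
    pcoa,
    permanova,
    q_tier,
    rank_sum_p,
    shannon_index,
    wilcoxon_bh,
)
from gutmeta.tables import ValidationError
from .conftest import make_relative


class TestUnivariate:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            (np.full(8, 1 / 8), np.log(8)),
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
        ],
    )
    def test_shannon_closed_forms(self, profile, expected):
        assert shannon_index(profile) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_unnormalized(self):
        with pytest.raises(ValidationError):
            shannon_index([0.5, 0.3])

    @pytest.mark.parametrize(
        "row,expected", [([0, 1, 3, 0], 2), ([0, 0], 0), ([0.5, 2], 1)]
    )
    def test_gene_count_threshold(self, row, expected):
        assert gene_count(row) == expected


def wilcoxon_enumeration_p(x, y):
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    obs = ranks[:n].sum()
    mean = ranks.sum() * n / len(pooled)
    sums = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    sums = np.array(sums)
    return float(np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-12))


class TestRankSum:
    def test_exact_small_sample_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            assert rank_sum_p(x, y) == pytest.approx(
                wilcoxon_enumeration_p(x, y), abs=1e-12
            )

    def test_constant_data_p_one(self):
        assert rank_sum_p([1, 1, 1], [1, 1, 1]) == 1.0


class TestBH:
    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.9])
        assert np.allclose(q, [0.03, 0.03, 0.9])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_q_monotone_in_p_rank_and_never_below_p(self, ps):
        ps = np.array(ps)
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= ps - 1e-12)

    def test_tier_scheme(self):
        assert q_tier(0.15) == "*"
        assert q_tier(0.0005) == "****"
        assert q_tier(0.07) == "**"
        assert q_tier(0.03) == "***"
        assert q_tier(0.5) == ""


class TestDistances:
    def test_identical_rows_zero_under_all_metrics(self):
        rel = make_relative([[0.2, 0.8], [0.2, 0.8]])
        for metric in ("bray_curtis", "jensen_shannon"):
            D = distance_matrix(rel, metric)
            assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_extremes(self):
        rel = make_relative([[1.0, 0.0], [0.0, 1.0]])
        assert distance_matrix(rel, "bray_curtis").values[0, 1] == pytest.approx(1.0)
        assert distance_matrix(rel, "jensen_shannon").values[0, 1] == pytest.approx(
            np.sqrt(np.log(2)), abs=1e-12
        )

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.ones(5), size=3)
        rel = make_relative(X)
        bc = distance_matrix(rel, "bray_curtis").values
        js = distance_matrix(rel, "jensen_shannon").values
        for i, j in itertools.combinations(range(3), 2):
            x, y = X[i], X[j]
            assert bc[i, j] == pytest.approx(
                np.abs(x - y).sum() / (x + y).sum(), abs=1e-12
            )
            m = (x + y) / 2
            kl = lambda a, b: np.sum(
                np.where(a > 0, a * np.log(np.where(a > 0, a / b, 1.0)), 0.0)
            )
            assert js[i, j] == pytest.approx(
                np.sqrt(0.5 * kl(x, m) + 0.5 * kl(y, m)), abs=1e-9
            )

    def test_jensen_shannon_triangle_inequality(self):
        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(6), size=3 * 1000)
        rel = make_relative(X.reshape(-1, 6))
        vals = rel.values
        from scipy.spatial.distance import jensenshannon

        for k in range(1000):
            a, b, c = vals[3 * k], vals[3 * k + 1], vals[3 * k + 2]
            dab = jensenshannon(a, b)
            dbc = jensenshannon(b, c)
            dac = jensenshannon(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_gower_mixed_types(self):
        df = pd.DataFrame(
            {"num": [0.0, 5.0, 10.0], "cat": ["x", "x", "y"]},
            index=["a", "b", "c"],
        )
        G = gower_distances(df)
        assert G[0, 1] == pytest.approx(0.25)  # (0.5 + 0) / 2
        assert G[0, 2] == pytest.approx(1.0)   # (1.0 + 1) / 2

    def test_metric_input_mismatch_rejected(self):
        rel = make_relative([[0.5, 0.5]])
        with pytest.raises(ValidationError):
            distance_matrix(rel.data, "bray_curtis")
        with pytest.raises(ValidationError):
            distance_matrix(rel, "gower")


class TestPcoa:
    def test_three_equidistant_points_give_equal_eigenvalues(self):
        D = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3), "bray_curtis")
        coords, evals = pcoa(D, n_axes=2)
        assert evals[0] == pytest.approx(evals[1], rel=1e-9)
        assert evals[0] > 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(10)], D, "bray_curtis")
        coords, _ = pcoa(dm, n_axes=2)
        C = coords.to_numpy()
        D2 = np.sqrt(((C[:, None] - C[None, :]) ** 2).sum(-1))
        assert np.abs(D - D2).max() < 1e-9

    def test_duplicate_samples_coincide(self):
        rel = make_relative([[0.2, 0.8], [0.2, 0.8], [0.7, 0.3]])
        D = distance_matrix(rel, "bray_curtis")
        coords, _ = pcoa(D, n_axes=1)
        assert coords.iloc[0, 0] == pytest.approx(coords.iloc[1, 0], abs=1e-9)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        rel = make_relative(rng.dirichlet(np.ones(6), size=8))
        D = distance_matrix(rel, "bray_curtis")
        ours, evals = pcoa(D, n_axes=2)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=D.ids)
        )
        assert np.allclose(
            np.abs(ours.to_numpy()),
            np.abs(theirs.samples.iloc[:, :2].to_numpy()),
            atol=1e-8,
        )


class TestPermanova:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        rel = make_relative(rng.dirichlet(np.ones(5), size=12))
        D = distance_matrix(rel, "bray_curtis")
        labels = np.array(["a"] * 6 + ["b"] * 6)
        r1 = permanova(D, labels, n_permutations=99, seed=0)
        perm = rng.permutation(12)
        D2 = DistanceMatrix([D.ids[i] for i in perm], D.values[np.ix_(perm, perm)], D.metric)
        r2 = permanova(D2, labels[perm], n_permutations=99, seed=0)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-12)

    def test_perfect_separation_minimal_p(self):
        # duplicated points per group, far apart: every distinct permutation
        # fits worse, so p hits the add-one floor
        pts = np.vstack([np.zeros((10, 2)), np.full((10, 2), 10.0)])
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(20)], D, "bray_curtis")
        res = permanova(dm, np.array(["a"] * 10 + ["b"] * 10), n_permutations=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3), "bray_curtis")
        with pytest.raises(ValidationError):
            permanova(dm, np.array(["x", "x", "y"]), seed=0)

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        rel = make_relative(rng.dirichlet(np.ones(6), size=14))
        D = distance_matrix(rel, "bray_curtis")
        labels = np.array(["a"] * 7 + ["b"] * 7)
        ours = permanova(D, labels, n_permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.values, ids=D.ids), labels, permutations=0
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestBioenv:
    def test_driving_covariate_recovered(self):
        rng = np.random.default_rng(7)
        rel = make_relative(rng.dirichlet(np.ones(8), size=25))
        D = distance_matrix(rel, "bray_curtis")
        coords, _ = pcoa(D, n_axes=1)
        cov = pd.DataFrame(index=pd.Index(D.ids))
        cov["driver"] = np.exp(coords.iloc[:, 0].to_numpy())  # monotone transform
        for j in range(5):
            cov[f"noise{j}"] = rng.normal(size=25)
        res = bioenv(D, cov, max_subset_size=2)
        assert "driver" in res.best_subset

    def test_all_noise_covariates_center_near_zero(self):
        rng = np.random.default_rng(8)
        best = []
        for s in range(50):
            rel = make_relative(rng.dirichlet(np.ones(6), size=15))
            D = distance_matrix(rel, "bray_curtis")
            cov = pd.DataFrame(
                rng.normal(size=(15, 3)), index=D.ids, columns=["c1", "c2", "c3"]
            )
            r = bioenv(D, cov, max_subset_size=1)
            # take the score of a fixed subset, not the maximum over subsets
            best.append(float(r.scores.loc[r.scores["subset"] == ("c1",), "r"].iloc[0]))
        assert abs(np.median(best)) < 0.1

    def test_tied_duplicate_covariates_pick_lexicographic_first(self):
        rng = np.random.default_rng(9)
        rel = make_relative(rng.dirichlet(np.ones(5), size=12))
        D = distance_matrix(rel, "bray_curtis")
        v = rng.normal(size=12)
        cov = pd.DataFrame({"b_copy": v, "a_copy": v}, index=D.ids)
        res = bioenv(D, cov, max_subset_size=2)
        assert res.best_subset == ("a_copy",)

    def test_combinatorial_guard(self):
        rng = np.random.default_rng(10)
        rel = make_relative(rng.dirichlet(np.ones(4), size=8))
        D = distance_matrix(rel, "bray_curtis")
        cov = pd.DataFrame(
            rng.normal(size=(8, 21)), index=D.ids,
            columns=[f"c{i:02d}" for i in range(21)],
        )
        with pytest.raises(ValidationError, match="max_subset_size"):
            bioenv(D, cov)


class TestFisher:
    def test_perfect_association_hypergeometric(self):
        membership = np.array(["g"] * 10 + ["h"] * 10)
        disease = np.array(["CD"] * 10 + ["CT"] * 10)
        res = fisher_association(membership, disease)
        assert res.loc["g", "p"] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_no_association_p_one(self):
        membership = np.array(["g"] * 10 + ["h"] * 10)
        disease = np.array((["CD"] * 5 + ["CT"] * 5) * 2)
        res = fisher_association(membership, disease)
        assert res.loc["g", "p"] == pytest.approx(1.0)

    def test_cohort_membership_associates_with_disease(self, default_cohort):
        labels = default_cohort.truth["labels"]
        res = fisher_association(
            labels.to_numpy(), default_cohort.metadata.disease_status.to_numpy()
        )
        assert res.loc["A", "q"] < 0.01
        assert res.loc["C", "q"] < 0.01


class TestWilcoxonBH:
    def test_exact_p_matches_enumeration_at_small_n(self):
        rng = np.random.default_rng(11)
        X = rng.normal(10, 1, size=(8, 3))
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(8)], columns=list("abc"))
        res = wilcoxon_bh(df, [f"S{i}" for i in range(4)], [f"S{i}" for i in range(4, 8)])
        for j, col in enumerate("abc"):
            expected = wilcoxon_enumeration_p(X[:4, j], X[4:, j])
            assert res.loc[col, "p"] == pytest.approx(expected, abs=1e-12)

    def test_constant_feature_p_one(self):
        df = pd.DataFrame(
            {"flat": np.ones(8), "var": np.arange(8.0)},
            index=[f"S{i}" for i in range(8)],
        )
        res = wilcoxon_bh(df, [f"S{i}" for i in range(4)], [f"S{i}" for i in range(4, 8)])
        assert res.loc["flat", "p"] == 1.0
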