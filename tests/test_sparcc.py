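import numpy as np
import pytest

from gutmeta.simulate import CohortConfig, simulate_cohort
from gutmeta.sparcc import (
    _basis_solution,
    _log_ratio_variances,
    _rho_from,
    _single_inference,
    build_network,
    compare_networks,
    sparcc_correlations,
    sparcc_pvalues,
)
from gutmeta.tables import ValidationError
from .conftest import make_counts


def lognormal_counts(rng, n, d, mu=5.0, sigma=1.0):
    return rng.poisson(rng.lognormal(mu, sigma, size=(n, d)))


class TestCore:
    def test_four_taxon_inference_matches_direct_solver(self):
        """On 4 taxa (no exclusion) the basis variances and correlations must
        agree with an explicit solve of the same t/omega linear system."""
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.full(4, 5.0), size=60)
        t = _log_ratio_variances(np.log(f))
        rho, omega = _single_inference(np.log(f), exclusion_threshold=2.0,
                                       max_exclusion_rounds=10)
        D = 4
        M = np.ones((D, D)) + (D - 2) * np.eye(D)
        omega_direct = np.linalg.inv(M) @ t.sum(axis=1)
        rho_direct = (
            omega_direct[:, None] + omega_direct[None, :] - t
        ) / (2 * np.sqrt(np.outer(omega_direct, omega_direct)))
        np.fill_diagonal(rho_direct, 1.0)
        assert np.abs(omega - omega_direct).max() < 1e-6
        assert np.abs(rho - np.clip(rho_direct, -1, 1)).max() < 1e-6

    def test_symmetry_unit_diagonal_and_bounds(self):
        rng = np.random.default_rng(0)
        tab = make_counts(lognormal_counts(rng, 80, 20))
        res = sparcc_correlations(tab, n_iterations=5, seed=1)
        assert np.array_equal(res.rho, res.rho.T)
        assert np.allclose(np.diag(res.rho), 1.0)
        assert np.all(np.abs(res.rho) <= 1.0)

    def test_fewer_than_four_taxa_rejected(self):
        tab = make_counts(np.ones((10, 3), dtype=int))
        with pytest.raises(ValidationError, match="4 taxa"):
            sparcc_correlations(tab, seed=0)

    def test_depth_rescaling_leaves_correlations_stable(self):
        """Compositional property: multiplying sequencing depth 10x changes
        the inferred correlations only through resampling noise."""
        rng = np.random.default_rng(4)
        base = rng.lognormal(4, 1, size=(100, 20))
        X1 = rng.poisson(base)
        X10 = rng.poisson(base * 10)
        r1 = sparcc_correlations(make_counts(X1), n_iterations=10, seed=2)
        r10 = sparcc_correlations(make_counts(X10), n_iterations=10, seed=2)
        off = np.triu_indices(20, 1)
        assert np.median(np.abs(r1.rho[off] - r10.rho[off])) < 0.05


class TestPvalues:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(5)
        tab = make_counts(lognormal_counts(rng, 40, 6))
        res = sparcc_correlations(tab, n_iterations=5, seed=0)
        p = sparcc_pvalues(tab, res, n_null=100, seed=1)
        off = p[np.triu_indices(6, 1)]
        assert off.min() >= 1 / 101
        assert off.max() <= 1.0

    def test_null_floor_enforced(self):
        rng = np.random.default_rng(5)
        tab = make_counts(lognormal_counts(rng, 20, 5))
        res = sparcc_correlations(tab, n_iterations=2, seed=0)
        with pytest.raises(ValidationError, match="n_null"):
            sparcc_pvalues(tab, res, n_null=10, seed=0)


class TestNetwork:
    @staticmethod
    def _result(rho, ids=None):
        from gutmeta.sparcc import SparccResult

        ids = ids or [f"T{i}" for i in range(rho.shape[0])]
        return SparccResult(ids, rho, np.ones(rho.shape[0]), 1, 0.25)

    def test_edge_filter_rules(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.6
        rho[2, 3] = rho[3, 2] = -0.35
        rho[0, 2] = rho[2, 0] = 0.9  # strong but not significant
        p = np.ones((4, 4))
        p[0, 1] = p[1, 0] = 0.005
        p[2, 3] = p[3, 2] = 0.002
        net = build_network(self._result(rho), p)
        assert set(map(frozenset, net.edges)) == {
            frozenset({"T0", "T1"}), frozenset({"T2", "T3"})
        }
        assert net.edges["T0", "T1"]["sign"] == 1
        assert net.edges["T2", "T3"]["sign"] == -1

    def test_all_insignificant_gives_empty_network(self):
        rho = np.full((4, 4), 0.9)
        np.fill_diagonal(rho, 1.0)
        net = build_network(self._result(rho), np.ones((4, 4)))
        assert net.number_of_edges() == 0

    def test_identity_and_bookkeeping_of_diff(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.7
        rho[1, 2] = rho[2, 1] = 0.4
        p = np.zeros((4, 4))
        net = build_network(self._result(rho), p)
        same = compare_networks(net, net)
        assert not same.edges_lost and not same.edges_gained
        assert same.edges_shared == set(map(frozenset, net.edges))
        empty = build_network(self._result(np.eye(4)), p)
        diff = compare_networks(net, empty)
        assert len(diff.edges_lost) == 2 and not diff.edges_gained
        assert diff.strong_lost == {frozenset({"T0", "T1"})}

    def test_disjoint_networks_rejected(self):
        import networkx as nx

        a = nx.Graph()
        a.add_node("x")
        b = nx.Graph()
        b.add_node("y")
        with pytest.raises(ValidationError, match="share no nodes"):
            compare_networks(a, b)


class TestDifferentialRecovery:
    def test_control_community_keeps_more_edges(self):
        """Correlations injected only into the control-like component produce
        a denser control network than the case-exclusive one (display
        threshold 0.3, empirical p < 0.01; 10 seeded cohorts)."""
        pairs = [("MGS0019", "MGS0020"), ("MGS0021", "MGS0022"), ("MGS0023", "MGS0024")]
        sub = [f"MGS{i:04d}" for i in range(19, 35)]
        wins = 0
        for s in range(10):
            cfg = CohortConfig.default(300 + s)
            cfg.correlations = [
                {"taxa": p, "strength": 0.05, "component": "A"} for p in pairs
            ]
            cohort = simulate_cohort(cfg)
            lab = cohort.truth["labels"]
            nets = {}
            for comp in ("A", "C"):
                tab = cohort.counts.subset(
                    samples=list(lab.index[lab == comp]), features=sub
                )
                res = sparcc_correlations(tab, n_iterations=10, seed=s)
                p = sparcc_pvalues(tab, res, n_null=100, seed=s, null_iterations=3)
                nets[comp] = build_network(res, p)
            wins += nets["A"].number_of_edges() > nets["C"].number_of_edges()
        assert wins >= 9
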