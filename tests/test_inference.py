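import itertools

import numpy as np
import pytest

from coocnet.datatypes import TaxonRecord, stack_tables
from coocnet.inference import (
    ConsensusConfig,
    CorrelationMatrix,
    EnsembleConfig,
    EnsembleNetwork,
    MbGraph,
    MBNeighborhood,
    SparCC,
    SparccConfig,
    SparccEstimate,
    SpearmanNetwork,
    basis_correlations,
    build_ensemble,
    logratio_variance,
)


def exact_moment_log_basis(cov, n, rng):
    """Draws whose sample covariance (ddof=1) equals ``cov`` exactly."""
    p = cov.shape[0]
    G = rng.normal(size=(n, p))
    G -= G.mean(axis=0)
    C = np.cov(G.T)
    G = G @ np.linalg.inv(np.linalg.cholesky(C)).T @ np.linalg.cholesky(cov).T
    return G


def planted_basis(p=8, pairs=((0, 1, 0.25), (2, 3, 0.2), (4, 5, -0.2),
                              (6, 7, 0.15)), seed=42):
    rng = np.random.default_rng(seed)
    R = np.eye(p)
    for i, j, r in pairs:
        R[i, j] = R[j, i] = r
    w = rng.uniform(0.5, 2.0, size=p)
    cov = np.sqrt(np.outer(w, w)) * R
    t = w[:, None] + w[None, :] - 2 * cov
    np.fill_diagonal(t, 0.0)
    return R, w, cov, t


class TestSparCC:
    def test_null_data_gives_small_correlations(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(
            np.exp(rng.normal(3, 1, size=(10, 1))), size=(10, 200)
        )
        est = SparCC(iterations=5, n_bootstrap=0, random_state=0).fit(counts.T)
        iu = np.triu_indices(10, k=1)
        assert np.median(np.abs(est.correlation_[iu])) < 0.15

    def test_noiseless_composition_recovery(self):
        """Basis correlations estimated from noiseless compositions match
        both the planted values and the direct t-system oracle."""
        R, w, cov, t_true = planted_basis()
        rng = np.random.default_rng(7)
        logb = exact_moment_log_basis(cov, 200, rng) + rng.normal(size=8)
        frac = np.exp(logb)
        frac /= frac.sum(axis=1, keepdims=True)
        t_hat = logratio_variance(np.log(frac).T)
        assert np.allclose(t_hat, t_true, atol=1e-10)
        rho_hat, _, _ = basis_correlations(t_hat)
        rho_oracle, _, _ = basis_correlations(t_true)
        iu = np.triu_indices(8, k=1)
        assert np.sqrt(np.mean((rho_hat[iu] - rho_oracle[iu]) ** 2)) < 0.05
        assert np.sqrt(np.mean((rho_hat[iu] - R[iu]) ** 2)) < 0.05

    def test_equal_latent_abundances_give_rho_one(self):
        rng = np.random.default_rng(2)
        lat = rng.normal(size=300)
        logb = np.vstack([lat, lat + 2.0, rng.normal(size=(4, 300))])
        frac = np.exp(logb)
        frac /= frac.sum(axis=0, keepdims=True)
        t = logratio_variance(np.log(frac))
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)
        rho, _, _ = basis_correlations(t)
        assert rho[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_compositional_invariance_small_pseudocount(self):
        """Scaling one sample's counts leaves basis correlations unchanged
        in the small-pseudocount limit."""
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 200, size=(6, 40))
        scaled = counts.copy()
        scaled[:, 0] *= 10
        a = SparCC(n_bootstrap=0, pseudocount=1e-9,
                   dirichlet_resampling=False).fit(counts.T)
        b = SparCC(n_bootstrap=0, pseudocount=1e-9,
                   dirichlet_resampling=False).fit(scaled.T)
        assert np.allclose(a.correlation_, b.correlation_, atol=1e-6)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            SparCC().fit(np.ones((10, 3)))

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 100, size=(30, 8))
        a = SparCC(iterations=3, n_bootstrap=10, random_state=9).fit(counts)
        b = SparCC(iterations=3, n_bootstrap=10, random_state=9).fit(counts)
        assert np.array_equal(a.correlation_, b.correlation_)
        assert np.array_equal(a.pvalues_, b.pvalues_)


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.arange(1.0, 11.0)
        X = np.column_stack([x, np.exp(x), x[::-1]])
        est = SpearmanNetwork().fit(X)
        assert est.correlation_[0, 1] == pytest.approx(1.0)
        assert est.correlation_[0, 2] == pytest.approx(-1.0)

    def test_six_point_example_matches_rank_formula(self):
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5], dtype=float)
        d2 = ((x - y) ** 2).sum()
        brute = 1 - 6 * d2 / (6 * (36 - 1))
        est = SpearmanNetwork().fit(np.column_stack([x, y]))
        assert est.correlation_[0, 1] == pytest.approx(brute)
        assert brute == pytest.approx(1 - 36 / 210)

    def test_constant_taxon_recorded_as_null(self):
        X = np.column_stack([np.arange(8.0), np.full(8, 3.0), np.arange(8.0)])
        est = SpearmanNetwork().fit(X)
        assert est.correlation_[0, 1] == 0.0
        assert est.pvalues_[0, 1] == 1.0

    def test_bh_q_at_least_p(self):
        rng = np.random.default_rng(11)
        est = SpearmanNetwork().fit(rng.normal(size=(25, 8)))
        iu = np.triu_indices(8, k=1)
        assert np.all(est.qvalues_[iu] >= est.pvalues_[iu] - 1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        X = rng.gamma(2, 1, size=(30, 5))
        a = SpearmanNetwork().fit(X).correlation_
        b = SpearmanNetwork().fit(np.log(X) ** 3 + 5).correlation_
        # log then odd cube is strictly monotone per taxon
        assert np.allclose(a, b, atol=1e-12)


def exhaustive_neighborhood_bic(X):
    """Best-subset neighborhood selection by BIC, OR-symmetrised."""
    n, p = X.shape
    adj = np.zeros((p, p), dtype=bool)
    for j in range(p):
        y = X[:, j] - X[:, j].mean()
        best_bic, best_set = np.inf, ()
        others = [k for k in range(p) if k != j]
        for r in range(len(others) + 1):
            for subset in itertools.combinations(others, r):
                if subset:
                    Z = X[:, subset] - X[:, subset].mean(axis=0)
                    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
                    rss = ((y - Z @ beta) ** 2).sum()
                else:
                    rss = (y ** 2).sum()
                bic = n * np.log(rss / n) + (r + 1) * np.log(n)
                if bic < best_bic:
                    best_bic, best_set = bic, subset
        for k in best_set:
            adj[j, k] = adj[k, j] = True
    return adj


class TestMBNeighborhood:
    CHAIN = {(0, 1), (1, 2), (2, 3), (3, 4)}

    @staticmethod
    def chain_data(seed, n=500):
        rng = np.random.default_rng(seed)
        omega = np.eye(5)
        for i in range(4):
            omega[i, i + 1] = omega[i + 1, i] = -0.4
        return rng.multivariate_normal(np.zeros(5), np.linalg.inv(omega), size=n)

    def test_chain_recovered_at_theoretical_penalty(self):
        """Neighborhood selection at lambda = 3*sqrt(log p / n) recovers the
        chain exactly in >= 90% of seeded runs."""
        lam = 3.0 * np.sqrt(np.log(5) / 500)
        hits = 0
        for seed in range(20):
            X = self.chain_data(seed)
            mb = MBNeighborhood(lambda_grid=[lam], random_state=seed).fit(X)
            edges = {
                (i, j) for i in range(5) for j in range(i + 1, 5)
                if mb.adjacency_[i, j]
            }
            hits += edges == self.CHAIN
        assert hits >= 18

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_chain_matches_exhaustive_subset_oracle(self, seed):
        """Exhaustive best-subset search and penalised neighborhood selection
        agree on the chain for identifiable draws."""
        X = self.chain_data(seed)
        oracle = exhaustive_neighborhood_bic(X)
        edges = {
            (i, j) for i in range(5) for j in range(i + 1, 5) if oracle[i, j]
        }
        assert edges == self.CHAIN
        lam = 3.0 * np.sqrt(np.log(5) / 500)
        mb = MBNeighborhood(lambda_grid=[lam], random_state=seed).fit(X)
        mb_edges = {
            (i, j) for i in range(5) for j in range(i + 1, 5)
            if mb.adjacency_[i, j]
        }
        assert mb_edges == edges

    def test_null_data_stays_sparse_under_stars(self):
        X = np.random.default_rng(1).normal(size=(300, 15))
        mb = MBNeighborhood(random_state=1).fit(X)
        density = mb.adjacency_.sum() / 2 / (15 * 14 / 2)
        assert density < 0.02

    def test_positive_dependence_gives_positive_sign(self):
        X = self.chain_data(3)
        lam = 3.0 * np.sqrt(np.log(5) / 500)
        mb = MBNeighborhood(lambda_grid=[lam], random_state=3).fit(X)
        for i, j in self.CHAIN:
            if mb.adjacency_[i, j]:
                assert mb.sign_[i, j] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            MBNeighborhood().fit(np.ones((5, 4)))


def _fake_inputs(p=4):
    """Hand-built method outputs over p taxa for consensus-rule tests."""
    rho_sp = np.eye(p)
    rho_se = np.eye(p)
    pv = np.ones((p, p)) - np.eye(p)
    qv = np.ones((p, p)) - np.eye(p)
    mb_adj = np.zeros((p, p), dtype=int)
    mb_sign = np.zeros((p, p))

    def set_pair(mat, i, j, v):
        mat[i, j] = mat[j, i] = v

    # (0,1): all three methods positive
    set_pair(rho_sp, 0, 1, 0.6); set_pair(pv, 0, 1, 0.001)
    set_pair(rho_se, 0, 1, 0.7); set_pair(qv, 0, 1, 0.001)
    set_pair(mb_adj, 0, 1, 1); set_pair(mb_sign, 0, 1, 1.0)
    # (0, 2): SparCC only
    set_pair(rho_sp, 0, 2, 0.5); set_pair(pv, 0, 2, 0.001)
    # (1, 2): SparCC positive, Spearman NEGATIVE, mb selected -> sign conflict
    set_pair(rho_sp, 1, 2, 0.5); set_pair(pv, 1, 2, 0.001)
    set_pair(rho_se, 1, 2, -0.7); set_pair(qv, 1, 2, 0.001)
    set_pair(mb_adj, 1, 2, 1); set_pair(mb_sign, 1, 2, 1.0)
    sp = SparccEstimate(rho_sp, np.ones(p), np.zeros((p, p)), 1, [], pv)
    se = CorrelationMatrix(rho_se, pv.copy(), qv)
    mb = MbGraph(mb_adj, 0.1, np.array([0.1]), None, np.zeros(1), mb_sign)
    taxa = [TaxonRecord(f"t{i}", "bacteria") for i in range(p)]
    return sp, se, mb, taxa


class TestBuildEnsemble:
    def test_full_support_included_with_count_3(self):
        sp, se, mb, taxa = _fake_inputs()
        net = build_ensemble(sp, se, mb, EnsembleConfig(), taxa)
        assert net.graph.has_edge("t0", "t1")
        assert net.graph["t0"]["t1"]["support_count"] == 3

    def test_single_method_excluded_at_min_support_2(self):
        sp, se, mb, taxa = _fake_inputs()
        net = build_ensemble(sp, se, mb, EnsembleConfig(), taxa)
        assert not net.graph.has_edge("t0", "t2")

    def test_sign_conflict_excluded(self):
        sp, se, mb, taxa = _fake_inputs()
        net = build_ensemble(sp, se, mb, EnsembleConfig(), taxa)
        assert not net.graph.has_edge("t1", "t2")

    def test_min_support_1_admits_single_method_edges(self):
        sp, se, mb, taxa = _fake_inputs()
        cfg = EnsembleConfig(consensus=ConsensusConfig(min_support=1))
        net = build_ensemble(sp, se, mb, cfg, taxa)
        assert net.graph.has_edge("t0", "t2")

    def test_isolated_nodes_dropped_but_reported(self):
        sp, se, mb, taxa = _fake_inputs()
        net = build_ensemble(sp, se, mb, EnsembleConfig(), taxa)
        assert "t3" not in net.graph
        assert "t3" in net.isolated_nodes

    def test_taxon_set_mismatch_rejected(self):
        sp, se, mb, taxa = _fake_inputs()
        with pytest.raises(ValueError):
            build_ensemble(sp, se, mb, EnsembleConfig(), taxa[:-1])


class TestEnsembleEndToEnd:
    def test_deterministic_under_seed(self, small_sim):
        _, _, sim = small_sim
        stacked = stack_tables(sim.table16, sim.table18)
        cfg = EnsembleConfig(
            sparcc=SparccConfig(iterations=3, n_bootstrap=20), seed=4
        )
        cfg.mb.stars_subsamples = 10
        a = EnsembleNetwork(cfg).fit(stacked).network_
        b = EnsembleNetwork(cfg).fit(stacked).network_
        assert set(a.graph.nodes) == set(b.graph.nodes)
        assert {frozenset(e) for e in a.graph.edges()} == {
            frozenset(e) for e in b.graph.edges()
        }
        for u, v, d in a.graph.edges(data=True):
            assert b.graph[u][v]["sparcc_rho"] == d["sparcc_rho"]

    def test_consensus_edges_all_positive(self, small_sim):
        _, _, sim = small_sim
        stacked = stack_tables(sim.table16, sim.table18)
        cfg = EnsembleConfig(
            sparcc=SparccConfig(iterations=3, n_bootstrap=20), seed=4
        )
        cfg.mb.stars_subsamples = 10
        net = EnsembleNetwork(cfg).fit(stacked).network_
        assert net.n_edges > 0
        for _, _, d in net.graph.edges(data=True):
            assert d["consensus_sign"] == "+"
            assert d["support_count"] >= 2
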