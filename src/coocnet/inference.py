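"""Ensemble co-occurrence network inference for compositional count data.

Three complementary methods are run on the stacked cross-domain table and
merged by a positive-sign consensus vote:

* SparCC basis correlations: estimates correlations of latent (basis)
  abundances from log-ratio variances t_ij = Var[log(x_i/x_j)], solving the
  approximate linear system for basis variances w_i and setting
  rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), with iterative exclusion
  of the strongest-correlated pairs. Significance comes from a permutation
  ("bootstrap") pseudo p-value.
* Spearman rank correlation on relative abundances with Benjamini-Hochberg
  adjustment.
* Meinshausen-Buhlmann neighborhood selection: per-taxon L1-penalised
  regression of its CLR profile on all others, penalty chosen by StARS
  (edge-selection instability across subsamples), OR-symmetrised.

An edge enters the consensus network when at least ``min_support`` methods
select it and every supporting method assigns it a positive sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable, CooccurrenceNetwork, TaxonRecord
from .preprocess import CLRTransformer


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SparccConfig:
    iterations: int = 20
    exclusion_threshold: float = 0.8
    exclusion_rounds: int = 10
    n_bootstrap: int = 100
    pseudo_p_cut: float = 0.05
    rho_cut: float = 0.3
    pseudocount: float = 1.0


@dataclass
class SpearmanConfig:
    rho_cut: float = 0.5
    q_cut: float = 0.01


@dataclass
class MbConfig:
    lambda_grid: list[float] | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_subsamples: int = 50
    stars_beta: float = 0.05
    subsample_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.stars_beta < 0.5:
            raise ValueError("stars_beta must be in (0, 0.5)")


@dataclass
class ConsensusConfig:
    min_support: int = 2
    positive_only: bool = True
    combine: str = "vote"          # "vote" or "average"
    average_cut: float = 0.4

    def __post_init__(self) -> None:
        if self.min_support not in (1, 2, 3):
            raise ValueError("min_support must be 1, 2 or 3")
        if self.combine not in ("vote", "average"):
            raise ValueError("combine must be 'vote' or 'average'")


@dataclass
class EnsembleConfig:
    sparcc: SparccConfig = field(default_factory=SparccConfig)
    spearman: SpearmanConfig = field(default_factory=SpearmanConfig)
    mb: MbConfig = field(default_factory=MbConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    seed: int = 0


# --------------------------------------------------------------------------
# SparCC
# --------------------------------------------------------------------------

def basis_correlations(
    t: np.ndarray,
    exclusion_threshold: float = 0.8,
    exclusion_rounds: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Solve the basis system for one log-ratio variance matrix.

    Returns (rho, basis variances, excluded pairs). The approximation
    assumes the average basis correlation is small, giving the linear
    system M w = t_rowsums with M = (p - 2) I + J; strongly correlated
    pairs violate the assumption and are excluded and the system re-solved.
    """
    p = t.shape[0]
    if p < 4:
        raise ValueError("basis system needs at least 4 taxa")
    M = np.ones((p, p)) + np.eye(p) * (p - 2)
    t_rowsum = t.sum(axis=1)
    excluded: list[tuple[int, int]] = []

    def solve() -> np.ndarray:
        w = np.linalg.solve(M, t_rowsum)
        return np.clip(w, 1e-12, None)

    def rho_from(w: np.ndarray) -> np.ndarray:
        sw = np.sqrt(w)
        rho = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(sw, sw))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho

    w = solve()
    rho = rho_from(w)
    for _ in range(exclusion_rounds):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # a node reduced to < 3 remaining partners makes the system fragile
        if M[i, i] <= 3 or M[j, j] <= 3:
            break
        excluded.append((int(i), int(j)))
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] -= 1
        M[j, i] -= 1
        t_rowsum[i] -= t[i, j]
        t_rowsum[j] -= t[i, j]
        try:
            w = solve()
        except np.linalg.LinAlgError:
            warnings.warn("singular exclusion-reduced system; keeping previous fit")
            break
        rho = rho_from(w)
    return rho, w, excluded


def logratio_variance(log_fracs: np.ndarray) -> np.ndarray:
    """t_ij = Var[log(x_i / x_j)] from taxa x samples log fractions."""
    cov = np.cov(log_fracs)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


class SparCC(BaseEstimator):
    """SparCC basis-correlation estimator (samples x taxa count input).

    ``fit`` averages (median) basis correlations over ``iterations``
    Dirichlet resamplings of the sample compositions, then attaches a
    permutation pseudo p-value per pair obtained by independently permuting
    each taxon's counts across samples.
    """

    def __init__(
        self,
        iterations: int = 20,
        exclusion_threshold: float = 0.8,
        exclusion_rounds: int = 10,
        n_bootstrap: int = 100,
        pseudocount: float = 1.0,
        dirichlet_resampling: bool = True,
        blocks: list | None = None,
        random_state: int = 0,
    ):
        self.iterations = iterations
        self.exclusion_threshold = exclusion_threshold
        self.exclusion_rounds = exclusion_rounds
        self.n_bootstrap = n_bootstrap
        self.pseudocount = pseudocount
        self.dirichlet_resampling = dirichlet_resampling
        self.blocks = blocks
        self.random_state = random_state

    def _rho_once(self, counts_tn: np.ndarray, rng: np.random.Generator | None):
        """One basis solve; Dirichlet-resampled fractions when rng given.

        Fractions are closed within each marker block (each block is its own
        sequencing library); log-ratios across blocks are then library-free.
        """
        blocks = self.blocks or [np.arange(counts_tn.shape[0])]
        fr = np.empty(counts_tn.shape)
        for rows in blocks:
            sub = counts_tn[rows, :]
            if rng is None:
                f = sub + self.pseudocount
                fr[rows, :] = f / f.sum(axis=0, keepdims=True)
            else:
                for s in range(sub.shape[1]):
                    fr[rows, s] = rng.dirichlet(sub[:, s] + self.pseudocount)
        t = logratio_variance(np.log(fr))
        rho, w, excl = basis_correlations(
            t, self.exclusion_threshold, self.exclusion_rounds
        )
        return rho, w, excl, t

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        counts = X.T  # internal layout: taxa x samples
        p, n = counts.shape
        if p < 4:
            raise ValueError("SparCC needs at least 4 taxa")
        rng = np.random.default_rng(self.random_state)

        rhos, ws = [], []
        excluded = []
        t_last = None
        draw_rng = rng if self.dirichlet_resampling else None
        for _ in range(max(1, self.iterations) if self.dirichlet_resampling else 1):
            rho, w, excl, t_last = self._rho_once(counts, draw_rng)
            rhos.append(rho)
            ws.append(w)
            excluded = excl
        self.correlation_ = np.median(rhos, axis=0)
        np.fill_diagonal(self.correlation_, 1.0)
        self.variances_ = np.median(ws, axis=0)
        self.tmatrix_ = t_last
        self.excluded_pairs_ = excluded
        self.n_iterations_ = max(1, self.iterations)

        if self.n_bootstrap > 0:
            obs = np.abs(self.correlation_)
            exceed = np.zeros((p, p))
            for _ in range(self.n_bootstrap):
                perm = np.empty_like(counts)
                for i in range(p):
                    perm[i] = rng.permutation(counts[i])
                rho_b, _, _, _ = self._rho_once(perm, None)
                exceed += np.abs(rho_b) >= obs
            self.pvalues_ = (1.0 + exceed) / (self.n_bootstrap + 1.0)
            np.fill_diagonal(self.pvalues_, 0.0)
        else:
            self.pvalues_ = np.zeros((p, p))
        return self


@dataclass
class SparccEstimate:
    """Functional-interface view of a fitted SparCC model."""

    rho: np.ndarray
    omega2: np.ndarray
    t_matrix: np.ndarray
    n_iterations: int
    excluded_pairs: list[tuple[int, int]]
    pvalues: np.ndarray


def sparcc(table: AbundanceTable, config: EnsembleConfig | None = None) -> SparccEstimate:
    cfg = (config or EnsembleConfig()).sparcc
    seed = (config or EnsembleConfig()).seed
    est = SparCC(
        iterations=cfg.iterations,
        exclusion_threshold=cfg.exclusion_threshold,
        exclusion_rounds=cfg.exclusion_rounds,
        n_bootstrap=cfg.n_bootstrap,
        pseudocount=cfg.pseudocount,
        random_state=seed,
    ).fit(table.counts.T)
    return SparccEstimate(
        est.correlation_, est.variances_, est.tmatrix_,
        est.n_iterations_, est.excluded_pairs_, est.pvalues_,
    )


# --------------------------------------------------------------------------
# Spearman
# --------------------------------------------------------------------------

class SpearmanNetwork(BaseEstimator):
    """Pairwise Spearman correlation with BH adjustment (samples x taxa)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError("Spearman needs at least 3 samples")
        # Pearson correlation of column ranks; constant columns have zero
        # rank variance and are recorded as no association (rho 0, p 1)
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        sd = ranks.std(axis=0)
        ok = sd > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = np.corrcoef(ranks, rowvar=False)
        rho = np.where(np.outer(ok, ok), rho, 0.0)
        rho = np.nan_to_num(rho, nan=0.0)
        np.fill_diagonal(rho, 1.0)
        # two-sided p from the t approximation (scipy's convention)
        r = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        pval = np.where(np.abs(r) >= 1.0, 0.0, pval)
        pval = np.where(np.outer(ok, ok), pval, 1.0)
        np.fill_diagonal(pval, 0.0)

        iu = np.triu_indices(p, k=1)
        q = np.ones((p, p))
        if iu[0].size:
            _, qflat, _, _ = multipletests(pval[iu], method="fdr_bh")
            q[iu] = qflat
            q.T[iu] = qflat
        np.fill_diagonal(q, 0.0)
        self.correlation_ = rho
        self.pvalues_ = pval
        self.qvalues_ = q
        return self


@dataclass
class CorrelationMatrix:
    rho: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray


def spearman_network(
    table: AbundanceTable, config: EnsembleConfig | None = None
) -> CorrelationMatrix:
    from .preprocess import relative_abundance

    rel = relative_abundance(table)
    est = SpearmanNetwork().fit(rel.T)
    return CorrelationMatrix(est.correlation_, est.pvalues_, est.qvalues_)


# --------------------------------------------------------------------------
# Meinshausen-Buhlmann neighborhood selection with StARS
# --------------------------------------------------------------------------

class MBNeighborhood(BaseEstimator):
    """Sparse neighborhood selection on CLR-scale data (samples x taxa).

    For each taxon, a lasso regression of its profile on all others is run
    along a shared penalty grid; the penalty is chosen by StARS: the
    densest grid point whose monotonised edge-selection instability across
    subsamples stays at or below ``stars_beta``. Neighborhoods are
    OR-symmetrised and edge signs taken from the larger-magnitude
    coefficient of the pair.
    """

    def __init__(
        self,
        lambda_grid: list[float] | None = None,
        n_lambda: int = 20,
        lambda_min_ratio: float = 0.01,
        stars_subsamples: int = 50,
        stars_beta: float = 0.05,
        subsample_fraction: float = 0.8,
        random_state: int = 0,
    ):
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.stars_subsamples = stars_subsamples
        self.stars_beta = stars_beta
        self.subsample_fraction = subsample_fraction
        self.random_state = random_state

    @staticmethod
    def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd = X.std(axis=0, ddof=0)
        ok = sd > 0
        Z = np.zeros_like(X)
        Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
        return Z, ok

    def _selection_stack(self, Z: np.ndarray, ok: np.ndarray,
                         grid: np.ndarray) -> np.ndarray:
        """Coefficient support per (lambda, i, j); OR-symmetrised."""
        n, p = Z.shape
        sel = np.zeros((len(grid), p, p), dtype=bool)
        idx = np.arange(p)
        for j in range(p):
            if not ok[j]:
                continue
            others = idx[(idx != j) & ok]
            if others.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = lasso_path(
                    Z[:, others], Z[:, j], alphas=grid, max_iter=2000
                )
            nz = coefs != 0  # (n_others, n_lambda)
            for k in range(len(grid)):
                sel[k, j, others] |= nz[:, k]
        return sel | sel.transpose(0, 2, 1)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 10:
            raise ValueError("neighborhood selection needs at least 10 samples")
        rng = np.random.default_rng(self.random_state)
        Z, ok = self._standardize(X)
        if not ok.all():
            warnings.warn("constant columns excluded from neighborhood selection")

        if self.lambda_grid is not None:
            grid = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
        else:
            gram = np.abs(Z.T @ Z) / n
            np.fill_diagonal(gram, 0.0)
            lam_max = max(gram.max(), 1e-3)
            grid = np.logspace(
                np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio),
                self.n_lambda,
            )
        self.lambda_grid_ = grid

        if len(grid) == 1:
            # degenerate grid: no stability selection needed
            self.lambda_selected_ = float(grid[0])
            self.stability_path_ = None
            self.instability_path_ = np.zeros(1)
            sel_full = self._selection_stack(Z, ok, grid)
            self.adjacency_ = sel_full[0].astype(int)
            np.fill_diagonal(self.adjacency_, 0)
            self._attach_signs(Z, ok)
            return self

        b = max(int(np.floor(self.subsample_fraction * n)), 10)
        freq = np.zeros((len(grid), p, p))
        for _ in range(self.stars_subsamples):
            rows = rng.choice(n, size=b, replace=False)
            Zs, oks = self._standardize(X[rows])
            freq += self._selection_stack(Zs, oks & ok, grid)
        freq /= self.stars_subsamples

        iu = np.triu_indices(p, k=1)
        n_pairs = iu[0].size
        inst = np.array([
            (2.0 * freq[k][iu] * (1.0 - freq[k][iu])).sum() / n_pairs
            for k in range(len(grid))
        ])
        self.stability_path_ = freq[:, iu[0], iu[1]]
        self.instability_path_ = inst

        # grid runs sparse -> dense; pick densest lambda whose running-max
        # (supremum over sparser lambdas) instability stays <= beta
        running = np.maximum.accumulate(inst)
        feasible = np.flatnonzero(running <= self.stars_beta)
        k_sel = int(feasible[-1]) if feasible.size else 0
        self.lambda_selected_ = float(grid[k_sel])

        sel_full = self._selection_stack(Z, ok, grid)
        self.adjacency_ = sel_full[k_sel].astype(int)
        np.fill_diagonal(self.adjacency_, 0)
        self._attach_signs(Z, ok)
        return self

    def _attach_signs(self, Z: np.ndarray, ok: np.ndarray) -> None:
        """Edge sign = sign of the larger-magnitude coefficient of the pair."""
        p = Z.shape[1]
        signs = np.zeros((p, p))
        mags = np.zeros((p, p))
        idx = np.arange(p)
        for j in range(p):
            if not ok[j]:
                continue
            others = idx[(idx != j) & ok]
            if others.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = lasso_path(
                    Z[:, others], Z[:, j],
                    alphas=[self.lambda_selected_], max_iter=2000,
                )
            c = coefs[:, 0]
            signs[j, others] = np.sign(c)
            mags[j, others] = np.abs(c)
        use_ji = mags.T > mags
        final_sign = np.where(use_ji, signs.T, signs)
        sign = np.where(self.adjacency_ > 0, final_sign, 0.0)
        # fall back to the partner's sign when one direction is zero
        self.sign_ = np.where(sign == 0, sign.T, sign)


@dataclass
class MbGraph:
    adjacency: np.ndarray
    lambda_selected: float
    lambda_grid: np.ndarray
    stability_path: np.ndarray
    instability_path: np.ndarray
    sign_estimates: np.ndarray


def mb_neighborhood(
    table: AbundanceTable, config: EnsembleConfig | None = None
) -> MbGraph:
    cfg = (config or EnsembleConfig()).mb
    seed = (config or EnsembleConfig()).seed
    clr = CLRTransformer().fit_transform(table.counts.T).T
    est = MBNeighborhood(
        lambda_grid=cfg.lambda_grid,
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
        stars_subsamples=cfg.stars_subsamples,
        stars_beta=cfg.stars_beta,
        subsample_fraction=cfg.subsample_fraction,
        random_state=seed,
    ).fit(clr.T)
    return MbGraph(
        est.adjacency_, est.lambda_selected_, est.lambda_grid_,
        est.stability_path_, est.instability_path_, est.sign_,
    )


# --------------------------------------------------------------------------
# consensus
# --------------------------------------------------------------------------

def build_ensemble(
    sparcc_est: SparccEstimate,
    spear: CorrelationMatrix,
    mb: MbGraph,
    config: EnsembleConfig,
    taxa: list[TaxonRecord],
) -> CooccurrenceNetwork:
    """Merge the three method outputs into the positive consensus network.

    Vote mode (default): an edge needs >= ``min_support`` supporting methods
    and, with ``positive_only``, unanimous positive sign among supporters.
    Average mode: the mean of the per-method association scores (SparCC rho,
    Spearman rho, signed 0/1 selection for neighborhood selection) must
    exceed ``average_cut``.
    Nodes left without edges are dropped from the graph but recorded.
    """
    p = len(taxa)
    for mat in (sparcc_est.rho, spear.rho, mb.adjacency):
        if mat.shape != (p, p):
            raise ValueError("method outputs disagree with the taxon set")
    cc = config.consensus
    scc, spc = config.sparcc, config.spearman

    sp_sup = (np.abs(sparcc_est.rho) >= scc.rho_cut) & (
        sparcc_est.pvalues < scc.pseudo_p_cut
    )
    se_sup = (np.abs(spear.rho) >= spc.rho_cut) & (spear.qvals < spc.q_cut)
    mb_sup = mb.adjacency > 0

    import networkx as nx

    g = nx.Graph()
    ids = [t.taxon_id for t in taxa]
    for t in taxa:
        g.add_node(
            t.taxon_id, domain_label=t.domain_label, family=t.family
        )

    for i in range(p):
        for j in range(i + 1, p):
            methods = []
            signs = []
            if sp_sup[i, j]:
                methods.append("sparcc")
                signs.append(np.sign(sparcc_est.rho[i, j]))
            if se_sup[i, j]:
                methods.append("spearman")
                signs.append(np.sign(spear.rho[i, j]))
            if mb_sup[i, j]:
                methods.append("mb")
                signs.append(mb.sign_estimates[i, j] or 1.0)

            if cc.combine == "vote":
                if len(methods) < cc.min_support:
                    continue
                if cc.positive_only and any(s <= 0 for s in signs):
                    continue
            else:  # average of per-method association scores
                score = (
                    sparcc_est.rho[i, j]
                    + spear.rho[i, j]
                    + (mb.sign_estimates[i, j] if mb_sup[i, j] else 0.0)
                ) / 3.0
                if score < cc.average_cut:
                    continue
                if not methods:
                    continue
            g.add_edge(
                ids[i], ids[j],
                support_count=max(1, len(methods)),
                methods=",".join(methods),
                sparcc_rho=float(sparcc_est.rho[i, j]),
                spearman_rho=float(spear.rho[i, j]),
                mb_selected=int(mb_sup[i, j]),
                consensus_sign="+",
            )

    isolated = [v for v in list(g.nodes) if g.degree(v) == 0]
    g.remove_nodes_from(isolated)
    net = CooccurrenceNetwork(g)
    net.isolated_nodes = isolated
    return net


class EnsembleNetwork(BaseEstimator):
    """End-to-end ensemble inference on a stacked cross-domain table."""

    def __init__(self, config: EnsembleConfig | None = None):
        self.config = config

    def fit(self, table: AbundanceTable, y=None):
        cfg = self.config or EnsembleConfig()
        self.sparcc_ = sparcc(table, cfg)
        self.spearman_ = spearman_network(table, cfg)
        self.mb_ = mb_neighborhood(table, cfg)
        self.network_ = build_ensemble(
            self.sparcc_, self.spearman_, self.mb_, cfg, table.taxa
        )
        self.isolated_nodes_ = self.network_.isolated_nodes
        return self


def infer_network(
    table: AbundanceTable, config: EnsembleConfig | None = None
) -> CooccurrenceNetwork:
    return EnsembleNetwork(config).fit(table).network_
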