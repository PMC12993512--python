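"""Synthetic paired 16S/18S data with a planted cross-domain network.

The generator follows a logistic-normal-multinomial model: latent
log-abundances are drawn from a multivariate normal whose precision matrix
has the planted network as its sparsity pattern, an environmental gradient
shifts a subset of taxa, latent values are closed to compositions and reads
are drawn multinomially per sample. This gives a well-defined ground truth
(edges, hubs, latent correlations) for every downstream inference stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AbundanceTable, SampleMetadata, TaxonRecord


@dataclass
class SimulationConfig:
    """Study-scale defaults: a moderate cross-domain community.

    60 taxa (40 bacteria, 14 phototrophs, 6 fungi), 150 paired samples,
    planted edge density 0.05 with 3 hub (keystone) taxa, library sizes
    20k-80k reads (the order of magnitude of typical amplicon libraries).
    """

    p_bacteria: int = 40
    p_phototroph: int = 14
    p_fungus: int = 6
    n_samples: int = 150
    depth_range: tuple[int, int] = (20_000, 80_000)
    n_hubs: int = 3
    edge_density: float = 0.05
    gradient_strength: float = 1.0
    gradient_fraction: float = 0.25
    precision_weight_range: tuple[float, float] = (0.6, 0.9)
    precision_diag_slack: float = 0.1
    latent_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.p_bacteria, self.p_phototroph, self.p_fungus) <= 0:
            raise ValueError("taxon counts must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ValueError("depth_range must satisfy 0 < min <= max")
        if self.n_hubs < 0 or self.n_hubs > self.p_total:
            raise ValueError("n_hubs must be between 0 and the taxon count")

    @property
    def p_total(self) -> int:
        return self.p_bacteria + self.p_phototroph + self.p_fungus


@dataclass
class PlantedNetwork:
    """Ground-truth interaction structure behind a simulation."""

    adjacency: np.ndarray          # symmetric binary, zero diagonal
    signs: np.ndarray              # +1 on planted edges (positive regime)
    hub_ids: list[str]
    taxon_ids: list[str]
    domain_labels: list[str]
    precision_matrix: np.ndarray

    def edge_set(self) -> set[tuple[str, str]]:
        p = len(self.taxon_ids)
        return {
            tuple(sorted((self.taxon_ids[i], self.taxon_ids[j])))
            for i in range(p)
            for j in range(i + 1, p)
            if self.adjacency[i, j]
        }


@dataclass
class SimulationResult:
    table16: AbundanceTable
    table18: AbundanceTable
    metadata: list[SampleMetadata]
    network: PlantedNetwork
    latent: np.ndarray = field(repr=False)      # taxa x samples log-abundances
    gradient: np.ndarray = field(repr=False)    # per-sample gradient value
    depths16: np.ndarray | None = field(default=None, repr=False)
    depths18: np.ndarray | None = field(default=None, repr=False)


def _taxon_labels(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, domains = [], []
    for i in range(config.p_bacteria):
        ids.append(f"ASV{i + 1:04d}")
        domains.append("bacteria")
    for i in range(config.p_phototroph):
        ids.append(f"OTU{i + 1:04d}")
        domains.append("phototroph")
    for i in range(config.p_fungus):
        ids.append(f"OTU{config.p_phototroph + i + 1:04d}")
        domains.append("fungus")
    return ids, domains


def plant_network(config: SimulationConfig) -> PlantedNetwork:
    """Build the planted graph and a certifiably-PD precision matrix.

    Three blocks (bacteria-rich, phototroph-rich, mixed fungal/bacterial)
    receive most edges; cross-block edges guarantee at least one
    bacteria-phototroph and one phototroph-fungus association. Hub nodes
    gain extra partners until their degree is at least three times the
    median degree. Precision off-diagonals are negative (-weight) so that
    planted edges correspond to positive partial correlations; the diagonal
    is set to the absolute row sum + 0.5, which makes the matrix strictly
    diagonally dominant and hence positive definite.
    """
    rng = np.random.default_rng(config.seed)
    p = config.p_total
    ids, domains = _taxon_labels(config)
    b = np.array([d == "bacteria" for d in domains])
    ph = np.array([d == "phototroph" for d in domains])
    fu = np.array([d == "fungus" for d in domains])

    # mixed block: all fungi plus a slice of bacteria
    n_mix_bact = max(2, config.p_bacteria // 5)
    blocks = np.zeros(p, dtype=int)
    blocks[ph] = 1
    blocks[fu] = 2
    bact_idx = np.flatnonzero(b)
    blocks[bact_idx[-n_mix_bact:]] = 2

    target_edges = int(round(config.edge_density * p * (p - 1) / 2))
    if target_edges < config.n_hubs:
        raise ValueError("edge density too low for the requested hub count")

    adj = np.zeros((p, p), dtype=bool)

    def add_edge(i: int, j: int) -> None:
        if i != j:
            adj[i, j] = adj[j, i] = True

    # guaranteed cross-domain edges
    add_edge(int(rng.choice(np.flatnonzero(b))), int(rng.choice(np.flatnonzero(ph))))
    add_edge(int(rng.choice(np.flatnonzero(ph))), int(rng.choice(np.flatnonzero(fu))))

    # fill remaining edges, 80% within blocks, 20% across
    guard = 0
    while adj.sum() // 2 < target_edges and guard < 100_000:
        guard += 1
        if rng.random() < 0.8:
            blk = int(rng.integers(0, 3))
            members = np.flatnonzero(blocks == blk)
            if len(members) < 2:
                continue
            i, j = rng.choice(members, size=2, replace=False)
        else:
            i, j = rng.choice(p, size=2, replace=False)
        add_edge(int(i), int(j))

    # hubs: highest-degree candidates boosted to >= 3x median degree
    hub_idx = list(rng.choice(p, size=config.n_hubs, replace=False))
    for h in hub_idx:
        med = max(1.0, float(np.median(adj.sum(axis=1))))
        want = int(np.ceil(3 * med))
        partners = [i for i in range(p) if i != h and not adj[h, i]]
        rng.shuffle(partners)
        while adj[h].sum() < want and partners:
            add_edge(h, partners.pop())

    weights = rng.uniform(*config.precision_weight_range, size=(p, p))
    weights = (weights + weights.T) / 2
    omega = np.zeros((p, p))
    omega[adj] = -weights[adj]
    np.fill_diagonal(
        omega, np.abs(omega).sum(axis=1) + config.precision_diag_slack
    )

    # strict diagonal dominance => PD; verify anyway (cheap, certifies truth)
    np.linalg.cholesky(omega)

    return PlantedNetwork(
        adjacency=adj.astype(int),
        signs=adj.astype(int),
        hub_ids=[ids[h] for h in sorted(hub_idx)],
        taxon_ids=ids,
        domain_labels=domains,
        precision_matrix=omega,
    )


def planted_correlation(net: PlantedNetwork) -> np.ndarray:
    """Latent correlation matrix implied by the planted precision matrix."""
    cov = np.linalg.inv(net.precision_matrix)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def simulate_counts(
    net: PlantedNetwork, config: SimulationConfig
) -> SimulationResult:
    """Draw paired count tables from the logistic-normal-multinomial model."""
    rng = np.random.default_rng(config.seed + 1)
    p, n = len(net.taxon_ids), config.n_samples
    # latent covariance is the inverse planted precision (the graphical
    # model's own marginals, heterogeneous variances included), with an
    # overall dispersion multiplier
    cov = np.linalg.inv(net.precision_matrix) * config.latent_sd ** 2

    base_mu = rng.normal(0.0, 1.0, size=p)
    latent = rng.multivariate_normal(base_mu, cov, size=n, method="cholesky").T

    # environmental gradient shifts a taxon subset
    gradient = rng.normal(0.0, 1.0, size=n)
    n_grad = int(round(config.gradient_fraction * p))
    grad_taxa = rng.choice(p, size=n_grad, replace=False)
    loadings = rng.uniform(0.5, 1.0, size=n_grad) * rng.choice([-1, 1], size=n_grad)
    if config.gradient_strength != 0:
        latent[grad_taxa, :] += (
            config.gradient_strength * np.outer(loadings, gradient)
        )

    comp = np.exp(latent - latent.max(axis=0, keepdims=True))
    comp /= comp.sum(axis=0, keepdims=True)

    # one multinomial draw per sample over the joint composition; the two
    # marker tables are row splits of the same draw (their column sums are
    # the realised per-marker read totals)
    labels = np.array(net.domain_labels)
    is16 = labels == "bacteria"
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    counts = np.empty((p, n), dtype=np.int64)
    for s in range(n):
        counts[:, s] = rng.multinomial(depths[s], comp[:, s])
    depths16 = counts[is16, :].sum(axis=0)
    depths18 = counts[~is16, :].sum(axis=0)

    sample_ids = [f"S{s + 1:04d}" for s in range(n)]
    taxa = [
        TaxonRecord(str(tid), str(dom), (), "unclassified")
        for tid, dom in zip(net.taxon_ids, labels)
    ]
    t16 = AbundanceTable(
        counts[is16], [t for t, k in zip(taxa, is16) if k], sample_ids, "16S"
    )
    t18 = AbundanceTable(
        counts[~is16], [t for t, k in zip(taxa, is16) if not k], sample_ids, "18S"
    )

    # design labels tied to the gradient (noisy threshold), floodplain random
    noise = rng.normal(0.0, 0.5, size=n)
    stream = np.where(gradient + noise > 0, "GFS", "TRIB")
    degl = np.where(
        gradient + rng.normal(0.0, 0.5, size=n) > 0, "pre2000", "post2000"
    )
    floodplain = rng.choice(["Otemma", "ValRoseg"], size=n)
    meta = []
    for s in range(n):
        g = gradient[s]
        env = {
            "gradient": float(g),
            "temperature": float(4.0 + 2.0 * g + rng.normal(0, 0.5)),
            "conductivity": float(np.exp(4.0 + 0.5 * g + rng.normal(0, 0.2))),
            "ph": float(7.5 + 0.2 * g + rng.normal(0, 0.1)),
            "turbidity": float(np.exp(1.0 - 0.8 * g + rng.normal(0, 0.3))),
            "doc": float(np.exp(0.5 + 0.3 * g + rng.normal(0, 0.2))),
        }
        meta.append(
            SampleMetadata(
                sample_id=sample_ids[s],
                floodplain=str(floodplain[s]),
                stream_type=str(stream[s]),
                deglaciation=str(degl[s]),
                environment=env,
            )
        )
    result = SimulationResult(
        t16, t18, meta, net, latent, gradient, depths16, depths18
    )
    result.depths = depths
    return result


def simulate(config: SimulationConfig) -> SimulationResult:
    """Convenience: plant the network and draw counts in one call."""
    return simulate_counts(plant_network(config), config)
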