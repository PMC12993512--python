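# coocnet

Cross-domain co-occurrence network analysis for paired 16S/18S amplicon
count tables, built for stream-biofilm microbiome studies where bacteria,
eukaryotic phototrophs (algae, diatoms) and fungi interact within one
community. The package answers three questions about such communities:
which taxa co-occur across domains, which taxa hold the network together
(keystones), and how much of the bacterial community composition those
keystones — versus the environment — can explain.

## What it computes

**Consensus networks.** Co-occurrence is inferred on the stacked
16S + 18S table by an ensemble of three methods, each on its native input:

- *SparCC* basis correlations from log-ratio variances
  t_ij = Var[log(x_i/x_j)]: solve the linear system for basis variances
  ω_i² and set ρ_ij = (ω_i² + ω_j² − t_ij) / (2 ω_i ω_j), with iterative
  exclusion of the strongest pairs and a permutation pseudo p-value;
- *Spearman* rank correlation on relative abundances with
  Benjamini–Hochberg adjustment;
- *Meinshausen–Bühlmann neighborhood selection*: per-taxon L1-penalised
  regression of its CLR profile on all others, penalty λ chosen by StARS
  (edge-selection instability across subsamples, target β = 0.05),
  OR-symmetrised.

An edge enters the consensus network when at least two methods support it
and all supporting methods agree on a positive sign — only unambiguous
positive co-occurrence is analysed.

**Stability under keystone removal.** Communities come from Louvain
modularity optimisation (clusters under five nodes pruned); keystones are
the top-10 nodes by joint degree + betweenness rank-sum; fragmentation
f = (number of disconnected subgraphs) / (number of nodes) is tracked as
keystones are removed one at a time.

**Variance partitioning.** Distance-based redundancy analysis (db-RDA) on
Wisconsin-standardised Bray–Curtis dissimilarities, with ordistep-style
forward selection of constraints by permutation tests (p ≤ 0.01, 999
permutations), compares the bacterial community variance explained by
bacterial keystones, eukaryotic keystones, and log-standardised
environmental variables.

A synthetic-data module generates paired count tables from a planted
sparse interaction network (logistic-normal-multinomial model, designated
hub taxa, environmental gradient), so the whole chain is testable without
any sequencing data. See `docs/methods.md` for the models, parameters and
design choices.

## Worked example

```python
from coocnet import (SimulationConfig, plant_network, simulate_counts,
                     stack_tables, EnsembleConfig, infer_network,
                     louvain_communities, topology, centrality,
                     select_keystones, removal_trajectory)

cfg = SimulationConfig(seed=7)                 # 60 taxa, 150 samples, 3 hubs
net = plant_network(cfg)
sim = simulate_counts(net, cfg)
graph = infer_network(stack_tables(sim.table16, sim.table18),
                      EnsembleConfig(seed=7))
part = louvain_communities(graph, min_size=5, seed=7)
topo = topology(graph, part)
print(f"consensus network: {topo.n_nodes} nodes, {topo.n_edges} edges, "
      f"{topo.n_clusters} clusters, Q = {topo.modularity:.3f}")
ks = select_keystones(centrality(graph), k=10)
print("keystones:", ", ".join(ks.keystones[:5]), "...")
print("planted hubs:", ", ".join(net.hub_ids))
traj = removal_trajectory(graph, ks, seed=7)
print(f"baseline f = {traj.baseline_f:.3f}, "
      f"f_mean after removals = {traj.f_mean:.3f}")
```

prints

```
consensus network: 56 nodes, 90 edges, 5 clusters, Q = 0.656
keystones: ASV0033, ASV0036, OTU0003, ASV0032, ASV0034 ...
planted hubs: ASV0008, ASV0033, OTU0014
baseline f = 0.036, f_mean after removals = 0.108
```

The inferred consensus network retains 56 of the 60 simulated taxa in a
strongly modular graph (Q = 0.66). The keystone list is led by ASV0033 —
one of the three planted hub taxa. Removing the ten keystones triples the
mean fragmentation relative to baseline (0.036 → 0.108): the network falls
apart when its central taxa are deleted, which is precisely the stability
property the analysis quantifies.

The same chain is available from the shell:

```bash
coocnet simulate --outdir data/ --seed 7
coocnet run --outdir results/ --seed 7          # full stratified pipeline
coocnet infer --table16 data/table16.tsv --table18 data/table18.tsv \
    --taxonomy16 data/taxonomy16.tsv --taxonomy18 data/taxonomy18.tsv \
    --metadata data/metadata.tsv --seed 7 --out network.graphml
```

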