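# Methods

`coocnet` rebuilds, as a tested pipeline, the cross-domain co-occurrence
analysis used for proglacial stream biofilms: paired 16S (bacteria) and 18S
(eukaryotic phototrophs and fungi) count tables are filtered, a consensus
positive co-occurrence network is inferred per study stratum with a
three-method ensemble, the network's community structure and stability
against keystone removal are characterised, and db-RDA quantifies how much
bacterial community variance keystone taxa explain relative to the
environment. This note documents the models, the tunable parameters, and
the design choices where the procedure was genuinely open.

## Data model and preprocessing

Count tables are taxa x samples integer matrices, never rarefied. 18S taxa
are assigned to `phototroph` or `fungus` by a keyword map on the lineage
(fungal phyla: Chytridiomycota, Cryptomycota, Zoopagomycota, Dikarya,
Ascomycota, Basidiomycota; phototroph clades: Chlorophyta, Charophyta /
Phragmoplastophyta, Cryptomonadales, Ochrophyta incl. Diatomea,
Chrysophyceae, Xanthophyceae); the map is a module-level constant and is
deliberately editable, because no closed-form rule exists for "phototroph".
Unmatched 18S lineages are labelled `unknown` and retained. Non-bacterial
16S reads (archaea, chloroplast, mitochondria keywords) are dropped at read
time. Only samples with both markers and consistent stream-type
categorisation across campaigns are analysed; tables are column-aligned
after pairing.

Filters: taxa observed in fewer than 5% of samples are discarded
(strictly-below dropped, equality retained — retention counts are sensitive
to this boundary, so it is fixed and tested); singletons (total count 1) and
taxa detected in a single sample are removed. The prevalence filter is
applied to both markers by default (`prevalence_on_18s` exempts the 18S
table). Wisconsin double standardisation (taxa scaled by their maxima, then
samples by their totals) precedes every Bray-Curtis computation used in
ordination. The CLR transform adds a pseudocount of 1 (configurable) before
log-ratio centering.

## Synthetic data generator

The generator is the ground truth for every recovery test, built on a
logistic-normal-multinomial model:

1. **Planted graph.** Taxa are split into three blocks (bacteria-rich,
   phototroph-rich, mixed fungal/bacterial); 80% of edges are placed within
   blocks and at least one bacteria-phototroph and one phototroph-fungus
   edge is guaranteed. `n_hubs` designated keystone taxa are wired up to at
   least 3x the median degree. Defaults: 60 taxa (40/14/6), edge density
   0.05, 3 hubs, 150 samples, library sizes 20k-80k reads.
2. **Precision matrix.** Edge weights are drawn uniform(0.6, 0.9) and
   entered as *negative* off-diagonal entries, so planted edges correspond
   to positive partial (and marginal) associations — the regime the
   positive-consensus ensemble targets. The diagonal is the absolute row
   sum + 0.1, which makes the matrix strictly diagonally dominant, hence
   certifiably positive definite, with the planted adjacency as its exact
   zero pattern. The implied marginal correlations on edges are ~0.5-0.6,
   the strength of a strong mutualistic co-occurrence signal; weaker
   weights (e.g. 0.2-0.4) put the signal below any workable detection
   threshold and make edge recovery impossible for every method in the
   ensemble, which is why the defaults sit where they do.
3. **Counts.** Latent log-abundances are multivariate normal with
   covariance equal to the inverse precision (its heterogeneous marginal
   variances included; `latent_sd` is an overall dispersion multiplier). An
   environmental gradient shifts a random 25% of taxa with strength
   `gradient_strength` (default 1). Latents are soft-maxed into one
   composition per sample and a single multinomial draw at the sample's
   library depth produces the counts; the 16S/18S tables are row splits of
   that draw, and stream-type / deglaciation labels are noisy thresholds of
   the gradient. Latent draws are stored on the result so oracle checks
   need no re-inference.

What the generator does **not** emulate: sequencing error, chimeras,
taxonomy misassignment, separate library preparation per marker (the two
tables share one multinomial draw — a per-library closure option exists on
the SparCC estimator via `blocks`, but the default conventions below assume
the joint composition), overdispersion beyond multinomial, and spatial or
temporal autocorrelation between samples. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
performance on real amplicon data.

## Ensemble network inference

Three methods run on the stacked (16S + 18S) table, each on its native
input convention: SparCC on counts, Spearman on relative abundances of the
stacked table, Meinshausen-Buhlmann (MB) neighborhood selection on the CLR
matrix.

**SparCC.** Log-ratio variances t_ij = Var[log(x_i/x_j)] are closure-free;
assuming basis correlations average to ~0, the basis variances w_i solve
the linear system M w = t row-sums with M = (p-2)I + J, and
rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1]. Pairs
with |rho| > 0.8 are excluded and the system re-solved (up to 10 rounds);
estimates are medians over 20 Dirichlet resamplings of the per-sample
compositions (pseudocount 1). Significance is a permutation pseudo p-value:
each taxon's counts are permuted independently across samples 100 times and
p = (1 + #{|rho_perm| >= |rho|}) / (B + 1). Known behaviour: under dense
positive dependence the average-correlation assumption biases rho toward
zero by up to ~30%; the noiseless-recovery test plants modest correlations
(<= 0.25) where the approximation error stays below 0.05 RMSE.

**Spearman.** Pearson correlation of column ranks with two-sided t
approximation p-values and Benjamini-Hochberg adjustment across the upper
triangle; constant taxa are recorded as rho 0, p 1.

**MB neighborhood selection.** Each taxon's standardized CLR profile is
lasso-regressed on all others along a shared 20-point log-spaced penalty
grid (lambda_max down to 0.01 lambda_max). The penalty is chosen by StARS:
50 subsamples of 80% of the samples, per-lambda edge-selection frequencies
theta, instability D = mean 2 theta (1 - theta) over pairs, monotonised by
a running maximum from the sparse end; the densest grid point with
monotonised instability <= beta = 0.05 wins. Neighborhoods are
OR-symmetrised; the edge sign is the sign of the larger-magnitude
coefficient of the pair. Known limitation: at very small p (~5 taxa) a
single strong edge's selection "birth flicker" across subsamples already
exceeds beta, so the running-max rule saturates before the stable window
and StARS returns a too-sparse graph; for such cases a fixed penalty at the
theoretical rate (a small multiple of sqrt(log p / n)) can be supplied via
`lambda_grid`, and the chain-recovery test does exactly that.

**Consensus.** Per-method support: SparCC |rho| >= 0.3 and pseudo-p < 0.05;
Spearman |rho| >= 0.5 and BH q < 0.01; MB membership in the selected
adjacency. An edge enters the consensus network when at least
`min_support = 2` methods support it and *all* supporting methods assign a
positive sign (sign conflicts are excluded, never averaged — only
unambiguous positive co-occurrence is analysed). Nodes left without edges
are dropped and reported. The merge rule is a design choice: a majority
vote is the conservative standard when methods' statistics are not
commensurable; score averaging is available behind `combine="average"`.
All thresholds live in `EnsembleConfig` and are recorded in output
metadata.

## Graph analysis

Networks are treated as simple, unweighted, undirected; edge statistics are
attributes only.

* **Communities.** Louvain modularity optimisation with restarts over a
  small resolution sweep (all candidates scored at the requested
  resolution, default 1.0), one Newman leading-eigenvector candidate, and
  greedy single-node relocation refinement using the O(deg) modularity
  delta; the best-Q partition wins. The extra candidates matter on small,
  weakly modular graphs, where a single greedy pass can stall ~8% short of
  the optimum. Communities with fewer than 5 nodes are pruned (recorded,
  excluded from cluster counts); Q is reported for the unpruned partition.
* **Topology.** Node/edge counts, retained-cluster count, hop diameter on
  the largest connected component, density 2E/(N(N-1)), degree
  assortativity (Pearson over edge endpoint degrees), global transitivity.
* **Centrality and keystones.** Degree and unnormalised Brandes betweenness
  (endpoints excluded); dense ranks with ties sharing the better rank. The
  keystone score is the rank-sum (degree rank + betweenness rank); the 10
  lowest rank-sums are the keystone list, ties broken by higher betweenness
  then lexical node id. Keystones need not be abundant — mean relative
  abundance is attached for reporting only.
* **Fragmentation.** f = connected components / nodes. The removal
  trajectory deletes keystones one at a time in static rank order
  (re-ranking after each removal via `recompute`), recomputing components,
  f, and the Louvain cluster count at each step; f_mean summarises the
  trajectory. The denominator is the *current* node count by default; the
  original count is available via `original_denominator` because the
  convention is genuinely ambiguous.

A structural caveat: in any positive-definite Gaussian graphical model a
high-degree hub cannot carry per-edge partial correlations as strong as
low-degree nodes (the precision row sum is bounded), so hub edges are
systematically the hardest to infer and hub identity degrades through the
inference path. Keystone-recovery guarantees are therefore stated for the
keystone criterion applied to a known graph, not for the full
inference-plus-ranking chain.

## Ordination and enrichment

Bray-Curtis dissimilarities (on Wisconsin-standardised bacterial tables)
are double-centered into the Gower matrix; principal coordinates on the
positive eigenvalues carry the analysis, negative-eigenvalue inertia is
excluded and reported separately (no square-root or Lingoes correction by
default). Constrained inertia is the Frobenius norm of the projection of
the coordinate space onto the (centered, scaled, rank-reduced) constraint
basis; canonical eigenvalues come from its SVD. `explained_fraction` is
constrained / total *positive* inertia; the adjusted (Ezekiel) R² is also
reported. For reference, vegan's capscale uses the net total (positive
minus negative inertia) as its denominator — the constrained inertia and
canonical eigenvalues agree with capscale to numerical precision, and both
conventions can be reconstructed from the reported fields.

Forward selection mirrors ordistep: at each step the remaining candidate
with the largest marginal pseudo-F (added inertia over residual inertia,
df-scaled) is tested by freely permuting its rows (999 permutations by
default, p = (1 + #{F_perm >= F}) / (n_perm + 1)); it enters when p <=
alpha (0.01), matching the reference implementation's acceptance rule —
with 199 permutations this puts the single-candidate type-I error at the
nominal level. Candidates nearly collinear with the selected set
(residual variance fraction < 0.002) are skipped. With several candidates
the best-of-q selection inflates the family-wise first-step error above
alpha, as expected for stepwise procedures; calibration claims are for the
single-candidate test.

`keystone_vs_environment` runs forward selection + db-RDA three times on
the same bacterial Bray-Curtis matrix — bacterial keystone relative
abundances, eukaryotic keystone relative abundances, and environmental
variables (natural log with a half-minimum-positive offset for
zero-containing columns) — and reports the three explained fractions side
by side. Family-level enrichment fits a per-family two-way fixed-effects
ANOVA (stream type x deglaciation + interaction) on relative abundances
with BH adjustment across families within each effect.

## Pipeline

`run_pipeline` executes the chain per stratum (floodplain x stream type x
deglaciation class, the study's eight networks), skipping strata below a
configurable sample floor (default 10, which is also the minimum MB needs).
All randomness flows from one root seed split deterministically per stage
and stratum (CRC-based, < 2^31); identical config + seed reproduces
byte-identical outputs, and the manifest records the config hash (output
directory excluded), seed, per-stratum results and skip reasons.

## Problem sizes in the test suite

The suite exercises the stated guarantees at desk scale: ensemble recovery
at p = 60 taxa, n = 150 samples over 10 seeds; keystone recovery over 20
planted graphs; Louvain quality against exhaustive search on 8-node graphs
(the largest size where all 4140 partitions can be enumerated);
permutation-test calibration over 1000 null simulations with 199
permutations; and the determinism check on a reduced pipeline (32 taxa, 80
samples). `scripts/acceptance.py` runs the full default-scale pipeline
(100 taxa, 320 samples, 8 strata) once and reports the quantities it
computes.
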