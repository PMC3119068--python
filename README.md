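# hmmnet

Similarity networks of SCOP profile hidden Markov models.

The SCOP database represents each protein superfamily by many profile HMMs
built from different seed domains, so the models overlap and are partly
redundant. `hmmnet` studies that redundancy with a network: run an
all-vs-all HMM–HMM comparison (HHsearch), place an edge between two models
whose e-value beats a significance cutoff, and analyze the resulting graph —
its degree distribution, density, connected components, centralities, and
above all how the components line up with SCOP's four-level hierarchy
(class / fold / superfamily / family). The package is aimed at structural
bioinformaticians who want to quantify model overlap in profile libraries,
or who need a tested reference implementation of the component-conservation
and randomization-null machinery for any labeled similarity network.

## The model

Given symmetrized pairwise e-values `e(u, v)` (the better of the two search
directions) and a cutoff `t` (default 10⁻³), the network is the simple
undirected graph `G = (V, E)` with an edge `{u, v}` whenever `e(u, v) < t`;
vertices with no passing edge (models that match only themselves) are
dropped. On `G` the package computes:

- degree histogram and an OLS quadratic fit to the log₂–log₂ degree
  distribution,
- density `2E / V(V−1)`, global transitivity `3·(triangles)/(connected
  triples)`, per-component density, diameter, mean distance, clique and
  tree flags, and Kendall τ_b between component size and density,
- Freeman betweenness `B(a) = Σ_{s<t} σ(s,t|a)/σ(s,t)` (unnormalized) and
  per-component closeness `c(a) = (n−1)/Σᵢ d(a,i)`,
- a conservation census: each component is classified by the deepest SCOP
  level shared by all members (family conserved, superfamily only, fold
  only, class only, cross-class),
- pairwise ROC curves per hierarchy level: a pair is positive if SCOP puts
  both models in the same group at that level, predicted positive if its
  e-value beats the cutoff; TPR = TP/(TP+FN), FPR = FP/(FP+TN) swept over
  cutoffs 10⁻²⁰ … 10⁻³,
- a per-superfamily dispersal index (number of components containing its
  models divided by its model count),
- a randomization null for the working hypothesis that models in one
  component share a family/superfamily more often than chance: random
  networks preserve the degree distribution and the component size multiset
  exactly (label permutation by default, connectivity-preserving double-edge
  swaps as an alternative), and the observed conservation proportion is
  compared against the null with an add-one empirical p-value.

A synthetic generator plants a SCOP-style hierarchy and draws tiered
e-values (same-family ≪ same-superfamily ≪ same-fold ≪ unrelated, with
asymmetric search directions and self-only models), so the whole pipeline
is exercised without the external HMM library.

## Worked example

```python
from hmmnet import *

universe = generate_universe(UniverseConfig(seed=1))
table = generate_hits(universe, SimilarityConfig(), seed=2)
labels = {str(r.sid): r.sccs for r in universe}

net = build_network(table, labels, cutoff=1e-3)
print(net.n_vertices, net.n_edges)            # 145 232

census = conservation_census(net)
print(round(census.proportion_conserved(HierarchyLevel.FAMILY), 3))       # 0.643
print(round(census.proportion_conserved(HierarchyLevel.SUPERFAMILY), 3))  # 0.964

null = null_distribution(net, labels, level=HierarchyLevel.FAMILY,
                         n_reps=1000, seed=3)
print(round(null.null_max, 4), round(null.empirical_p, 6))  # 0.1071 0.000999
```

Of 167 generated models, 145 survive into the network (the rest match only
themselves). The 28 components are highly family-coherent — 64% contain a
single family and 96% a single superfamily, with transitivity 0.84 — while
under label permutation at most 11% of components are ever family-conserved
across 1000 replicates, so the clustering-by-family hypothesis is accepted
at p ≈ 0.001, mirroring the behaviour of the real SCOP library network.

The same analysis runs from the shell:

```sh
hmmnet simulate --seed 1 --outdir sim
hmmnet build --hits sim/hits.tsv --labels sim/labels.tsv --edges-out edges.tsv
hmmnet metrics --edges edges.tsv --labels sim/labels.tsv --outdir out
hmmnet report --synthetic --seed 1 --outdir out_full   # everything at once
```

All outputs are TSV tables (edge list, GraphML export, degree histogram and
fit, network and per-component summaries, centrality tables with top-20
views, cutoff sweep, conservation census, ROC table, dispersal table,
null-model summary), each with a provenance comment line recording version,
seed, and configuration hash.

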