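# Methods

## Network construction

The input is a set of directed hits (query sid, target sid, e-value) from
an all-vs-all profile–profile search, plus a map from sid to SCOP concise
classification (sccs). Duplicate directed hits collapse to their smallest
e-value; the two directions of each unordered pair are then combined into
one pairwise e-value. HMM–HMM comparison is not symmetric, and the source
of the asymmetry (alignment pathing, model lengths) carries no information
we use, so the default combiner is the *minimum* (most significant) of the
two directions — the most inclusive reading of "the pair's e-value".
`max` and `mean` are available for sensitivity analysis.

An edge joins a pair when its e-value is **strictly below** the cutoff
(default 10⁻³, the conventional profile-profile significance threshold also
used to delimit Pfam clans). Strict `<` follows the natural reading of
"below the threshold"; an `inclusive` flag switches to `≤`. Exact equality
is measure-zero for continuous e-values, so the choice is immaterial in
practice but kept explicit. Vertices without any passing edge — including
models whose only hit is themselves — are removed after thresholding, so
the network reproduces the two-stage count (models with any match → models
with a partner). The graph is analyzed unweighted; pair e-values are kept
only as edge annotations for export.

## Graph statistics

All component, distance, and centrality computations run on the simple
undirected graph:

- **Betweenness** is Freeman's unnormalized count over unordered pairs,
  endpoints excluded: `B(a) = Σ_{s<t, s≠a≠t} σ(s,t|a)/σ(s,t)`. The
  unnormalized form is used because its magnitudes are directly
  interpretable as mediated pair counts (values in the thousands for hub
  models of large components); cross-component pairs contribute zero.
- **Closeness** is the normalized form `c(a) = (n−1)/Σᵢ d(a,i)` and is
  defined *per connected component only* (range (0, 1], reaching 1 exactly
  when a vertex neighbours everything in its component). Calling it on a
  disconnected graph is an error rather than silently producing the
  harmonic workaround — a whole-network closeness has no meaning when most
  vertex pairs are unreachable.
- **Transitivity** is the global clustering coefficient,
  3·triangles / connected triples, zero when no triples exist.
- **Component summaries** record size, edge count, density
  `2E/(n(n−1))`, diameter, mean pairwise distance, and clique
  (`density = 1` ⟺ `diameter = 1`) and tree (`E = n−1`) flags.
- The **size–density association** is Kendall's τ_b (tie-corrected, the
  appropriate variant since small components tie heavily in both size and
  density), restricted to components of size > 2 because density is
  degenerate (always 1) for two-vertex components; p-values come from
  scipy's two-sided test.
- The **log–log degree fit** regresses log₂ of the raw vertex count per
  degree on log₂ degree by unweighted OLS with one point per observed
  degree — raw counts, not relative frequencies, which only shift the
  intercept. The fit needs ≥ 3 distinct degrees and is reported as absent
  (not an error) on networks too small to determine it.
- Top-k centrality tables sort descending with ties broken by sid so
  reports are deterministic.

## Hierarchy analysis

Each component is assigned the deepest SCOP level shared by all members
(agreement is prefix-based, so comparing every member against one fixed
member suffices). The census reports per-category counts and cumulative
conserved proportions (family; family ∪ superfamily-only; …).

ROC curves treat every unordered pair of a fixed sid universe as a
classification instance per hierarchy level: positive if the two models
share the level in SCOP, predicted positive if the pair e-value beats the
cutoff, with unreported pairs counted as worse than any cutoff (this is
what makes TN well-defined). The universe defaults to the sids networked at
the loosest cutoff of the sweep and stays fixed across cutoffs so TP+FN is
constant per level; `all-matched` (every sid in the hit table, self-only
models included) is the natural alternative, since a full-scale analysis
could reasonably use either universe. Counting is group-wise (positives from label-group
sizes, predicted positives from the pair map), never by materializing the
O(n²) pair set.

The dispersal index of a superfamily is (components containing ≥ 1 of its
models) / (its networked model count), computed over networked models only
— models filtered out as self-only matches belong to no component and
would make the quotient meaningless.

## Randomization null

The working hypothesis is that components collect models of one family or
superfamily far more often than random assignment would. The null must
preserve the degree distribution and the number and sizes of components.
Both are satisfied *exactly* by fixing the graph and permuting the
multiset of sccs labels over the vertices, which is the default scheme and
matches the hypothesis being tested (family identity assigned to nodes at
random). A structural alternative — degree-preserving double-edge swaps
applied within each component, rejecting any swap that would create a
self-loop or multi-edge or disconnect the component — is provided for
readers who prefer rewiring nulls; it preserves the same two constraints
and is asserted to do so on every draw.

Per-replicate generators are spawned from `SeedSequence([master_seed,
replicate_index])`, so results are reproducible and independent of
evaluation order. The empirical p-value uses the add-one estimator
`(1 + #{null ≥ observed}) / (n_reps + 1)`, which can never be zero. The
default replicate count is 10,000; a few hundred suffice for the test
suite's checks and run in well under a minute.

## Synthetic data

The generator plants a class → fold → superfamily → family hierarchy
(counts drawn per parent from configurable ranges; defaults give ~150–250
models over 2–3 classes, enough for a few dozen components) and draws
e-values as `10^x` with `x ~ Normal(μ_tier, σ_tier)` per relatedness tier,
because e-values span orders of magnitude and every analysis reasons on
log-scaled cutoffs. Each emitted pair produces both directed hits sharing
one base draw plus independent log-scale jitter (σ = 0.3 by default),
emulating HHsearch's asymmetric query/target e-values. Every model hits
itself, and a configurable fraction (default 12%, matching the observed
ratio of self-only models in the real library) hits nothing else,
exercising the isolated-vertex filtering path.

Default tier parameters (log₁₀ mean, sd, hit probability): same-family
(−28, 4, 0.95), same-superfamily (−10, 4, 0.05), same-fold (−2, 2, 0.005),
unrelated (+1.5, 1.5, 0.002). At the 10⁻³ cutoff these yield networks that
are mostly family-pure with a minority of superfamily-merged and rare
fold-merged components, high transitivity (~0.85), and many small cliques —
the qualitative regime of the real SCOP 1.75 network. A
`SimilarityConfig.tier_separated()` preset places all cross-family tiers
entirely above the cutoff, so every component is family-conserved by
construction; it is used for parameter-recovery checks.

What the generator does *not* emulate: realistic degree heterogeneity
within superfamilies (hubs arise only stochastically), HHsearch score and
probability columns, alignment coordinates, or the long-tailed component
size distribution of the real library (synthetic components stay small).
Passing tests therefore demonstrate correctness of the machinery and
qualitative recovery of planted structure, not quantitative agreement with
full-scale statistics of the real library, which require the external SCOP
1.75 HMM collection and a cluster-scale all-vs-all search.

## Sid and sccs grammar

Sids are accepted as `d` + 4-character PDB code + one chain character +
one domain character, with `_` allowed in either suffix position — this
covers every identifier form in SCOP 1.75 without implementing the full
historical grammar. Sccs strings are `class.fold.superfamily.family` with
class in a–g and positive integer indices; parsing is strict and
round-trips exactly. Synthetic sids are grammatical (`d` + base-36 counter
+ `a_`) so generated data passes the same validation as real data.

## Pipeline and numerical choices

- Stage composition: each CLI subcommand runs one stage on explicit files;
  the `report` command runs all stages in-process. Both paths share the
  same table builders, so staged and monolithic runs emit identical rows.
- E-values are serialized in scientific notation with 6 significant
  digits; comparisons always use parsed floats.
- Every report carries a provenance comment (`# hmmnet <version>
  seed=<seed> config=<sha256-prefix>`); the hash excludes the output
  directory, which does not affect the analysis.
- Degenerate inputs: empty networks are refused by the metrics that would
  divide by zero (density, histogram, transitivity); the quadratic fit is
  omitted rather than fatal on tiny networks; a sid that survives
  thresholding without a label aborts the run naming the sids.
- Plot generation is deliberately out of scope: every figure-ready table
  (degree histogram, component sizes, ROC points, null replicates) is
  emitted as TSV for external plotting.

## Limitations

- The ROC pair universe and the exact randomization scheme are genuinely
  open design choices for this kind of analysis; both are explicit and
  configurable here, and results can shift slightly between the
  alternatives.
- The rewiring null can mix slowly on dense components (many proposals
  rejected); it is provided as a cross-check, not the default.
- `.hhr` parsing covers the header and hit-list summary table only, and
  only the e-value column is consumed.
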