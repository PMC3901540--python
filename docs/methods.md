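# Methods

This note documents the models, conventions and numerical choices behind
`realmod`, and what the synthetic benchmarks do and do not establish.

## Data model and conventions

Networks are sets of nodes (opaque strings) and edges, directed or
undirected, read from whitespace-separated edge lists (`#` comments skipped;
a third column, e.g. a weight, is ignored with a warning — the analysis is
strictly binary). Duplicate lines collapse; in undirected networks `(a, b)`
and `(b, a)` are one edge.

Conventions that a user should be aware of:

- **Self-loops** (cannibalism in food webs) are retained. A loop contributes
  1 to a node's generality `g` and 1 to its vulnerability `v`, hence 2 to its
  degree `d`; in Newman–Girvan Q it contributes one within-module edge and
  both endpoints to its module (the adjacency-matrix `A_ii = 2` convention).
- **Reciprocal directed edges** `i→j` and `j→i` count as two distinct edges
  wherever E or W is counted. Predator–prey adjacency matrices are directed;
  whether reciprocal links should instead collapse to one interaction is a
  modelling choice the user can make by symmetrizing first
  (`symmetrize()` collapses reciprocal pairs).
- **Bipartite incidence matrices** (host–parasite, pollination) are
  transformed to directed unipartite networks with one edge per nonzero cell,
  row-node → column-node, preserving every interaction exactly once.
  Quantitative cells are refused; the measures here are for binary matrices.
- **Isolated nodes** cannot be represented in an edge-list file. The CLI
  `score` command therefore treats the partition file as the authoritative
  node inventory: nodes named only there are added as isolated nodes (they
  affect neither Q_R nor Q).
- Partition labels are canonicalized to `0..k−1` by first appearance over
  lexicographically sorted nodes, so partitions compare by grouping, not by
  label spelling.

## Realized modularity

`Q_R = W/E` is computed on the network's **native** edge set (directed if so
stored), since it counts interactions, not projections. Newman–Girvan
`Q = Σ_m (e_mm − a_m²)` is computed on the undirected projection, matching
how the Louvain detector operates; directed-modularity variants are out of
scope. `Q'_R = 2 Q_R − 1` is exact arithmetic on `Q_R`.

The claim that randomly assigned modules centre `Q'_R` on 0 holds for
*balanced two-module* assignments (where just under half of all node pairs
fall within modules); for unbalanced or many-module random assignments the
centre shifts. The property test and the acceptance check are restricted to
balanced bisections accordingly.

## Louvain detector

A reference implementation of two-phase greedy modularity maximization:

- **Phase 1** sweeps nodes in a seeded-random order (one shuffle per pass)
  and moves a node only for a strictly positive modularity gain; among
  equal-gain targets the lowest community label wins. Both choices make runs
  deterministic under `(network, seed)`.
- **Phase 2** aggregates communities into super-nodes; internal weight
  accumulates on the diagonal at twice its value, keeping the weighted Q of
  the aggregated graph equal to the Q of the induced partition.
- Passes repeat until a pass improves Q by less than `1e−8` (the numeric
  floor for "modularity ceases to increase"). The per-pass Q trace is
  recorded and is non-decreasing; the final partition's Q is recomputed on
  the original graph and matches the last trace entry to 1e−9.

A single seeded run is the default; `best_louvain(..., restarts=k)` (CLI
`--restarts`) keeps the best of k derived seeds. On exhaustive enumeration
of all partitions of random graphs with n ≤ 8, the detector attains the true
maximum on ≳ 90% of instances and never exceeds it.

## Null model

For each ordered pair (i, j), `P(i→j) = ½(g_i/d_i + v_j/d_j)`, probabilities
clipped to [0, 1]; terms with `d = 0` contribute 0, and zero-degree nodes
keep all their pair probabilities at 0 (they stay isolated in every
replicate). Self-pairs are excluded unless the empirical network contains at
least one self-loop, in which case they are sampled like any pair. Replicates
are independent Bernoulli draws per pair.

**Known caveat.** As written, this degree-profile normalization need not
conserve expected connectance: a pure-source node (`g = d`) paired with a
pure-sink node (`v = d`) gets `P = 1` regardless of network density, and for
networks whose in/out ratios hover near ½ the pair probabilities hover near
½ whatever the empirical connectance. The formula is nevertheless the
default, implemented as stated; an alternative "size" normalization
`P = ½(g_i/n + v_j/n)`, which does conserve expected edge counts, is
available via `normalization="size"` (CLI `--null-normalization size`).
When the in/out ratio is constant across nodes the degree form reduces to an
Erdős–Rényi model with that constant probability.

The null model requires a **directed** network: under the undirected
convention `g = v = d`, the formula degenerates to `P = 1` for every
connected pair, so undirected input is rejected rather than silently
mis-modelled. The CLI reads edge lists as directed for `nulltest`.

Ensembles derive one sampling seed and one detection seed per replicate from
the master seed, so runs are bit-reproducible end-to-end. Replicates with
fewer than 2 edges are discarded and counted (not resampled, which would
bias the ensemble); the retained/discarded split is reported.

## Significance summaries

Over the retained replicates the pipeline reports means, sample variances
(ddof = 1), deltas `dq = Q_emp − mean(Q_null)` and `dqr` likewise, and a
confidence interval realized as the **percentile interval** at quantiles
`(1−level)/2` and `1−(1−level)/2` with linear interpolation (default level
0.90, i.e. the 5th–95th percentiles). Percentiles were chosen over
mean ± z·sd because modularity distributions are bounded and often skewed;
the interval estimator behind the original analyses is not specified, so
this is this package's choice. Raising the level never narrows the interval.

A statistic is *flagged* when the empirical value falls strictly outside its
interval. The joint outcome is labelled:

- `more-modular-both` / `less-modular-both` — both flags fire, both deltas
  positive / negative;
- `conflicted-Q-low-QR-high` — Q below chance yet Q'_R above it (the
  interesting case: modules weak by Q are still internally denser than the
  null's);
- `conflicted-Q-high-QR-low` — the mirror image;
- `indistinct` — anything else, including the case where only one flag
  fires: the four named labels assert agreement of *both* statistics, so a
  single-signal outcome is deliberately not over-interpreted.

## Synthetic generators

- `planted_partition(sizes, p_in, p_out, directed, seed)` — each
  within-module pair linked with `p_in`, between-module with `p_out`
  (`0 ≤ p_out ≤ p_in ≤ 1` enforced; no self-loops). Used for recovery
  benchmarks at 4 modules × 25 nodes, `p_in = 0.3`, `p_out = 0.01`.
- `erdos_renyi(n, p)` — the degenerate equal-probability case.
- `fixture_network(E, W, sizes, seed)` — exactly E edges, exactly W
  within-module, sampled uniformly without replacement from the within- and
  between-pair pools. The default (E = 36, W = 31, four modules of 9)
  reproduces the worked-example arithmetic `Q_R = 31/36 ≈ 0.86`,
  `Q'_R ≈ 0.72` on every seed; the exact drawn topology (and hence its
  Louvain Q) is not pinned, only the (W, E) statistics.

What these benchmarks show — and do not. Planted-partition graphs are
degree-homogeneous within modules; real food webs have heavy-tailed degree
distributions, trophic ordering, and connectances that co-vary with size.
Passing the synthetic suite establishes the *mechanics* (counting, sampling,
optimization, calibration) and the qualitative behaviours (Q'_R insensitive
to density where Q is not; strong planted structure classified
`more-modular-both`), not empirical conclusions about any particular
ecological compendium.

## Problem sizes and numerical choices

Benchmarks run at desk scale: exhaustive-partition oracles up to n = 8
(Bell(8) = 4140 partitions), recovery and significance at 100 nodes with
200-replicate ensembles, consistency checks with 1000 Bernoulli draws of
50-node networks, and a 20-network density sweep spanning connectance
0.05–0.5 at a fixed `p_in/p_out = 2.5` ratio (the largest ratio keeping
`p_in ≤ 1` at connectance 0.5 for the 4 × 25 layout). Default replicate
count for production runs is 1000, CI level 0.90. Gain comparisons in the
Louvain sweep use a `1e−12` guard so float noise cannot masquerade as an
improving move; convergence uses the `1e−8` per-pass floor.

## Limitations

- Binary interactions only: no weighted or quantitative variants of Q, Q_R
  or the null model.
- One detector: walktrap, spinglass, edge betweenness and friends are
  supported only through partition-file import (`score`), not implemented.
- The degree-profile null's connectance drift (above) means its ensembles
  can be much denser than sparse empirical networks; deltas remain
  interpretable as "relative to what the degree profile generates", but
  cross-study comparisons should state which normalization was used.
- No p-values or multiple-testing control across network batches; the
  outside-CI flag at level 0.90 is a descriptive screen, not a test with
  guaranteed error rates.
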