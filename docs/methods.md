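# Methods

This note states precisely what `pscluster` computes, which parameters
control it, how the synthetic instances are generated, and where the
implementation makes numerical or modelling choices that a user should be
aware of.

## 1. Similarity measures

Documents carry an id, title, abstract, journal, year and a keyword set.
Abstracts (falling back to titles) are tokenised to lowercase alphanumeric
words, stopwords removed, and weighted by TF.IDF:

- term frequency `TF(t, d) = f(t, d) / max_s f(s, d)` (max-normalised counts),
- inverse document frequency `IDF(t) = log2(N / n_t)` with `N` documents and
  `n_t` the number containing `t`.

Three distance measures are offered, each converted to a similarity
`sim = 1 − d` and finally divided by the maximum entry so the matrix lies in
[0, 1]:

- **d1** — mean of the TF.IDF vector distance and a journal indicator
  (0 if both documents appeared in the same journal, 1 otherwise, 1 if a
  journal is missing). The journal term is a weak prior that documents from
  one venue are topically closer.
- **d2** — the TF.IDF vector distance alone. Cosine distance is the
  default; euclidean distance is available and is rescaled by the matrix
  maximum. A document whose vector is all-zero (every token is a stopword
  or appears in every document) is at distance 1 from everything.
- **d3** — Tanimoto (Jaccard) distance on the keyword sets. Two empty
  keyword sets count as identical; an empty set against a non-empty one as
  maximally distant.

## 2. Conflict graph

Given thresholds `0 < ι ≤ ε ≤ 1`, a pair with similarity `s` becomes

- a **black** edge if `s < ι` (clearly dissimilar),
- a **blue** edge if `ι ≤ s ≤ ε` (borderline),
- a non-edge if `s > ε` (similar enough to share a cluster).

Both comparisons against ε and ι are inclusive on the blue side, so `ι = ε`
still admits blue edges exactly at the common threshold; apart from that
degenerate band, `ι = ε` means no borderline edges and the problem becomes
ordinary proper coloring of the conflict graph (hard clustering).

Partial graphs over disjoint sub-corpora built with the same ε, ι and
measure can be merged: the union of the partial edge sets plus a
classification of every cross pair equals the graph the monolithic build
produces, which supports divide-and-conquer construction. Note that TF.IDF
is corpus-dependent, so exact agreement between a merged and a monolithic
graph is guaranteed only for corpus-independent measures such as `d3`, or
when all parts are scored against the union corpus.

## 3. Pseudostable covering

A *tuple* is a pair of stable sets `D1`, `D2` together with a set of
pairwise node-disjoint blue paths `[v, u, w]` with `v ∈ D1`, `w ∈ D2`; a
tuple may also be a bare stable set. The middle node `u` of a path is an
*inner* (bridge) document: it belongs to both clusters at once. A covering
is a family of tuples whose stable sets and inner nodes together cover all
documents. Its weight is the number of *distinct* stable sets used — a set
shared by several tuples is counted once — and the objective is to minimise
that weight. In the relaxed problem solved here an inner node may appear in
paths of several tuples; `validate_covering` can also enforce the stricter
one-path-per-inner-node rule, and `strict_variant_check` reports whether a
covering additionally satisfies the acyclicity and degree-≤ 2 restrictions
of the strict problem variants (quotient graph over distinct stable sets).

### Greedy eliminator

A proper start coloring is computed by one of three heuristics, each
deterministic with lexicographic tie-breaking (an optional seed permutes
the tie-break priority):

- **gis** — greedy independent sets, repeatedly peeling a maximal stable
  set built in ascending-degree order;
- **slf** — saturation-largest-first (DSATUR): color vertices by
  descending saturation, breaking ties by degree, then priority;
- **clique** — clique partition of the complement graph by iteratively
  merging the pair of super-nodes with the most common complement
  neighbours; each clique of the complement is a stable set.

The eliminator then visits color classes in ascending size. A node `u`
still in its class, incident to blue edges, not already a path endpoint,
with two blue neighbours `v`, `w` in two *different* surviving classes
(neither already an endpoint or inner node) is removed from its class and
becomes the inner node of the path `[v, u, w]`. Emptied classes vanish, so
the final cluster count never exceeds the start color count. Complexity is
dominated by the start coloring; the elimination pass is linear in the blue
adjacency lists.

### Exact integer program

Binary variables `x_{i,k}` assign document `i` to color `k ∈ {0, …, K}`,
where color 0 marks inner nodes and `K` is an upper bound (by default the
start coloring's color count); `y_k` marks used colors and the objective is
`Σ y_k`. Constraints: every document gets exactly one color, assignments
imply usage, and edge endpoints may not share a positive color. Only
documents that are the centre of at least one blue path on two blue edges
may take color 0. For each potential inner node the default **exact**
formulation introduces a witness variable per candidate blue triple: an
inner node must have at least one witness triple whose endpoints are
non-inner and carry different positive colors. A variant that instead
requires *every* blue triple around an inner node to be heterochromatic and
forbids blue-adjacent inner nodes (`formulation="printed"`) is retained for
comparison; it is never looser but can exclude valid coverings, so the
exact formulation is the default. Symmetry is broken by ordering the `y_k`.
Models are solved with HiGHS through `scipy.optimize.milp`; a brute-force
backtracking oracle (`brute_force_optimum`, refusing instances beyond a
size cap) verifies both formulations on small graphs. A covering is
reconstructed from a solution by giving each inner node its smallest
witness triple; bridging paths over the same pair of clusters that share a
node are split into separate tuples so that within-tuple disjointness
holds.

### Bounds and threshold selection

- The edge-count bound `⌊(1 + √(8e + 1)) / 2⌋ ≥ χ(G)` gives an a-priori
  cap on the cluster count from the number of conflicts alone; it has been
  checked exhaustively against the chromatic number on every graph with at
  most five nodes. An alternative closed form with a different radicand is
  available but is undefined (negative radicand) on most sparse graphs, in
  which case `None` is returned.
- `estimate_eps_for_k` bisects over the distinct similarity values and
  returns the ε whose saturation-coloring color count is closest to a
  requested cluster count, with ι set to a fixed fraction of ε.
- `bounds_from_cannot_link` derives ε (the maximum similarity among the
  listed must-separate pairs, inclusive) and ι (their minimum, clamped to a
  tiny positive value when a listed pair has similarity 0, since ι must be
  positive; such pairs come out black).

## 4. Weighted cluster graph

Clusters become nodes; every pair of clusters joined by at least one bridge
gets an edge with two weights: `d_s`, the number of bridging paths between
them, and `d`, the mean over those paths of
`(|N(u) ∩ D_j| + |N(u) ∩ D_k|) / (|D_j| + |D_k|)` where `N(u)` are the
conflict-graph neighbours (either edge color) of the inner node `u`. `d`
lies in (0, 1]; `d = 1` means every bridge is adjacent to every member of
both clusters. The graph exports to GraphML and DOT.

## 5. Random instances and the synthetic corpus

- `gilbert_instance(n, p, p_blue, seed)` — each of the `n·(n−1)/2` pairs is
  an edge independently with probability `p`, and each edge is blue with
  probability `p_blue`, black otherwise. Defaults `p = 0.75`,
  `p_blue = 0.2` reflect that a conflict graph is *dense* (most document
  pairs are dissimilar) with a modest borderline band.
- `gnm_instance(n, m, p_blue, seed)` — exactly `m` edges uniformly at
  random.
- `sparse_gilbert(n, p, p_blue, seed)` — the same distribution as the
  Gilbert model, generated by geometric skipping in O(edges) time for large
  sparse instances.
- `synthetic_corpus` plants `k` topics with per-topic keyword vocabularies
  and journals; each document draws a fixed fraction of its keywords from
  its own topic vocabulary (60 % of the vocabulary size by default, which
  guarantees within-topic keyword overlap) and, with `keyword_overlap > 0`,
  some from other topics. Abstracts are token sequences over the topic
  vocabulary. This is a deliberately stylised generator: it produces
  block-structured similarity with controllable cross-topic leakage, not
  realistic natural language.

All generators are deterministic for a fixed seed.

## 6. Numerical choices

- Similarities are kept as dense `float64` matrices; graphs store edge sets
  of `frozenset` pairs, so all comparisons are exact set operations.
- Threshold comparisons are performed on the normalised similarities
  without tolerance. Values at exactly ε or ι are classified inclusively
  (blue). Users comparing against externally computed matrices should be
  aware of the usual floating-point caveats at exact threshold boundaries.
- The MILP uses integrality constraints throughout (no LP rounding); HiGHS
  returns proven optima, and `IlpSolution.status` distinguishes `optimal`,
  `feasible` (time limit hit) and `infeasible` (possible when a `K` below
  the optimum is forced by hand).
- All orderings (class visiting order, candidate scans, triple enumeration)
  are lexicographic, so every pipeline stage is deterministic; the optional
  coloring seed only permutes tie-break priorities.

## 7. Limitations

- The exact solver enumerates one witness variable per blue triple; on
  graphs with many blue edges the triple count grows roughly with the sum
  of squared blue degrees, so ILP solves are practical for small and
  medium instances only. The greedy path handles larger instances.
- The greedy eliminator is order-dependent and carries no approximation
  guarantee; it never increases the cluster count over the start coloring
  but can miss eliminations an optimal covering would make.
- Bridge membership is binary (a document bridges exactly two clusters);
  the model does not express graded membership or bridges across three or
  more clusters.
- `d1`/`d2` inherit TF.IDF's corpus dependence: adding documents changes
  all similarities, and very short texts can produce all-zero vectors.
- The synthetic corpus is a stylised benchmark; results on it demonstrate
  mechanism (planted structure is recovered), not performance on real
  corpora.
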