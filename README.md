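# pscluster — soft document clustering by pseudostable graph covering

`pscluster` clusters a corpus of documents while letting individual
*bridge* documents belong to two clusters at once. Instead of partitioning a
similarity graph, it covers a **conflict graph** — documents are joined by an
edge when they are *dissimilar* — with stable sets plus short bridging paths.

## The model in brief

1. **Similarity.** Documents are compared with one of three measures:
   `d1` (average of TF.IDF vector distance and a same-journal indicator),
   `d2` (TF.IDF vector distance alone, cosine or euclidean), or
   `d3` (Tanimoto distance on keyword sets). All are rescaled to a
   similarity in [0, 1].
2. **Conflict graph.** Two thresholds ι ≤ ε turn the matrix into a graph:
   pairs with similarity below ι get a **black** edge (clearly dissimilar),
   pairs between ι and ε get a **blue** edge (borderline), and pairs above
   ε get no edge. Setting ι = ε removes the borderline band and the method
   reduces to ordinary graph coloring, i.e. hard clustering.
3. **Pseudostable covering.** The graph is covered by stable sets (the
   clusters) optionally joined by node-disjoint blue paths of three nodes.
   The middle node of such a path is a bridge document shared by the two
   clusters at its ends. The covering weight is the number of distinct
   stable sets used, and the goal is to minimise it.
4. **Algorithms.** A start coloring (greedy independent sets, DSATUR-style
   saturation coloring, or clique partition of the complement) is improved
   by a greedy eliminator that dissolves color classes into bridging paths,
   so the cluster count never exceeds the start color count. An exact
   integer linear program (solved with HiGHS via SciPy) computes the true
   minimum on small and medium instances.
5. **Outputs.** Soft cluster assignments per document, and a weighted
   cluster graph whose edge weights record how many bridges join two
   clusters (`d_s`) and how strongly the bridges tie into both sides (`d`).

See `docs/methods.md` for the precise definitions, parameter semantics and
known limitations.

## Running the tests

```sh
python -m pytest -q tests/
```

## Worked example

Five short documents: two about hot-spring microbiology (`d1`, `d2`), two
about industrial enzymes (`d4`, `d5`), and one survey about enzymes *from*
thermophiles (`d3`) that genuinely belongs to both topics.

```python
from pscluster import (Document, similarity_matrix, build_graph,
                       slf_coloring, greedy_cover, soft_assignments,
                       covering_weight, build_cluster_graph)

corpus = [
    Document(id="d1", title="Microbial ecology of hot springs",
             abstract="thermophilic bacteria communities in hot spring mats",
             journal="Microbial Ecology", year=2004,
             keywords=frozenset({"thermophile", "bacteria", "hot-spring"})),
    Document(id="d2", title="Thermophile diversity survey",
             abstract="diversity of thermophilic bacteria across spring mats",
             journal="Microbial Ecology", year=2006,
             keywords=frozenset({"thermophile", "bacteria", "diversity"})),
    Document(id="d3", title="Enzymes from extremophiles",
             abstract="catalytic properties of enzymes from thermophiles",
             journal="Extremophiles", year=2005,
             keywords=frozenset({"thermophile", "enzyme"})),
    Document(id="d4", title="Protein engineering of lipases",
             abstract="directed evolution improves industrial enzyme stability",
             journal="Applied Biocatalysis", year=2007,
             keywords=frozenset({"enzyme", "industry", "engineering"})),
    Document(id="d5", title="Industrial biocatalysis at scale",
             abstract="process design for industrial enzyme applications",
             journal="Applied Biocatalysis", year=2008,
             keywords=frozenset({"enzyme", "industry", "process"})),
]

sim = similarity_matrix(corpus, measure="d3")
g = build_graph(sim, eps=0.4, iota=0.2)
print("black edges:", sorted(tuple(sorted(e)) for e in g.black_edges))
print("blue edges: ", sorted(tuple(sorted(e)) for e in g.blue_edges))
start = slf_coloring(g)
print("start colors:", start.num_colors)
cov = greedy_cover(g, start)
print("clusters:", sorted(sorted(s) for s in cov.stable_sets))
print("bridges: ", [(p.endpoint_a, p.inner, p.endpoint_b) for p in cov.paths])
print("weight:  ", covering_weight(cov))
for doc_id, entry in sorted(soft_assignments(cov).items()):
    print(f"{doc_id}: clusters={entry['clusters']} bridge={entry['bridge']}")
wg = build_cluster_graph(cov, g)
print("cluster graph:", dict(wg.edges))
```

This prints:

```
black edges: [('d1', 'd4'), ('d1', 'd5'), ('d2', 'd4'), ('d2', 'd5')]
blue edges:  [('d1', 'd3'), ('d2', 'd3'), ('d3', 'd4'), ('d3', 'd5')]
start colors: 3
clusters: [['d1', 'd2'], ['d4', 'd5']]
bridges:  [('d1', 'd3', 'd4')]
weight:   2
d1: clusters=[0] bridge=False
d2: clusters=[0] bridge=False
d3: clusters=[0, 1] bridge=True
d4: clusters=[1] bridge=False
d5: clusters=[1] bridge=False
cluster graph: {(0, 1): {'d_s': 1, 'd': 1.0}}
```

The start coloring needs three classes because `d3` is borderline-dissimilar
to everything. The greedy eliminator dissolves `d3`'s singleton class into
the blue path `d1 – d3 – d4`, leaving two clusters with `d3` as a shared
bridge document. The cluster-graph weight `d = 1.0` says the bridge is
adjacent to every member of both clusters.

## Command-line interface

The same pipeline is available as the `pscluster` command:

```sh
pscluster simulate --n 100 --p 0.75 --p-blue 0.2 --seed 1 --out scratch/g.graphml
pscluster cluster --graph scratch/g.graphml --method greedy --out scratch/cov.json
pscluster export --covering scratch/cov.json --graph scratch/g.graphml \
    --format dot --out scratch/clusters.dot
```

or end to end from a corpus file (JSONL or CSV):

```sh
pscluster pipeline --input corpus.jsonl --measure d3 --target-k 3 \
    --outdir scratch/run
```

`pipeline` writes `graph.graphml`, `covering.json`, `clusters.graphml`,
`clusters.dot` and a `run.json` summary into the output directory; with a
fixed `--seed` the artifacts are byte-identical across runs.

## Reproduction

The summary computation behind the package's headline behaviour — solver
agreement with exhaustive search, cluster-count ordering, scaling to 100
documents, hard-clustering reduction, divide-and-conquer merging, planted
topic recovery and the edge-count chromatic bound — is scripted:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script writes each quantity as `{"value": ..., "n": ...}` where `n` is
the number of instances the quantity was computed over. It is deterministic
for a fixed seed and finishes in a few seconds on one CPU.
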