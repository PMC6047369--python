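"""Random conflict-graph instances and a topic-structured synthetic corpus.

The random protocol mirrors the study conditions used to benchmark the
heuristics: Gilbert G(n, p) graphs with edge probability p = 0.75 whose
edges turn blue with an independent per-edge probability p' = 0.2, at
n = 15 (where the exact program is still tractable) and n = 100.  A
uniform G(n, m) variant and a geometric-skipping linear-time generator for
sparse graphs are also provided.  The synthetic corpus generator plants
disjoint (or partially overlapping) topic vocabularies so that end-to-end
recovery of the topics can be tested without external data.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .graph import ConflictGraph, edge
from .similarity import Document


def _node_ids(n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"v{i:0{width}d}" for i in range(n)]


def gilbert_instance(
    n: int, p: float, p_blue: float, seed: int | None = None
) -> ConflictGraph:
    """G(n, p): each pair is an edge w.p. p; each edge blue w.p. p_blue."""
    if not (0 <= p <= 1 and 0 <= p_blue <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = _node_ids(n)
    g = ConflictGraph(nodes=set(ids))
    for u, v in combinations(ids, 2):
        if rng.random() < p:
            target = g.blue_edges if rng.random() < p_blue else g.black_edges
            target.add(edge(u, v))
    return g


def gnm_instance(
    n: int, m: int, p_blue: float, seed: int | None = None
) -> ConflictGraph:
    """Uniform graph with exactly m edges; blue coin per realised edge."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m={m} out of range [0, {max_m}]")
    rng = np.random.default_rng(seed)
    ids = _node_ids(n)
    pairs = list(combinations(ids, 2))
    chosen = rng.choice(len(pairs), size=m, replace=False)
    g = ConflictGraph(nodes=set(ids))
    for k in chosen:
        u, v = pairs[int(k)]
        target = g.blue_edges if rng.random() < p_blue else g.black_edges
        target.add(edge(u, v))
    return g


def sparse_gilbert(
    n: int, p: float, p_blue: float, seed: int | None = None
) -> ConflictGraph:
    """G(n, p) by geometric gap skipping, O(n + m) for sparse graphs.

    Walks the linear index of the n(n-1)/2 pairs, jumping ahead by
    geometrically distributed gaps; the edge-set distribution matches
    gilbert_instance (not bit-for-bit for a shared seed).
    """
    if not 0 <= p < 1:
        raise ValueError("p must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = _node_ids(n)
    g = ConflictGraph(nodes=set(ids))
    if p == 0 or n < 2:
        return g
    total = n * (n - 1) // 2
    log1p = math.log(1.0 - p)
    pos = -1
    while True:
        r = rng.random()
        pos += 1 + int(math.log(1.0 - r) / log1p)
        if pos >= total:
            break
        # invert the linear index to the pair (i, j), i < j
        i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * pos)) // 2)
        offset = pos - i * (2 * n - i - 1) // 2
        j = i + 1 + offset
        target = g.blue_edges if rng.random() < p_blue else g.black_edges
        target.add(edge(ids[i], ids[j]))
    return g


def synthetic_corpus(
    k_topics: int = 3,
    docs_per_topic: int = 10,
    vocab_per_topic: int = 10,
    keyword_overlap: float = 0.0,
    keywords_per_doc: int | None = None,
    abstract_tokens: int = 40,
    seed: int | None = None,
) -> list[Document]:
    """Documents drawn from planted topic vocabularies.

    Each topic owns ``vocab_per_topic`` keywords, of which a fraction
    ``keyword_overlap`` is shared across all topics; a document samples
    ``keywords_per_doc`` of them (default 60% of the vocabulary, which
    guarantees any two same-topic documents share a keyword) plus a
    bag-of-words abstract from the topic's word list.  With overlap 0 the
    cross-topic keyword similarity is exactly 0.
    """
    if not 0 <= keyword_overlap < 1:
        raise ValueError("keyword_overlap must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_shared = int(round(keyword_overlap * vocab_per_topic))
    shared = [f"kw_shared_{i}" for i in range(n_shared)]
    if keywords_per_doc is None:
        keywords_per_doc = max(1, math.ceil(0.6 * vocab_per_topic))
    docs: list[Document] = []
    for t in range(k_topics):
        vocab = shared + [
            f"kw_t{t}_{i}" for i in range(vocab_per_topic - n_shared)
        ]
        words = [f"word_t{t}_{i}" for i in range(vocab_per_topic * 3)]
        journal = f"journal_{t}"
        for d in range(docs_per_topic):
            kws = rng.choice(
                vocab, size=min(keywords_per_doc, len(vocab)), replace=False
            )
            abstract = " ".join(
                words[int(i)] for i in rng.integers(0, len(words), abstract_tokens)
            )
            docs.append(
                Document(
                    id=f"t{t}d{d:03d}",
                    title=f"synthetic document {d} of topic {t}",
                    abstract=abstract,
                    journal=journal,
                    year=int(2000 + rng.integers(0, 20)),
                    keywords=frozenset(str(k) for k in kws),
                )
            )
    return docs


def example_three_documents() -> ConflictGraph:
    """The canonical 3-document illustration of soft clustering.

    Documents a and c are strongly dissimilar (black edge); b sits on the
    border to both (two blue edges).  The covering yields two singleton
    clusters with b bridging them.
    """
    return ConflictGraph(
        nodes={"a", "b", "c"},
        black_edges={edge("a", "c")},
        blue_edges={edge("a", "b"), edge("b", "c")},
        eps=0.5,
        iota=0.25,
        measure="example",
    )
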