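"""Corpus handling and pairwise document similarity.

Documents carry free text (title + abstract), a journal name, a year and a
keyword set (e.g. MeSH terms).  Three similarity modes are supported:

* ``d1`` — mean of the TF.IDF vector distance and a 0/1 journal distance,
  converted to a similarity via ``1 - d``;
* ``d2`` — the TF.IDF vector distance alone, converted the same way;
* ``d3`` — Tanimoto (Jaccard) similarity of the keyword sets, used directly.

The canonical internal representation is a *similarity* on [0, 1]; distance
measures are mapped through ``sim = 1 - d`` before storage.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# A compact English stop-word list.  Tokenization is deliberately simple
# (lowercase, strip punctuation, whitespace split); no stemming.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a about above after again against all am an and any are as at be because
    been before being below between both but by can could did do does doing
    down during each few for from further had has have having he her here hers
    him his how i if in into is it its itself just me more most my no nor not
    now of off on once only or other our ours out over own same she should so
    some such than that the their theirs them then there these they this those
    through to too under until up very was we were what when where which while
    who whom why will with would you your yours""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class Document:
    """One corpus record."""

    id: str
    title: str = ""
    abstract: str = ""
    journal: str = ""
    year: int | None = None
    keywords: frozenset[str] = field(default_factory=frozenset)

    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


def tokenize(text: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> list[str]:
    """Lowercase, strip punctuation, split, drop stop words."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------


def _document_from_record(rec: dict) -> Document:
    kws = rec.get("keywords", [])
    if isinstance(kws, str):
        kws = [k for k in kws.split("|") if k]
    year = rec.get("year")
    return Document(
        id=str(rec["id"]),
        title=rec.get("title", "") or "",
        abstract=rec.get("abstract", "") or "",
        journal=rec.get("journal", "") or "",
        year=int(year) if year not in (None, "") else None,
        keywords=frozenset(str(k) for k in kws),
    )


def load_corpus_jsonl(path) -> list[Document]:
    """Read a corpus from JSONL (one document object per line)."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            docs.append(_document_from_record(rec))
    _check_unique_ids(docs)
    return docs


def load_corpus_csv(path) -> list[Document]:
    """Read a corpus from CSV with a '|'-separated ``keywords`` column."""
    docs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            docs.append(_document_from_record(rec))
    _check_unique_ids(docs)
    return docs


def load_corpus(path) -> list[Document]:
    path = str(path)
    if path.endswith(".csv"):
        return load_corpus_csv(path)
    return load_corpus_jsonl(path)


def _check_unique_ids(docs: list[Document]) -> None:
    ids = [d.id for d in docs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate document ids: {dupes}")


# ---------------------------------------------------------------------------
# TF.IDF
# ---------------------------------------------------------------------------


def tfidf_vectors(
    corpus: list[Document],
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> dict[str, dict[str, float]]:
    """Per-document term weights TF_ij * IDF_i.

    TF_ij = f_ij / max_k f_kj (max-normalised raw counts within document j);
    IDF_i = log2(N / n_i) with n_i the number of documents containing term i.
    A term present in every document therefore gets weight 0.
    """
    if not corpus:
        raise ValueError("empty corpus")
    counts: dict[str, dict[str, int]] = {}
    for doc in corpus:
        tokens = tokenize(doc.text(), stopwords)
        if not tokens:
            logger.warning("document %s has an empty token list", doc.id)
            counts[doc.id] = {}
            continue
        c: dict[str, int] = {}
        for t in tokens:
            c[t] = c.get(t, 0) + 1
        counts[doc.id] = c

    n_docs = len(corpus)
    df: dict[str, int] = {}
    for c in counts.values():
        for term in c:
            df[term] = df.get(term, 0) + 1

    vectors: dict[str, dict[str, float]] = {}
    for doc_id, c in counts.items():
        if not c:
            vectors[doc_id] = {}
            continue
        max_f = max(c.values())
        vec = {}
        for term, f in c.items():
            idf = math.log2(n_docs / df[term])
            w = (f / max_f) * idf
            if w != 0.0:
                vec[term] = w
        vectors[doc_id] = vec
    return vectors


def vector_distance(
    a: dict[str, float], b: dict[str, float], norm: str = "cosine"
) -> float:
    """Distance between two term vectors; missing terms count as 0.

    Cosine distance is 1 - cosine similarity and lies in [0, 1] for
    non-negative weights.  Euclidean distance is returned raw here; callers
    building a matrix rescale by the corpus maximum (see similarity_matrix).
    Two all-zero vectors are maximally dissimilar by convention.
    """
    if norm not in ("cosine", "euclidean"):
        raise ValueError(f"unknown norm {norm!r}")
    na = math.sqrt(sum(w * w for w in a.values()))
    nb = math.sqrt(sum(w * w for w in b.values()))
    if norm == "cosine":
        if na == 0.0 or nb == 0.0:
            logger.warning("all-zero term vector; cosine distance set to 1")
            return 1.0
        dot = sum(w * b.get(t, 0.0) for t, w in a.items())
        return 1.0 - dot / (na * nb)
    # euclidean
    if na == 0.0 and nb == 0.0:
        logger.warning("two all-zero term vectors; euclidean distance set to 1")
        return 1.0
    terms = set(a) | set(b)
    return math.sqrt(sum((a.get(t, 0.0) - b.get(t, 0.0)) ** 2 for t in terms))


def tanimoto(ma: frozenset[str] | set[str], mb: frozenset[str] | set[str]) -> float:
    """Tanimoto (Jaccard) similarity |Ma ∩ Mb| / |Ma ∪ Mb|.

    Two empty keyword sets are indistinguishable and score 1; an empty set
    against a non-empty one scores 0.
    """
    if not ma and not mb:
        logger.info("tanimoto on two empty keyword sets -> 1")
        return 1.0
    union = len(set(ma) | set(mb))
    inter = len(set(ma) & set(mb))
    return inter / union


def journal_distance(a: Document, b: Document) -> int:
    """0 if the two documents share a journal (case-insensitive), else 1."""
    if not a.journal or not b.journal:
        logger.warning("missing journal on %s or %s; distance 1", a.id, b.id)
        return 1
    return 0 if a.journal.strip().lower() == b.journal.strip().lower() else 1


# ---------------------------------------------------------------------------
# Similarity matrix
# ---------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise document similarity with an id index."""

    ids: list[str]
    values: np.ndarray
    normalized: bool = False
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id index")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        self._index = {d: i for i, d in enumerate(self.ids)}

    def get(self, x: str, y: str) -> float:
        return float(self.values[self._index[x], self._index[y]])

    def normalize(self) -> "SimilarityMatrix":
        """Rescale by the maximum value if any entry exceeds 1."""
        vmax = float(self.values.max(initial=0.0))
        if vmax > 1.0:
            return SimilarityMatrix(
                self.ids, self.values / vmax, normalized=True, measure=self.measure
            )
        return SimilarityMatrix(
            self.ids, self.values.copy(), normalized=True, measure=self.measure
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, d in enumerate(self.ids):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{d}\t{row}\n")


def similarity_matrix(
    corpus: list[Document],
    measure: str = "d1",
    norm: str = "cosine",
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> SimilarityMatrix:
    """Pairwise similarity under d1, d2 or d3, normalised to [0, 1].

    d1(x,y) = (d_V(x,y) + d_J(x,y)) / 2 and d2 = d_V are distances and are
    stored as 1 - d; d3 is the keyword Tanimoto similarity, stored directly.
    """
    if len(corpus) < 2:
        raise ValueError("nothing to compare: corpus has fewer than 2 documents")
    if measure not in ("d1", "d2", "d3"):
        raise ValueError(f"unknown measure {measure!r}")

    ids = [d.id for d in corpus]
    n = len(corpus)
    sim = np.eye(n)

    if measure == "d3":
        for i in range(n):
            for j in range(i + 1, n):
                sim[i, j] = sim[j, i] = tanimoto(
                    corpus[i].keywords, corpus[j].keywords
                )
    else:
        vectors = tfidf_vectors(corpus, stopwords)
        dv = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dv[i, j] = dv[j, i] = vector_distance(
                    vectors[ids[i]], vectors[ids[j]], norm
                )
        if norm == "euclidean":
            dmax = dv.max(initial=0.0)
            if dmax > 0:
                dv = dv / dmax
        if measure == "d1":
            dj = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    dj[i, j] = dj[j, i] = journal_distance(corpus[i], corpus[j])
            dist = (dv + dj) / 2.0
        else:
            dist = dv
        sim = 1.0 - dist
        np.fill_diagonal(sim, 1.0)

    m = SimilarityMatrix(ids, sim, measure=measure)
    return m.normalize()
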