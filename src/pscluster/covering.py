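"""Pseudostable-tuple coverings: the soft-clustering data model and the
greedy eliminator.

A covering assigns every document either to a stable set (a cluster) of the
conflict graph or to the inner position of a 3-node blue path bridging two
clusters (a "bridge" document, softly assigned to both).  A *multiple
pseudostable tuple* bundles two stable sets D1, D2 with all the disjoint
blue paths running between them; a tuple may also be a bare stable set
(D2 = ∅).  The tuple value ζ is 1 for a bare set and 2 otherwise; summing ζ
with a correction for stable sets shared between tuples yields the number
of distinct clusters, the quantity both the greedy heuristic and the exact
integer program minimise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .coloring import Coloring, validate_coloring
from .graph import ConflictGraph, edge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsPath:
    """Blue 3-node path; the inner node is the softly assigned document."""

    endpoint_a: str
    inner: str
    endpoint_b: str

    def __post_init__(self) -> None:
        if len({self.endpoint_a, self.inner, self.endpoint_b}) != 3:
            raise ValueError("path nodes must be distinct")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset((self.endpoint_a, self.inner, self.endpoint_b))


@dataclass
class PsTuple:
    """Two stable sets plus the blue paths bridging them (D2 may be empty)."""

    D1: frozenset[str]
    D2: frozenset[str] = frozenset()
    paths: tuple[PsPath, ...] = ()

    def __post_init__(self) -> None:
        self.D1 = frozenset(self.D1)
        self.D2 = frozenset(self.D2)
        self.paths = tuple(self.paths)
        if not self.D1:
            raise ValueError("D1 must be non-empty")
        if bool(self.D2) != bool(self.paths):
            raise ValueError("D2 is empty iff the tuple has no paths")

    @property
    def zeta(self) -> int:
        return 2 if self.D2 else 1

    @property
    def nodes(self) -> frozenset[str]:
        out = set(self.D1) | set(self.D2)
        for p in self.paths:
            out |= p.nodes
        return frozenset(out)


@dataclass
class Covering:
    """A set of pseudostable tuples covering every node of the graph."""

    tuples: list[PsTuple] = field(default_factory=list)

    @property
    def stable_sets(self) -> list[frozenset[str]]:
        """Distinct stable sets across all tuples, in first-seen order."""
        seen: list[frozenset[str]] = []
        for t in self.tuples:
            for d in (t.D1, t.D2):
                if d and d not in seen:
                    seen.append(d)
        return seen

    @property
    def paths(self) -> list[PsPath]:
        return [p for t in self.tuples for p in t.paths]

    def inner_nodes(self) -> set[str]:
        return {p.inner for p in self.paths}

    def covered_nodes(self) -> set[str]:
        out: set[str] = set()
        for t in self.tuples:
            out |= t.nodes
        return out

    @property
    def num_clusters(self) -> int:
        return len(self.stable_sets)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        sets = self.stable_sets
        index = {s: i for i, s in enumerate(sets)}
        bridges = []
        for t in self.tuples:
            for p in t.paths:
                bridges.append(
                    {
                        "doc": p.inner,
                        "path": [p.endpoint_a, p.inner, p.endpoint_b],
                        "clusters": [index[t.D1], index[t.D2]],
                    }
                )
        payload = {
            "clusters": [sorted(s) for s in sets],
            "bridges": sorted(bridges, key=lambda b: b["doc"]),
            "weight": covering_weight(self),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Covering":
        payload = json.loads(text)
        sets = [frozenset(s) for s in payload["clusters"]]
        by_pair: dict[tuple[int, int], list[PsPath]] = {}
        for b in payload["bridges"]:
            a, v, w = b["path"]
            i, j = b["clusters"]
            by_pair.setdefault((i, j), []).append(PsPath(a, v, w))
        tuples = []
        in_tuple: set[int] = set()
        for (i, j), paths in sorted(by_pair.items()):
            tuples.append(PsTuple(sets[i], sets[j], tuple(paths)))
            in_tuple |= {i, j}
        for i, s in enumerate(sets):
            if i not in in_tuple:
                tuples.append(PsTuple(s))
        return cls(tuples)


def covering_weight(c: Covering) -> int:
    """Total tuple value with shared stable sets counted only once.

    Each tuple contributes ζ (1 for a bare stable set, 2 when it joins two
    sets); a stable set occurring in several tuples is corrected by -1 per
    duplicated occurrence so the weight equals the number of distinct
    clusters.  For a chain of tuples (A,B), (B,C) sharing B this gives
    2 + 2 - 1 = 3.
    """
    slots: list[frozenset[str]] = []
    for t in c.tuples:
        slots.append(t.D1)
        if t.D2:
            slots.append(t.D2)
    total_zeta = sum(t.zeta for t in c.tuples)
    assert total_zeta == len(slots)
    return total_zeta - (len(slots) - len(set(slots)))


# ---------------------------------------------------------------------------
# Greedy eliminator
# ---------------------------------------------------------------------------


def _group_into_tuples(
    classes: dict[int, set[str]], raw_paths: list[tuple[str, str, str, int, int]]
) -> Covering:
    """Assemble tuples: paths grouped per unordered pair of surviving classes.

    ``raw_paths`` entries are (v, u, w, class_of_v, class_of_w).  Classes
    bridged by no path become bare tuples.  Paths within a tuple must be
    pairwise node-disjoint, so paths over the same class pair that share a
    node are split first-fit into several tuples over the same pair of sets.
    """
    sets = {c: frozenset(members) for c, members in classes.items() if members}
    by_pair: dict[tuple[int, int], list[PsPath]] = {}
    for v, u, w, cv, cw in raw_paths:
        a, b = (cv, cw) if cv <= cw else (cw, cv)
        ea, eb = (v, w) if cv <= cw else (w, v)
        by_pair.setdefault((a, b), []).append(PsPath(ea, u, eb))
    tuples: list[PsTuple] = []
    used: set[int] = set()
    for (a, b), paths in sorted(by_pair.items()):
        groups: list[tuple[set[str], list[PsPath]]] = []
        for p in sorted(paths, key=lambda p: p.inner):
            for nodes_seen, members in groups:
                if not nodes_seen & p.nodes:
                    nodes_seen |= p.nodes
                    members.append(p)
                    break
            else:
                groups.append((set(p.nodes), [p]))
        for _, members in groups:
            tuples.append(PsTuple(sets[a], sets[b], tuple(members)))
        used |= {a, b}
    for c in sorted(sets):
        if c not in used:
            tuples.append(PsTuple(sets[c]))
    return Covering(tuples)


def greedy_cover(g: ConflictGraph, start: Coloring) -> Covering:
    """Eliminate stable sets of a proper coloring via blue bridging paths.

    Color classes are visited in ascending size (small classes are cheapest
    to empty); within a class, nodes in lexicographic order.  A node u that
    lies on blue edges, is not already a path endpoint and has two blue
    neighbours v, w in two *different* surviving classes — neither already
    an inner node or endpoint — is removed from its class and becomes the
    inner node of the path [v, u, w].  Emptied classes disappear, so the
    cluster count never exceeds the start coloring's color count.
    """
    ok, violations = validate_coloring(g, start)
    if not ok:
        raise ValueError(f"start coloring is not proper: {violations[:3]}")

    classes = {c: set(members) for c, members in start.classes().items()}
    cls_of = dict(start.assignment)
    blue_adj = g.blue_adjacency()

    ende: set[str] = set()   # nodes serving as a path endpoint
    inner: set[str] = set()  # nodes removed into the inner position
    raw_paths: list[tuple[str, str, str, int, int]] = []

    order = sorted(classes, key=lambda c: (len(classes[c]), min(classes[c])))
    for c in order:
        for u in sorted(set(classes.get(c, ()))):
            if u not in classes.get(c, ()):  # pragma: no cover - defensive
                continue
            if u in ende or u in inner:
                continue
            candidates = [
                x for x in sorted(blue_adj[u])
                if x not in inner and x not in ende and x in cls_of
                and x not in inner
            ]
            found = None
            for ai in range(len(candidates)):
                for bi in range(ai + 1, len(candidates)):
                    v, w = candidates[ai], candidates[bi]
                    if cls_of[v] != cls_of[w]:
                        found = (v, w)
                        break
                if found:
                    break
            if found is None:
                continue
            v, w = found
            classes[c].discard(u)
            del cls_of[u]
            inner.add(u)
            ende.add(v)
            ende.add(w)
            raw_paths.append((v, u, w, cls_of[v], cls_of[w]))
            if not classes[c]:
                del classes[c]

    covering = _group_into_tuples(classes, raw_paths)
    logger.info(
        "greedy: %d start colors -> %d clusters, %d bridges",
        start.num_colors, covering.num_clusters, len(covering.paths),
    )
    return covering


# ---------------------------------------------------------------------------
# Validation and reporting
# ---------------------------------------------------------------------------


def _is_stable(s: frozenset[str], g: ConflictGraph) -> bool:
    members = sorted(s)
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            if g.has_edge(members[a], members[b]):
                return False
    return True


def validate_covering(
    c: Covering, g: ConflictGraph, allow_shared_inner: bool = False
) -> tuple[bool, list[str]]:
    """Check every tuple/covering invariant against the graph.

    With ``allow_shared_inner`` (the relaxed covering problem) an inner node
    may appear in several tuples' paths; otherwise in exactly one.
    """
    violations: list[str] = []
    for ti, t in enumerate(c.tuples):
        for name, d in (("D1", t.D1), ("D2", t.D2)):
            if d and not d <= g.nodes:
                violations.append(f"tuple {ti}: {name} has nodes outside the graph")
            if d and not _is_stable(d, g):
                violations.append(f"tuple {ti}: {name} not stable")
        seen_path_nodes: set[str] = set()
        for p in t.paths:
            if edge(p.endpoint_a, p.inner) not in g.blue_edges or \
               edge(p.inner, p.endpoint_b) not in g.blue_edges:
                violations.append(f"tuple {ti}: path {p} not blue")
            if p.endpoint_a not in t.D1:
                violations.append(f"tuple {ti}: path {p} endpoint_a not in D1")
            if p.endpoint_b not in t.D2:
                violations.append(f"tuple {ti}: path {p} endpoint_b not in D2")
            if seen_path_nodes & p.nodes:
                violations.append(f"tuple {ti}: paths not pairwise disjoint at {p}")
            seen_path_nodes |= p.nodes
    uncovered = g.nodes - c.covered_nodes()
    if uncovered:
        violations.append(f"nodes not covered: {sorted(uncovered)}")
    counts: dict[str, int] = {}
    for p in c.paths:
        counts[p.inner] = counts.get(p.inner, 0) + 1
    if not allow_shared_inner:
        for v, k in sorted(counts.items()):
            if k != 1:
                violations.append(f"inner node {v} appears in {k} paths")
    return (not violations, violations)


def strict_variant_check(c: Covering) -> dict:
    """Classify the covering against the strict problem variants.

    Builds the quotient graph (nodes = distinct stable sets, one edge per
    tuple with D2 ≠ ∅) and reports whether it is acyclic and whether every
    node has degree ≤ 2 — the restrictions of the strict variants.  Purely
    informational; nothing is enforced.
    """
    import networkx as nx

    sets = c.stable_sets
    index = {s: i for i, s in enumerate(sets)}
    q = nx.MultiGraph()
    q.add_nodes_from(range(len(sets)))
    for t in c.tuples:
        if t.D2:
            q.add_edge(index[t.D1], index[t.D2])
    acyclic = nx.is_forest(q) if q.number_of_edges() else True
    max_deg = max((d for _, d in q.degree()), default=0)
    return {
        "acyclic": acyclic,
        "max_degree": max_deg,
        "degrees_le_2": max_deg <= 2,
        "satisfies_strict_restrictions": acyclic and max_deg <= 2,
    }


def soft_assignments(c: Covering) -> dict[str, dict]:
    """Map each document to its cluster id(s); bridge documents get two."""
    sets = c.stable_sets
    index = {s: i for i, s in enumerate(sets)}
    out: dict[str, dict] = {}
    for s in sets:
        for v in s:
            out.setdefault(v, {"clusters": [], "bridge": False})
            if index[s] not in out[v]["clusters"]:
                out[v]["clusters"].append(index[s])
    for t in c.tuples:
        for p in t.paths:
            entry = out.setdefault(p.inner, {"clusters": [], "bridge": False})
            entry["bridge"] = True
            for cid in (index[t.D1], index[t.D2]):
                if cid not in entry["clusters"]:
                    entry["clusters"].append(cid)
    for entry in out.values():
        entry["clusters"].sort()
    return out


def covering_from_coloring(coloring: Coloring) -> Covering:
    """Hard clustering: each color class is one bare tuple."""
    return _group_into_tuples(
        {c: set(m) for c, m in coloring.classes().items()}, []
    )
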