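"""Exact minimisation of the cluster count via an integer linear program.

The model is a coloring-style formulation: binary x_{i,k} assigns node i to
color k, where positive colors are stable sets (clusters) and the reserved
color 0 marks inner nodes of blue bridging paths; binary y_k flags whether
color k is used.  Minimising Σ y_k minimises the number of clusters.

Constraints: every node takes exactly one color (incl. 0); x_{i,k} ≤ y_k;
no edge of any color is monochromatic in a positive color; color 0 is
admissible only for nodes of the blue subgraph that are the centre of at
least one blue 3-node path (the guard closing the gap that would otherwise
let a pathless node take color 0).  Symmetry is broken with y_k ≥ y_{k+1}.

Two readings of the path conditions are provided.  The default ``exact``
formulation introduces a witness variable z_t per path: an inner node needs
at least one witness path whose endpoints take distinct positive colors —
exactly what a valid covering requires, so every greedy covering remains
feasible and the optimum never exceeds the greedy cluster count.  The
``printed`` formulation instead forces *every* path at an inner node to
have non-monochromatic, non-inner endpoints (and at most one inner node on
any path); this is stricter than the covering semantics — it even forbids
two blue-adjacent inner nodes — and can exceed a valid covering's cluster
count, so it is kept only for reference.

Solved with scipy's HiGHS-backed ``milp``.  A seeded backtracking oracle
(`brute_force_optimum`) provides independent optima for tiny instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .coloring import Coloring
from .covering import Covering, _group_into_tuples
from .graph import BlueTriple, ConflictGraph

logger = logging.getLogger(__name__)


@dataclass
class IlpModel:
    nodes: list[str]
    K: int
    triples: list[BlueTriple]
    formulation: str            # "exact" (witness paths) or "printed"
    c: np.ndarray               # objective coefficients
    A: sparse.csr_matrix        # constraint matrix
    lb: np.ndarray
    ub: np.ndarray
    var_ub: np.ndarray          # per-variable upper bounds (0/1)
    row_tags: list[str] = field(default_factory=list)

    def x_index(self, i: int, k: int) -> int:
        return i * (self.K + 1) + k

    def y_index(self, k: int) -> int:
        return len(self.nodes) * (self.K + 1) + (k - 1)

    def z_index(self, t: int) -> int:
        if self.formulation != "exact":
            raise ValueError("witness variables exist only in the exact formulation")
        return len(self.nodes) * (self.K + 1) + self.K + t

    @property
    def num_vars(self) -> int:
        n_z = len(self.triples) if self.formulation == "exact" else 0
        return len(self.nodes) * (self.K + 1) + self.K + n_z

    def write_lp(self, path) -> None:
        """Dump the model in CPLEX LP text format for debugging."""
        names = []
        for i, v in enumerate(self.nodes):
            for k in range(self.K + 1):
                names.append(f"x_{i}_{k}")
        for k in range(1, self.K + 1):
            names.append(f"y_{k}")
        if self.formulation == "exact":
            for t in range(len(self.triples)):
                names.append(f"z_{t}")
        lines = ["Minimize", " obj: " + " + ".join(
            names[j] for j in range(self.num_vars) if self.c[j]
        ), "Subject To"]
        A = self.A.tocsr()
        for r in range(A.shape[0]):
            row = A.getrow(r)
            terms = " + ".join(
                (f"{int(val)} {names[j]}" if val != 1 else names[j]).replace("+ -", "- ")
                for j, val in zip(row.indices, row.data)
            ).replace("+ -1 ", "- ")
            tag = self.row_tags[r] if r < len(self.row_tags) else f"c{r}"
            if self.lb[r] == self.ub[r]:
                lines.append(f" {tag}_{r}: {terms} = {int(self.lb[r])}")
            else:
                if np.isfinite(self.ub[r]):
                    lines.append(f" {tag}_{r}: {terms} <= {int(self.ub[r])}")
                if np.isfinite(self.lb[r]):
                    lines.append(f" {tag}_{r}_lb: {terms} >= {int(self.lb[r])}")
        lines.append("Binaries")
        fixed = [names[j] for j in range(self.num_vars) if self.var_ub[j] == 0]
        lines.append(" " + " ".join(n for n in names))
        if fixed:
            lines.append("\\ fixed to 0 via bounds: " + " ".join(fixed))
        lines.append("End")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class IlpSolution:
    status: str                     # optimal | feasible | infeasible | timeout
    objective: int | None           # number of colors used
    colors: dict[str, int] | None   # node -> 0..K


def _greedy_clique_lower_bound(g: ConflictGraph) -> int:
    adj = g.adjacency()
    best = 1 if g.nodes else 0
    for v in sorted(g.nodes):
        clique = {v}
        for w in sorted(adj[v], key=lambda x: -len(adj[x])):
            if all(w in adj[c] for c in clique):
                clique.add(w)
        best = max(best, len(clique))
    return best


def build_ilp(
    g: ConflictGraph,
    triples: list[BlueTriple] | None = None,
    K: int | None = None,
    formulation: str = "exact",
) -> IlpModel:
    """Assemble the integer program for a graph and its blue 3-node paths.

    K defaults to the number of nodes; callers typically pass the color
    count of a heuristic coloring (a valid upper bound that shrinks the
    model without affecting the optimum).  ``formulation`` selects the
    path semantics (see module docstring).
    """
    from .graph import enumerate_blue_triples

    if formulation not in ("exact", "printed"):
        raise ValueError(f"unknown formulation {formulation!r}")
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    if triples is None:
        triples = enumerate_blue_triples(g)
    if K is None:
        K = len(nodes)
    if K < 1:
        raise ValueError("K must be >= 1")
    lbound = _greedy_clique_lower_bound(g)
    if K < lbound:
        logger.warning(
            "K=%d below greedy clique bound %d; model may be infeasible", K, lbound
        )

    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    n_vars = n * (K + 1) + K + (len(triples) if formulation == "exact" else 0)
    m = IlpModel(
        nodes=nodes, K=K, triples=list(triples), formulation=formulation,
        c=np.zeros(n_vars), A=sparse.csr_matrix((0, 0)),
        lb=np.array([]), ub=np.array([]), var_ub=np.ones(n_vars),
    )
    for k in range(1, K + 1):
        m.c[m.y_index(k)] = 1.0

    # color 0 admissible only for triple centres within B
    centers = {t.v for t in triples}
    blue = g.blue_nodes()
    for v in nodes:
        if v not in blue or v not in centers:
            m.var_ub[m.x_index(idx[v], 0)] = 0.0

    rows, cols, data, lb, ub, tags = [], [], [], [], [], []

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float, tag: str):
        r = len(lb)
        for j, val in entries:
            rows.append(r)
            cols.append(j)
            data.append(val)
        lb.append(lo)
        ub.append(hi)
        tags.append(tag)

    # each node gets exactly one color (0..K)
    for v in nodes:
        i = idx[v]
        add_row([(m.x_index(i, k), 1.0) for k in range(K + 1)], 1.0, 1.0, "one_color")
    # linking x <= y
    for v in nodes:
        i = idx[v]
        for k in range(1, K + 1):
            add_row([(m.x_index(i, k), 1.0), (m.y_index(k), -1.0)],
                    -np.inf, 0.0, "link")
    # proper coloring on every edge, positive colors
    for e in sorted(g.edges, key=sorted):
        u, w = sorted(e)
        for k in range(1, K + 1):
            add_row([(m.x_index(idx[u], k), 1.0), (m.x_index(idx[w], k), 1.0)],
                    -np.inf, 1.0, "edge")
    if formulation == "printed":
        # a color-0 centre forbids monochromatic endpoints on all its paths
        for t in triples:
            for k in range(1, K + 1):
                add_row(
                    [(m.x_index(idx[t.i], k), 1.0), (m.x_index(idx[t.j], k), 1.0),
                     (m.x_index(idx[t.v], 0), 1.0)],
                    -np.inf, 2.0, "path_hetero",
                )
            # at most one node of any path is an inner node
            add_row(
                [(m.x_index(idx[t.i], 0), 1.0), (m.x_index(idx[t.j], 0), 1.0),
                 (m.x_index(idx[t.v], 0), 1.0)],
                -np.inf, 1.0, "path_single_inner",
            )
    else:
        # exact: an inner node needs at least one witness path whose
        # endpoints take distinct positive colors
        by_center: dict[str, list[int]] = {}
        for tix, t in enumerate(triples):
            by_center.setdefault(t.v, []).append(tix)
        for v, tixs in sorted(by_center.items()):
            add_row(
                [(m.x_index(idx[v], 0), 1.0)]
                + [(m.z_index(tix), -1.0) for tix in tixs],
                -np.inf, 0.0, "witness_exists",
            )
        for tix, t in enumerate(triples):
            # a witness is only meaningful for an inner centre
            add_row([(m.z_index(tix), 1.0), (m.x_index(idx[t.v], 0), -1.0)],
                    -np.inf, 0.0, "witness_center")
            # witness endpoints are not inner nodes themselves
            add_row([(m.z_index(tix), 1.0), (m.x_index(idx[t.i], 0), 1.0)],
                    -np.inf, 1.0, "witness_end_a")
            add_row([(m.z_index(tix), 1.0), (m.x_index(idx[t.j], 0), 1.0)],
                    -np.inf, 1.0, "witness_end_b")
            # witness endpoints are not monochromatic
            for k in range(1, K + 1):
                add_row(
                    [(m.x_index(idx[t.i], k), 1.0),
                     (m.x_index(idx[t.j], k), 1.0), (m.z_index(tix), 1.0)],
                    -np.inf, 2.0, "witness_hetero",
                )
    # symmetry breaking y_k >= y_{k+1}
    for k in range(1, K):
        add_row([(m.y_index(k + 1), 1.0), (m.y_index(k), -1.0)],
                -np.inf, 0.0, "symmetry")

    m.A = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(lb), m.num_vars)
    )
    m.lb = np.array(lb)
    m.ub = np.array(ub)
    m.row_tags = tags
    return m


def solve_ilp(m: IlpModel, time_limit: float | None = None) -> IlpSolution:
    """Solve the model; never raises on infeasibility."""
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=m.c,
        constraints=LinearConstraint(m.A, m.lb, m.ub),
        integrality=np.ones(m.num_vars),
        bounds=Bounds(np.zeros(m.num_vars), m.var_ub),
        options=options,
    )
    if res.status == 2:
        return IlpSolution("infeasible", None, None)
    if res.x is None:
        return IlpSolution("timeout", None, None)
    status = "optimal" if res.status == 0 else "feasible"
    x = np.round(res.x).astype(int)
    colors = {}
    for i, v in enumerate(m.nodes):
        k = int(np.argmax([x[m.x_index(i, k)] for k in range(m.K + 1)]))
        colors[v] = k
    objective = int(sum(x[m.y_index(k)] for k in range(1, m.K + 1)))
    return IlpSolution(status, objective, colors)


def solve_graph(
    g: ConflictGraph,
    K: int | None = None,
    time_limit: float | None = None,
    formulation: str = "exact",
) -> IlpSolution:
    """Convenience wrapper: build and solve in one step."""
    from .graph import enumerate_blue_triples

    triples = enumerate_blue_triples(g)
    return solve_ilp(build_ilp(g, triples, K, formulation), time_limit)


def extract_covering(
    s: IlpSolution, g: ConflictGraph, triples: list[BlueTriple] | None = None
) -> Covering:
    """Turn an ILP solution's colors into a pseudostable-tuple covering.

    Positive color classes become stable sets; every color-0 node is attached
    to its smallest-id path whose endpoints are positively and differently
    colored (guaranteed to exist by the model's guard and path constraints).
    """
    from .graph import enumerate_blue_triples

    if s.colors is None:
        raise ValueError(f"solution has no assignment (status {s.status})")
    if triples is None:
        triples = enumerate_blue_triples(g)
    classes: dict[int, set[str]] = {}
    zeros = []
    for v, k in s.colors.items():
        if k == 0:
            zeros.append(v)
        else:
            classes.setdefault(k, set()).add(v)
    raw_paths = []
    by_center: dict[str, list[BlueTriple]] = {}
    for t in triples:
        by_center.setdefault(t.v, []).append(t)
    for v in sorted(zeros):
        chosen = None
        for t in sorted(by_center.get(v, [])):
            ci, cj = s.colors[t.i], s.colors[t.j]
            if ci > 0 and cj > 0 and ci != cj:
                chosen = t
                break
        if chosen is None:
            raise RuntimeError(
                f"no valid path for inner node {v}: model consistency bug"
            )
        raw_paths.append(
            (chosen.i, v, chosen.j, s.colors[chosen.i], s.colors[chosen.j])
        )
    return _group_into_tuples(classes, raw_paths)


def coloring_from_solution(s: IlpSolution) -> Coloring:
    """Positive color classes as a Coloring (inner nodes excluded)."""
    if s.colors is None:
        raise ValueError("solution has no assignment")
    return Coloring({v: k for v, k in s.colors.items() if k > 0}).renumbered()


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_optimum(
    g: ConflictGraph, max_n: int = 9, formulation: str = "exact"
) -> int:
    """Exhaustive minimum cluster count under the same semantics as the ILP.

    Enumerates assignments node -> {0, 1, ..., t} by backtracking with
    symmetry breaking, for increasing t, and returns the smallest number of
    positive colors admitting a feasible assignment.  Color 0 is allowed
    only for blue 3-node-path centres.  Under ``exact`` semantics every
    color-0 node needs at least one path centred at it whose endpoints take
    distinct positive colors; under ``printed`` semantics every path at a
    color-0 node must have non-monochromatic endpoints and no path carries
    two color-0 nodes.
    """
    from .graph import enumerate_blue_triples

    if formulation not in ("exact", "printed"):
        raise ValueError(f"unknown formulation {formulation!r}")
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n > max_n:
        raise ValueError(f"brute force refused for n={n} > max_n={max_n}")
    if n == 0:
        return 0
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[idx[w] for w in g.neighbors(v)] for v in nodes]
    triples = enumerate_blue_triples(g)
    tr = [(idx[t.i], idx[t.v], idx[t.j]) for t in triples]
    centers = {v for _, v, _ in tr}
    triples_of: list[list[int]] = [[] for _ in range(n)]   # any role
    centered_at: list[list[int]] = [[] for _ in range(n)]  # centre role
    for tix, (i, v, j) in enumerate(tr):
        centered_at[v].append(tix)
        for node in (i, v, j):
            triples_of[node].append(tix)

    def printed_triple_ok(assign: list[int], tix: int) -> bool:
        i, v, j = tr[tix]
        known = [x for x in (assign[i], assign[v], assign[j]) if x >= 0]
        if sum(1 for x in known if x == 0) > 1:
            return False
        if assign[v] == 0 and assign[i] > 0 and assign[i] == assign[j]:
            return False
        return True

    def witness_possible(assign: list[int], center: int) -> bool:
        """Some path at this color-0 centre can still become a witness."""
        for tix in centered_at[center]:
            i, _, j = tr[tix]
            a, b = assign[i], assign[j]
            if a == 0 or b == 0:
                continue
            if a > 0 and b > 0 and a == b:
                continue
            return True  # valid now, or still undecided
        return False

    def ok_after(assign: list[int], pos: int) -> bool:
        if formulation == "printed":
            return all(printed_triple_ok(assign, tix) for tix in triples_of[pos])
        # exact: re-check every color-0 centre whose paths involve pos
        affected = {pos} | {tr[tix][1] for tix in triples_of[pos]}
        for v in affected:
            if assign[v] == 0 and not witness_possible(assign, v):
                return False
        return True

    def feasible(t: int) -> bool:
        assign = [-1] * n

        def bt(pos: int, max_used: int) -> bool:
            if pos == n:
                return True
            options = []
            if pos in centers:
                options.append(0)
            options.extend(range(1, min(max_used + 1, t) + 1))
            for c in options:
                if c > 0 and any(assign[w] == c for w in adj[pos]):
                    continue
                assign[pos] = c
                if ok_after(assign, pos) and bt(pos + 1, max(max_used, c)):
                    return True
                assign[pos] = -1
            return False

        return bt(0, 0)

    for t in range(1, n + 1):
        if feasible(t):
            return t
    raise RuntimeError("no feasible assignment found")  # pragma: no cover
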