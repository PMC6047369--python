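"""Choosing the similarity thresholds ε and ι.

Two routes: an *external* criterion targets a desired cluster count via a
chromatic upper bound (in practice the SLF heuristic's color count stands in
for it), bisecting ε over the observed similarity values; an *internal*
criterion derives the thresholds from cannot-link document pairs that must
end up in different clusters.
"""

from __future__ import annotations

import logging
import math

from .coloring import slf_coloring
from .graph import build_graph
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


def chromatic_upper_bound(n: int, e: int, formula: str = "corrected") -> int | None:
    """Edge-count upper bound on the chromatic number.

    ``corrected`` plugs the complement's edge count ē = n(n-1)/2 - e into the
    clique-cover bound, which simplifies to ⌊(1 + √(8e + 1)) / 2⌋.
    ``printed`` evaluates ⌊(1 + √(-4n² - 4n + 8e + 1)) / 2⌋ (which substitutes
    n² - e for ē) and returns None whenever its radicand is negative.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    max_e = n * (n - 1) // 2
    if not 0 <= e <= max_e:
        raise ValueError(f"edge count {e} out of range [0, {max_e}]")
    if formula == "corrected":
        return int((1 + math.sqrt(8 * e + 1)) // 2) if e else 1
    if formula == "printed":
        radicand = -4 * n * n - 4 * n + 8 * e + 1
        if radicand < 0:
            return None
        return int((1 + math.sqrt(radicand)) // 2)
    raise ValueError(f"unknown formula {formula!r}")


def estimate_eps_for_k(
    sim: SimilarityMatrix,
    k: int,
    iota_fraction: float = 0.5,
    max_iter: int = 32,
) -> tuple[float, float]:
    """Bisect ε over the observed similarity values to hit k clusters.

    At each candidate ε the graph is built with ι = iota_fraction · ε and
    the SLF heuristic's color count u serves as the cluster-count estimate;
    u is non-decreasing in ε (more edges, never fewer).  Returns the (ε, ι)
    whose u is closest to k, preferring the smaller ε on ties.
    """
    n = len(sim.ids)
    if not 1 <= k <= n:
        raise ValueError(f"target k={k} outside [1, {n}]")
    if not 0 < iota_fraction <= 1:
        raise ValueError("iota_fraction must lie in (0, 1]")
    if not sim.normalized:
        sim = sim.normalize()
    offdiag = [
        float(sim.values[i, j]) for i in range(n) for j in range(i + 1, n)
    ]
    values = sorted({v for v in offdiag if v > 0})
    if not values:
        # every pair at similarity 0: any positive eps gives the same graph
        values = [1.0]
    # a candidate strictly below the smallest observed similarity allows the
    # edgeless graph (k = 1) to be reached when no pair sits at similarity 0
    values = [values[0] / 2] + values

    def colors_at(eps: float) -> int:
        iota = max(iota_fraction * eps, 1e-12)
        g = build_graph(sim, eps=eps, iota=iota)
        return slf_coloring(g).num_colors

    lo, hi = 0, len(values) - 1
    best: tuple[int, float, float] | None = None  # (|u-k|, eps, iota)
    trace = []
    for _ in range(max_iter):
        mid = (lo + hi) // 2
        eps = values[mid]
        u = colors_at(eps)
        trace.append((eps, u))
        cand = (abs(u - k), eps, max(iota_fraction * eps, 1e-12))
        if best is None or cand[0] < best[0] or (cand[0] == best[0] and eps < best[1]):
            best = cand
        if u == k or lo >= hi:
            break
        if u > k:
            hi = mid - 1
        else:
            lo = mid + 1
        if lo > hi:
            break
    assert best is not None
    logger.info("eps search trace: %s", trace)
    if best[0] != 0:
        logger.warning(
            "target k=%d not reached exactly; best color count differs by %d",
            k, best[0],
        )
    return best[1], best[2]


def bounds_from_cannot_link(
    sim: SimilarityMatrix, pairs: list[tuple[str, str]]
) -> tuple[float, float]:
    """ε and ι from document pairs required to land in different clusters.

    ε is the maximum similarity over the pairs (inclusive, so every listed
    pair receives an edge under the rule sim ≤ ε) and ι the minimum, making
    the pairs at similarity ≥ ι blue and the rest black.
    """
    if not pairs:
        raise ValueError("need at least one cannot-link pair")
    sims = []
    for a, b in pairs:
        try:
            sims.append(sim.get(a, b))
        except KeyError as exc:
            raise ValueError(f"unknown document id in pair ({a}, {b})") from exc
    eps, iota = max(sims), min(sims)
    if eps <= 0:
        raise ValueError("all cannot-link pairs have similarity 0; any ε works")
    if iota <= 0:
        # a pair at similarity 0 must come out black, which needs ι > 0
        iota = eps * 1e-9
        logger.info("minimum pair similarity is 0; ι clamped to %g", iota)
    return eps, iota
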