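"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — plain enumeration or direct formula
evaluation — and shares no code with the implementations under test.
"""

from __future__ import annotations

import itertools
from collections import Counter
from functools import lru_cache


def enumerate_align_score(query: str, reference: str, match, mismatch, gap_open, gap_extend) -> int:
    """Exhaustive best score by plain recursion over every alignment path.

    Query-global, reference end-gaps free, affine cost open + k*extend.
    Exponential; only usable for very short sequences.
    """
    best = [-(10**9)]

    def rec(i: int, j: int, state: str, score: int) -> None:
        if i == len(query):
            if score > best[0]:
                best[0] = score
            return
        if j < len(reference):
            s = match if query[i] == reference[j] != "N" else mismatch
            rec(i + 1, j + 1, "M", score + s)
        pen = gap_extend + (gap_open if state != "X" else 0)
        rec(i + 1, j, "X", score + pen)
        if j < len(reference):
            pen = gap_extend + (gap_open if state != "Y" else 0)
            rec(i, j + 1, "Y", score + pen)

    for j0 in range(len(reference) + 1):
        rec(0, j0, "M", 0)
    return best[0]


def memo_align_score(query: str, reference: str, match, mismatch, gap_open, gap_extend) -> int:
    """Same exhaustive maximum as :func:`enumerate_align_score`, with caching
    so the full short-sequence sweep is tractable."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> int:
        if i == len(query):
            return 0
        options = []
        if j < len(reference):
            s = match if query[i] == reference[j] != "N" else mismatch
            options.append(s + rec(i + 1, j + 1, "M"))
            pen = gap_extend + (gap_open if state != "Y" else 0)
            options.append(pen + rec(i, j + 1, "Y"))
        pen = gap_extend + (gap_open if state != "X" else 0)
        options.append(pen + rec(i + 1, j, "X"))
        return max(options)

    return max(rec(0, j0, "M") for j0 in range(len(reference) + 1))


def brute_merge_decision(s1: str, s2_rc: str, min_overlap: int, max_mismatch_frac: float):
    """Best merge offset by scanning every candidate, or None.

    Returns (offset, overlap_len) of the accepted best overlap under the
    same score / tie rules as the implementation, computed independently.
    """
    candidates = []
    for offset in range(len(s1)):
        ov = min(len(s1) - offset, len(s2_rc))
        if ov < min_overlap:
            continue
        mm = sum(a != b for a, b in zip(s1[offset:], s2_rc[:ov]))
        if mm / ov > max_mismatch_frac:
            continue
        candidates.append(((ov - 2 * mm), ov, -offset))
    if not candidates:
        return None
    score, ov, neg = max(candidates)
    return -neg, ov


def all_a_runs(seq: str) -> list[tuple[int, int]]:
    """Every maximal A run as (start, end), by direct scan."""
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def bh_direct(pvals):
    """BH by the textbook definition q_i = min_{k: p_k >= p_i} (m * p_k / k)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = min(1.0, running)
    return q


def median_of_ratios(counts) -> list[float]:
    """Size factors by direct per-sample median of count/geomean ratios."""
    import math

    genes = [row for row in counts if all(c > 0 for c in row)]
    geo = [math.exp(sum(math.log(c) for c in row) / len(row)) for row in genes]
    n_samples = len(counts[0])
    raw = []
    for s in range(n_samples):
        ratios = sorted(row[s] / g for row, g in zip(genes, geo))
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        raw.append(med)
    geo_f = math.exp(sum(math.log(f) for f in raw) / len(raw))
    return [f / geo_f for f in raw]


def hypergeom_enumeration(n1: int, n2: int, universe: int):
    """Exact overlap mean/variance by enumerating all pairs of subsets."""
    items = range(universe)
    sizes = Counter()
    total = 0
    for a in itertools.combinations(items, n1):
        sa = set(a)
        for b in itertools.combinations(items, n2):
            sizes[len(sa.intersection(b))] += 1
            total += 1
    mean = sum(k * n for k, n in sizes.items()) / total
    var = sum((k - mean) ** 2 * n for k, n in sizes.items()) / total
    return mean, var


def poisson_wald(yt, yc):
    """Poisson-limit Wald test on normalized count means (oracle)."""
    import math

    from scipy import stats

    mt = sum(yt) / len(yt) + 0.5
    mc = sum(yc) / len(yc) + 0.5
    beta = math.log(mt) - math.log(mc)
    var = 1 / (mt * len(yt)) + 1 / (mc * len(yc))
    z = beta / math.sqrt(var)
    return beta / math.log(2), 2 * stats.norm.sf(abs(z))
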