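"""Gene-set overlap statistics for comparing transcript catalogs.

Two capped-transcript catalogs (e.g. from two capture methods, or from WT
and a deNADding-deficient mutant) are compared against a null in which the
number of significant genes is kept but their identities are randomized
over the quantified universe. :func:`permutation_overlap` draws that null
(10,000 iterations by default) and reports the observed intersection with
the permutation mean +/- SD and an add-one empirical p;
:func:`hypergeom_overlap` is its closed-form counterpart (two fixed-size
sets drawn independently from a finite universe have a hypergeometric
intersection), and :func:`chi2_independence` tests independence of the two
memberships on the 2x2 classification table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
from scipy import stats

from nadcapseq.errors import InputError


@dataclass
class OverlapResult:
    """Observed overlap against the identity-randomization null."""

    observed: int
    perm_mean: float
    perm_sd: float
    empirical_p: float
    analytic_mean: float
    analytic_sd: float
    n_iter: int
    seed: int
    chi2: float
    chi2_p: float


def permutation_overlap(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: Sequence[str],
    n_iter: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Randomize set identities over the universe and recompute the overlap.

    Each iteration independently draws |A| and |B| gene ids uniformly
    without replacement from the universe and records the intersection
    size. The empirical p uses the add-one convention
    (1 + #{perm >= observed}) / (n_iter + 1), so it is never exactly 0.
    Also fills the analytic hypergeometric mean/SD and the chi-squared
    independence test of the observed 2x2 membership table.
    """
    universe = list(universe)
    n = len(universe)
    if n == 0:
        raise InputError("empty universe")
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    a = set(set_a)
    b = set(set_b)
    if not a <= set(universe) or not b <= set(universe):
        raise InputError("sets must be subsets of the universe")
    n1, n2 = len(a), len(b)
    observed = len(a & b)

    rng = np.random.default_rng(seed)
    sizes = np.empty(n_iter, dtype=np.int64)
    in_b = np.zeros(n, dtype=bool)
    for it in range(n_iter):
        idx_a = rng.permutation(n)[:n1]
        idx_b = rng.permutation(n)[:n2]
        in_b[:] = False
        in_b[idx_b] = True
        sizes[it] = int(in_b[idx_a].sum())

    mean, sd, _ = hypergeom_overlap(n1, n2, n)
    emp_p = (1 + int((sizes >= observed).sum())) / (n_iter + 1)

    both = observed
    only_a = n1 - observed
    only_b = n2 - observed
    neither = n - n1 - n2 + observed
    table = np.array([[both, only_a], [only_b, neither]])
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, chi2_p = chi2_independence(table)
    else:
        chi2, chi2_p = float("nan"), float("nan")

    return OverlapResult(
        observed=observed,
        perm_mean=float(sizes.mean()),
        perm_sd=float(sizes.std(ddof=1)),
        empirical_p=emp_p,
        analytic_mean=mean,
        analytic_sd=sd,
        n_iter=n_iter,
        seed=seed,
        chi2=chi2,
        chi2_p=chi2_p,
    )


def hypergeom_overlap(
    n1: int, n2: int, universe_size: int, observed: int | None = None
) -> tuple[float, float, float | None]:
    """Closed-form null for the intersection of two random fixed-size sets.

    mean = n1*n2/N; var = n1*n2*(N-n1)*(N-n2) / (N^2*(N-1)). When
    ``observed`` is given, also returns the upper-tail probability
    P(overlap >= observed) from the hypergeometric mass.
    """
    n = universe_size
    if n <= 0:
        raise InputError("universe size must be positive")
    if n1 > n or n2 > n or n1 < 0 or n2 < 0:
        raise InputError("set sizes must lie in [0, universe size]")
    mean = n1 * n2 / n
    var = n1 * n2 * (n - n1) * (n - n2) / (n**2 * max(n - 1, 1))
    tail = None
    if observed is not None:
        tail = float(stats.hypergeom.sf(observed - 1, n, n1, n2))
    return float(mean), float(np.sqrt(var)), tail


def chi2_independence(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared independence test on a 2x2 table.

    No continuity correction by default; p from the chi-squared
    distribution with 1 degree of freedom.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("expected a 2x2 table")
    if (t < 0).any():
        raise InputError("table cells must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InputError("table margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def overlap_summary(
    set_a: Collection[str], set_b: Collection[str], ndigits: int = 2
) -> dict:
    """Exact set arithmetic: intersection, exclusives and shared fractions.

    Fractions are percentages of each set covered by the intersection,
    rounded to ``ndigits``.
    """
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return {
        "size_a": len(a),
        "size_b": len(b),
        "intersection": inter,
        "exclusive_a": len(a) - inter,
        "exclusive_b": len(b) - inter,
        "fraction_of_a_shared_pct": round(100 * inter / len(a), ndigits) if a else 0.0,
        "fraction_of_b_shared_pct": round(100 * inter / len(b), ndigits) if b else 0.0,
    }
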