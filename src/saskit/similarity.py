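"""Correlation-map (CorMap) style similarity testing between profiles.

Two profiles measured on the same grid are compared through the sign pattern
of their pointwise difference.  Under the null hypothesis that both measure
the same underlying curve, each sign is an independent fair coin flip, so the
length C of the longest same-sign run follows the longest-run distribution of
n Bernoulli(1/2) trials.  The reported p-value is the exact probability that
the longest run is >= C, computed by the run-length-limited counting
recurrence with Python big integers (exact for n well beyond 10^4).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .exceptions import ValidationError
from .sasdata import Profile, same_q_grid

__all__ = [
    "SimilarityResult",
    "longest_run",
    "prob_longest_run",
    "cormap_test",
    "pairwise_cormap",
    "pairwise_to_csv",
]


@dataclass(frozen=True)
class SimilarityResult:
    n_points: int
    longest_run: int
    p_value: float


def longest_run(signs) -> int:
    """Length of the longest contiguous block of identical nonzero values.

    Zeros break runs; an all-zero input has longest run 0.
    """
    s = np.asarray(signs)
    if s.size == 0:
        raise ValidationError("empty sign sequence")
    best = 0
    current = 0
    prev = 0
    for v in s:
        if v != 0 and v == prev:
            current += 1
        elif v != 0:
            current = 1
        else:
            current = 0
        prev = v
        if current > best:
            best = current
    return int(best)


@lru_cache(maxsize=None)
def _count_max_run_at_most(n: int, m: int) -> int:
    """Number of binary sequences of length n whose longest run is <= m.

    By symmetry this is twice the number of compositions of n into parts of
    size <= m (each composition is a run-length pattern; 2 choices for the
    first symbol).  Computed with an O(n) sliding-window big-int recurrence.
    """
    if m <= 0:
        return 0
    if m >= n:
        return 2 ** n
    # c[k] = compositions of k into parts <= m; c[k] = 2c[k-1] - c[k-1-m]
    c = [0] * (n + 1)
    c[0] = 1
    running = 1  # sum of c[k-m..k-1]
    for k in range(1, n + 1):
        c[k] = running
        running += c[k]
        if k - m >= 0:
            running -= c[k - m]
    return 2 * c[n]


def prob_longest_run(n: int, c: int) -> float:
    """Exact P(longest run of identical outcomes >= c) for n fair coin flips."""
    n, c = int(n), int(c)
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (1 <= c <= n):
        raise ValidationError(f"need 1 <= c <= n, got c={c}, n={n}")
    good = _count_max_run_at_most(n, c - 1)
    return float(Fraction((2 ** n) - good, 2 ** n))


def cormap_test(p1: Profile, p2: Profile, qrange=None) -> SimilarityResult:
    """Longest-run similarity test between two profiles.

    The compared points are those of the shared grid (optionally restricted
    to ``qrange = (qmin, qmax)``).  Exactly equal intensities (sign 0) break
    runs; the degenerate all-equal comparison returns C = 0, p = 1, since
    identical data can only mean duplication, not dissimilarity.
    """
    if not same_q_grid(p1.q, p2.q):
        raise ValidationError("profiles must share a q grid for comparison")
    mask = np.ones(len(p1.q), dtype=bool)
    if qrange is not None:
        qmin, qmax = qrange
        mask = (p1.q >= qmin) & (p1.q <= qmax)
    if mask.sum() < 3:
        raise ValidationError("fewer than 3 overlapping points to compare")
    diff = p1.intensity[mask] - p2.intensity[mask]
    signs = np.sign(diff).astype(int)
    n = int(mask.sum())
    c = longest_run(signs)
    p = 1.0 if c == 0 else prob_longest_run(n, c)
    return SimilarityResult(n_points=n, longest_run=c, p_value=p)


def pairwise_cormap(profiles, qrange=None):
    """All-against-all CorMap tests; returns a symmetric nested list matrix.

    Diagonal entries are defined as p = 1 with longest run 0.  No multiple-
    testing correction is applied here; callers own that decision.
    """
    m = len(profiles)
    if m < 2:
        raise ValidationError("need at least 2 profiles")
    n_pts = len(profiles[0].q)
    mat = [[None] * m for _ in range(m)]
    for i in range(m):
        mat[i][i] = SimilarityResult(n_pts, 0, 1.0)
        for j in range(i + 1, m):
            res = cormap_test(profiles[i], profiles[j], qrange=qrange)
            mat[i][j] = res
            mat[j][i] = res
    return mat


def pairwise_to_csv(matrix, path, names=None) -> None:
    """Export a pairwise result matrix as CSV: profile_i, profile_j, n, C, p."""
    m = len(matrix)
    if names is None:
        names = [str(i) for i in range(m)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["profile_i", "profile_j", "n", "C", "p"])
        for i in range(m):
            for j in range(i + 1, m):
                r = matrix[i][j]
                w.writerow([names[i], names[j], r.n_points, r.longest_run,
                            f"{r.p_value:.6g}"])
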