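"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own data structures and algorithms:
interval algebra is done on per-base boolean arrays, the coverage caller as a
per-base scan, the binomial tail by direct pmf summation, Fisher's exact test
by full enumeration over tables with fixed margins, and the Pearson
correlation from the raw sum formulas.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# -- interval algebra on boolean arrays -------------------------------------


def bool_mask(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


# -- coverage caller as a per-base scan --------------------------------------


def depth_array(runs, length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=int)
    for s, e, d in runs:
        depth[s:e] = d
    return depth


def call_regions_scan(depth: np.ndarray, h: int, l: int, g: int) -> list[tuple[int, int]]:
    """Threshold -> gap-merge -> length-filter, entirely per-base."""
    runs = mask_to_intervals(depth >= h)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= g:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= l]


# -- exact binomial upper tail ------------------------------------------------


def binom_tail_sum(m: int, x: int, p: float) -> float:
    """P(M >= m | X = x) by direct summation of the pmf."""
    if m <= 0:
        return 1.0
    total = 0.0
    for k in range(m, x + 1):
        total += math.comb(x, k) * (p**k) * ((1 - p) ** (x - k))
    return min(total, 1.0)


# -- Fisher's exact test by enumeration ---------------------------------------


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Sum probabilities of all fixed-margin tables no more probable than observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(total)


# -- Pearson correlation from sums --------------------------------------------


def pearson_sums(x, y) -> float:
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den
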