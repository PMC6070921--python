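"""Independent reference implementations used to cross-check the package.

These deliberately re-derive each quantity from first principles (explicit
Hamming scans, exact binomial tail bisection, full permutation enumeration,
rank-then-Pearson) rather than reusing any code path from arvprofiler.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from arvprofiler._seq import revcomp


def oracle_assign_pure(read, signatures, min_overhang=10, max_mismatches=3):
    """Pure-python Hamming scan over every signature, strand and offset."""
    hits = []  # (mismatches, signature index)
    R = len(read)
    for si, sig in enumerate(signatures):
        variants = (
            (sig.sequence, sig.junction_offset),
            (revcomp(sig.sequence), len(sig.sequence) - sig.junction_offset),
        )
        for seq, J in variants:
            L = len(seq)
            for o in range(-R + 1, L):
                lo, hi = max(0, o), min(L, o + R)
                if lo > J - min_overhang or hi < J + min_overhang:
                    continue
                mm = sum(1 for i in range(lo, hi) if seq[i] != read[i - o])
                if mm <= max_mismatches:
                    hits.append((mm, si))
    if not hits:
        return None
    best = min(mm for mm, _ in hits)
    sig_ids = {si for mm, si in hits if mm == best}
    if len(sig_ids) != 1:
        return None
    return signatures[sig_ids.pop()].junction


class OracleScanner:
    """Vectorised brute-force scanner: every signature, strand and offset is
    materialised as a padded window row; the junction-coverage rule is applied
    per row after counting mismatches over the overlap."""

    def __init__(self, signatures, read_length, min_overhang=10, max_mismatches=3):
        self.signatures = signatures
        self.max_mismatches = max_mismatches
        R = read_length
        rows = []
        sig_idx = []
        for si, sig in enumerate(signatures):
            variants = (
                (sig.sequence, sig.junction_offset),
                (revcomp(sig.sequence), len(sig.sequence) - sig.junction_offset),
            )
            for seq, J in variants:
                L = len(seq)
                padded = "\0" * (R - 1) + seq + "\0" * (R - 1)
                for o in range(-R + 1, L):
                    lo, hi = max(0, o), min(L, o + R)
                    if lo > J - min_overhang or hi < J + min_overhang:
                        continue
                    window = padded[o + R - 1 : o + 2 * R - 1]
                    rows.append(np.frombuffer(window.encode(), dtype=np.uint8))
                    sig_idx.append(si)
        self.W = np.vstack(rows)
        self.sig_idx = np.array(sig_idx)
        self.pad = np.count_nonzero(self.W == 0, axis=1)

    def assign(self, read):
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        mm = np.count_nonzero(self.W != arr, axis=1) - self.pad
        best = int(mm.min())
        if best > self.max_mismatches:
            return None
        sigs = set(self.sig_idx[mm == best].tolist())
        if len(sigs) != 1:
            return None
        return self.signatures[sigs.pop()].junction


def binom_sf_at_least(k: int, n: int, p: float) -> float:
    """P(Bin(n, p) >= k) by direct summation."""
    from scipy.stats import binom

    return float(binom.sf(k - 1, n, p))


def cp_lower_bisect(k: int, n: int, alpha: float = 0.025, tol: float = 1e-10) -> float:
    """Smallest p with P(Bin(n, p) >= k) >= alpha, by bisection."""
    if k == 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if binom_sf_at_least(k, n, mid) >= alpha:
            hi = mid
        else:
            lo = mid
    return hi


def mw_u_statistic(a, b) -> float:
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_enum(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    u_obs = mw_u_statistic(a, b)
    m_obs = min(u_obs, na * len(b) - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = mw_u_statistic(ga, gb)
        if min(u, na * len(gb) - u) <= m_obs + 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def midranks(values) -> np.ndarray:
    """Midrank computation from scratch (average rank over ties)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson rho, computed without scipy."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx * rx).sum() * (ry * ry).sum()))
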