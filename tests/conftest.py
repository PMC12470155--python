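"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dnascape.profiles import EnvironmentProfile


# ---------------------------------------------------------------------------
# brute-force tandem-repeat oracle (independent of the vectorized detector)
# ---------------------------------------------------------------------------

def brute_force_tandem_repeats(seq: str, max_unit: int = 6, min_total: int = 4):
    """Enumerate every (start, unit-length) pair, extend maximal runs, apply
    the qualification / smallest-period / greedy-overlap rules by direct
    string comparison.  Returns [(start, end, unit)] sorted by start."""
    L = len(seq)

    def min_period(s: int, e: int) -> int:
        for p in range(1, e - s):
            if all(seq[i] == seq[i + p] for i in range(s, e - p)):
                return p
        return e - s

    def qualifies(length: int, p: int) -> bool:
        return length >= max(min_total, 2 * p)

    candidates = set()
    for p in range(1, max_unit + 1):
        for s in range(L - 2 * p + 1):
            if "N" in seq[s:s + p]:
                continue
            # extend the period-p run rightward from s
            e = s + p
            while e < L and seq[e] == seq[e - p] and seq[e] != "N":
                e += 1
            # maximal: cannot extend left
            if s > 0 and seq[s - 1] == seq[s - 1 + p] and seq[s - 1] != "N":
                continue
            if e - s < 2 * p:
                continue
            if not qualifies(e - s, p):
                continue
            if min_period(s, e) != p:
                continue
            candidates.add((s, e, p))

    ordered = sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    covered = [False] * L
    accepted = []
    for s, e, p in ordered:
        i = s
        while i < e:
            while i < e and covered[i]:
                i += 1
            j = i
            while j < e and not covered[j]:
                j += 1
            if j > i and qualifies(j - i, p) and min_period(i, j) == p:
                accepted.append((i, j, seq[i:i + p]))
                for k in range(i, j):
                    covered[k] = True
            i = j
    return sorted(accepted)


# ---------------------------------------------------------------------------
# naive dinucleotide scanner
# ---------------------------------------------------------------------------

def naive_dinucleotide_counts(seq: str, resolution: int):
    """Position-by-position dinucleotide and nucleotide bin counts."""
    import collections
    n_bins = -(-len(seq) // resolution)
    dinuc = [collections.Counter() for _ in range(n_bins)]
    nuc = [collections.Counter() for _ in range(n_bins)]
    for i, ch in enumerate(seq):
        if ch != "N":
            nuc[i // resolution][ch] += 1
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if "N" not in pair:
            dinuc[i // resolution][pair] += 1
    return dinuc, nuc


# ---------------------------------------------------------------------------
# profile construction helpers
# ---------------------------------------------------------------------------

def make_profile(mean: np.ndarray, se: float | np.ndarray = 1.0,
                 weight: float = 400.0, resolution: int = 1000,
                 n_anchors: int = 400) -> EnvironmentProfile:
    """Profile with the given per-distance means and standard errors
    (variance = se^2 * weight, so profile.se reproduces ``se``)."""
    mean = np.asarray(mean, dtype=float)
    k = mean.size // 2
    distances = (np.arange(mean.size) - k) * resolution
    se = np.broadcast_to(np.asarray(se, dtype=float), mean.shape)
    weight_arr = np.full(mean.size, float(weight))
    variance = se ** 2 * weight_arr
    return EnvironmentProfile(distances, mean.copy(), variance, weight_arr,
                              np.full(mean.size, n_anchors), resolution)


def triangular_bump(n_half: int, height: float, half_width_bins: int) -> np.ndarray:
    """Symmetric triangular deviation over 2*n_half+1 bins."""
    d = np.abs(np.arange(-n_half, n_half + 1))
    return height * np.clip(1 - d / half_width_bins, 0, None)


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
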