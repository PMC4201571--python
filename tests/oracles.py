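"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own vectorized implementations:
clustering is recomputed by pairwise union-find, p-values by naive double
loops, and matching by exhaustive assignment search.
"""

from __future__ import annotations

import itertools

import numpy as np

from pepperm.indicators import INDICATOR_DIRECTIONS, INDICATOR_NAMES, round_sig


def brute_force_mass_filter(masses, neutral, tol):
    return [i for i, m in enumerate(masses) if abs(m - neutral) <= tol]


def brute_force_candidate_filter(masses, observed, window):
    return [
        i
        for i, m in enumerate(masses)
        if any(abs(m - o) <= window for o in observed)
    ]


def brute_force_clusters(records, mass_tol=1.5, rounding=6):
    """Union-find over the pairwise homeometric relation: identical rounded
    indicator tuples and masses within mass_tol (transitively chained)."""
    n = len(records)
    keys = [
        tuple(
            "nan" if np.isnan(v) else v
            for v in round_sig(np.array(r.indicators.as_tuple(), dtype=float), rounding)
        )
        for r in records
    ]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if keys[i] == keys[j] and abs(
                records[i].neutral_mass - records[j].neutral_mass
            ) <= mass_tol:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


def brute_force_pvalue(records, target, indicator, mass_tol=1.5, rounding=6):
    """Naive recount: cluster by brute force, then double-loop the
    equal-or-better comparison over cluster representatives."""
    col = list(INDICATOR_NAMES).index(indicator)
    direction = INDICATOR_DIRECTIONS[indicator]
    clusters = brute_force_clusters(records, mass_tol, rounding)
    tidx = next(i for i, r in enumerate(records) if r is target)
    tval = round_sig(target.indicators.as_tuple()[col], rounding)
    count = 0
    for grp in clusters:
        v = round_sig(records[grp[0]].indicators.as_tuple()[col], rounding)
        if np.isnan(tval):
            return float("nan"), len(clusters)
        if np.isnan(v):
            continue
        ok = v >= tval if direction == "higher" else v <= tval
        if ok:
            count += 1
    assert any(tidx in grp for grp in clusters)
    return count / len(clusters), len(clusters)


def brute_force_optimal_matching(theo_mz, exp_mz, tol):
    """Maximum one-to-one matching size by exhaustive assignment search
    (tiny instances only)."""
    theo_mz, exp_mz = list(theo_mz), list(exp_mz)
    best = 0
    for perm in itertools.permutations(range(len(exp_mz)), min(len(theo_mz), len(exp_mz))):
        for subset in itertools.combinations(range(len(theo_mz)), len(perm)):
            size = sum(
                1 for t, e in zip(subset, perm) if abs(theo_mz[t] - exp_mz[e]) <= tol
            )
            best = max(best, size)
    return best


def poisson_sf_series(n, lam, terms=200):
    """P(X >= n) by direct series summation of the complement."""
    import math

    cdf = sum(math.exp(-lam) * lam**j / math.factorial(j) for j in range(n))
    return 1.0 - cdf


def xcorr_explicit(bin_values, theo_bins, offset=75):
    """Fast-XCorr by explicit offset loop on an already binned/normalized
    vector: dot(theo, y - mean_{tau != 0} y_shifted) / 1e4."""
    n = len(bin_values)
    y = np.asarray(bin_values, dtype=float)
    total = 0.0
    for b in theo_bins:
        background = 0.0
        for tau in range(-offset, offset + 1):
            if tau == 0:
                continue
            j = b + tau
            if 0 <= j < n:
                background += y[j]
        total += y[b] - background / (2 * offset)
    return total / 1e4
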