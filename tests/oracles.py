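"""Independent brute-force oracles used to validate the package's primitives.

Each oracle recomputes its quantity by direct summation / iterative
relaxation, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def huang_fuzziness_direct(counts: np.ndarray, t: int) -> float:
    """Huang–Wang fuzziness at threshold t by direct summation."""
    counts = np.asarray(counts, dtype=float)
    g = np.arange(256, dtype=float)
    occ = np.nonzero(counts)[0]
    c = float(occ[-1] - occ[0])
    low = g <= t
    n0, n1 = counts[low].sum(), counts[~low].sum()
    if n0 == 0 or n1 == 0:
        return np.nan
    m0 = (counts[low] * g[low]).sum() / n0
    m1 = (counts[~low] * g[~low]).sum() / n1
    total = 0.0
    for gi in range(256):
        if counts[gi] == 0:
            continue
        m = m0 if gi <= t else m1
        mu = 1.0 / (1.0 + abs(gi - m) / c)
        s = 0.0
        if 0 < mu < 1:
            s = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        total += counts[gi] * s
    return total


def huang_brute(counts: np.ndarray) -> int:
    """Exhaustive-scan argmin of the Huang fuzziness (ties -> smallest t)."""
    occ = np.nonzero(np.asarray(counts))[0]
    best_t, best_e = None, np.inf
    for t in range(int(occ[0]), int(occ[-1])):
        e = huang_fuzziness_direct(counts, t)
        if not np.isnan(e) and e < best_e:
            best_t, best_e = t, e
    return best_t


def li_cross_entropy_direct(counts: np.ndarray, t: int) -> float:
    """Li–Lee cross-entropy at threshold t, levels shifted by +1."""
    counts = np.asarray(counts, dtype=float)
    g = np.arange(256, dtype=float) + 1.0
    low = np.arange(256) <= t
    n0, n1 = counts[low].sum(), counts[~low].sum()
    if n0 == 0 or n1 == 0:
        return np.nan
    m0 = (counts[low] * g[low]).sum()
    m1 = (counts[~low] * g[~low]).sum()
    return float(-m0 * np.log(m0 / n0) - m1 * np.log(m1 / n1))


def li_brute(counts: np.ndarray) -> int:
    occ = np.nonzero(np.asarray(counts))[0]
    best_t, best_e = None, np.inf
    for t in range(int(occ[0]), int(occ[-1])):
        e = li_cross_entropy_direct(counts, t)
        if not np.isnan(e) and e < best_e:
            best_t, best_e = t, e
    return best_t


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """Random occupied 8-bit histogram with at least 2 distinct levels."""
    n_levels = rng.integers(2, 40)
    levels = rng.choice(256, size=n_levels, replace=False)
    counts = np.zeros(256, dtype=int)
    counts[levels] = rng.integers(1, 500, size=n_levels)
    return counts


_STEPS = {
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
    4: ((-1, 0), (0, -1), (0, 1), (1, 0)),
}


def propagation_oracle(
    seeds: np.ndarray,
    intensity: np.ndarray,
    growth: np.ndarray,
    lam: float,
    connectivity: int = 8,
    quantum: float = 1e-7,
) -> np.ndarray:
    """Per-pixel seeded assignment by iterative Bellman-Ford relaxation.

    For each seed label, relax sqrt(dI^2 + lam*d^2) step costs over the
    growth region until convergence (no heap, no priority order), then
    assign each pixel the smallest label attaining the minimal cost.
    Accumulated costs are snapped to the same quantum as the implementation
    so that mathematically tied paths compare equal.
    """
    labels = np.unique(seeds[seeds > 0])
    nrows, ncols = seeds.shape
    steps = _STEPS[connectivity]
    costs = []
    for lab in labels:
        d = np.full(seeds.shape, np.inf)
        d[(seeds == lab) & growth] = 0.0
        changed = True
        while changed:
            changed = False
            for dr, dc in steps:
                src_r = slice(max(0, -dr), nrows - max(0, dr))
                src_c = slice(max(0, -dc), ncols - max(0, dc))
                dst_r = slice(max(0, dr), nrows + min(0, dr))
                dst_c = slice(max(0, dc), ncols + min(0, dc))
                w = np.sqrt(
                    (intensity[src_r, src_c] - intensity[dst_r, dst_c]) ** 2
                    + lam * float(dr * dr + dc * dc)
                )
                cand = d[src_r, src_c] + w
                cand = np.round(cand / quantum) * quantum
                cand = np.where(growth[dst_r, dst_c], cand, np.inf)
                better = cand < d[dst_r, dst_c]
                if better.any():
                    block = d[dst_r, dst_c]
                    block[better] = cand[better]
                    d[dst_r, dst_c] = block
                    changed = True
        costs.append(d)
    stack = np.stack(costs)  # (L, rows, cols)
    finite = np.isfinite(stack).any(axis=0)
    # first argmin = smallest label among exact (quantized) ties
    winner = np.argmin(stack, axis=0)
    out = np.where(finite & growth, labels[winner], 0).astype(np.int32)
    out[seeds > 0] = seeds[seeds > 0]
    return out
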