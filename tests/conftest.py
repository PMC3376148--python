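"""Shared fixtures and independent oracles for the fragmatch test suite.

The oracles here deliberately re-derive results by brute force (grid
search, exhaustive interval scan) so that the package's optimized paths
are checked against an implementation that shares no code with them.
"""

import itertools

import numpy as np
import pytest

from fragmatch.decay import fragment_size


def grid_search_decay_rss(times, sizes, theta4_fixed=None):
    """Brute-force least-squares oracle over a documented parameter lattice.

    Scans a dense grid of (theta1, theta2, theta3[, theta4]) inside the
    fitting bounds and returns the minimum residual sum of squares found.
    Coarse by construction; a proper optimizer must do at least this well.
    """
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    t1_grid = np.linspace(0.0, sizes.min(), 12)
    t2_grid = np.geomspace(1.0, 10.0 * sizes.max(), 24)
    t3_grid = np.geomspace(1e-3, 30.0, 18)
    t4_grid = [theta4_fixed] if theta4_fixed is not None else np.geomspace(0.05, 5.0, 18)
    best = np.inf
    for t4 in t4_grid:
        decay = np.power(times[:, None] + t3_grid[None, :], -t4)  # (n, t3)
        for t1 in t1_grid:
            resid_base = sizes[:, None] - t1  # (n, 1)
            for i3 in range(len(t3_grid)):
                d = decay[:, i3]
                # optimal theta2 for this (t1, t3, t4) in closed form, clipped
                t2_opt = float(np.dot(d, resid_base[:, 0]) / np.dot(d, d))
                for t2 in set(
                    [min(max(t2_opt, 1e-9), 10.0 * sizes.max())]
                ) | set(t2_grid[:: 6]):
                    rss = float(np.sum((resid_base[:, 0] - t2 * d) ** 2))
                    if rss < best:
                        best = rss
    return best


def exhaustive_interval_calls(values, sigma, threshold, min_probes, min_abs_log2):
    """Exhaustive-scan oracle for the interval-score caller on one chromosome.

    Recursively finds the argmax of |mean| * sqrt(n) / sigma over every
    (i, j) subinterval by a plain double loop, extracts it while the score
    clears the threshold, then applies the probe-count and mean filters.
    Returns [(i, j, score)] in genomic order, j exclusive.
    """
    values = np.asarray(values, dtype=float)
    out = []

    def best(lo, hi):
        b, bs = None, -1.0
        for i in range(lo, hi):
            acc = 0.0
            for j in range(i + 1, hi + 1):
                acc += values[j - 1]
                n = j - i
                score = abs(acc / n) * np.sqrt(n) / sigma
                if score > bs:
                    bs, b = score, (i, j)
        return b, bs

    def recurse(lo, hi):
        if hi - lo < 1:
            return
        (i, j), score = best(lo, hi)
        if score < threshold:
            return
        out.append((i, j, score))
        recurse(lo, i)
        recurse(j, hi)

    recurse(0, len(values))
    filtered = [
        (i, j, s)
        for (i, j, s) in out
        if (j - i) >= min_probes and abs(values[i:j].mean()) > min_abs_log2
    ]
    return sorted(filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
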