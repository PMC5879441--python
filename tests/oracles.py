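"""Independent brute-force references used by the test suite."""

import math

import numpy as np

from circarhythm.cohort import entropy


def gain_oracle(values, labels, cuts):
    """Contingency-table information gain, computed independently."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    edges = [-np.inf] + sorted(cuts) + [np.inf]
    h = entropy(labels)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (values > lo) & (values <= hi)
        if sel.any():
            h -= sel.mean() * entropy(labels[sel])
    return h


def mdl_oracle(values, labels):
    """Exhaustive-search MDL discretization, written independently: try
    every midpoint between adjacent distinct values, apply the acceptance
    inequality, recurse on both sides."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)

    def rec(v, y):
        if len(np.unique(y)) < 2 or len(v) < 2:
            return []
        uniq = np.unique(v)
        if len(uniq) < 2:
            return []
        best_gain, best_cut = -1.0, None
        for a, b in zip(uniq[:-1], uniq[1:]):
            c = (a + b) / 2
            g = gain_oracle(v, y, [c])
            if g > best_gain + 1e-12:
                best_gain, best_cut = g, c
        n = len(y)
        left, right = v <= best_cut, v > best_cut
        k = len(np.unique(y))
        k1, k2 = len(np.unique(y[left])), len(np.unique(y[right]))
        delta = math.log2(3 ** k - 2) - (
            k * entropy(y) - k1 * entropy(y[left]) - k2 * entropy(y[right]))
        if best_gain <= (math.log2(n - 1) + delta) / n:
            return []
        return (rec(v[left], y[left]) + [best_cut]
                + rec(v[right], y[right]))

    return sorted(rec(values, labels))
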