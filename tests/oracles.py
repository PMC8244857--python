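"""Brute-force reference implementations used as independent test oracles.

Deliberately slow and literal: each function recomputes a statistic from its
definition (explicit loops, no shared code with the package) so agreement
with the package is a genuine two-route check.
"""

import math

import numpy as np


def midranks(values):
    """Average ranks (1-based) with mid-rank ties, by explicit enumeration."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        # ranks occupied by the tie group: less+1 ... less+equal
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def pearson(x, y):
    """Pearson correlation from explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_bruteforce(x, y):
    """Spearman rho = Pearson of mid-ranks."""
    return pearson(midranks(x), midranks(y))


def logrank_bruteforce(times, events, group):
    """Log-rank chi-square by per-event-time O-E and variance tallies."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group).astype(bool)
    event_times = sorted(set(times[events == 1]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def group_means_bruteforce(values, sample_groups, offset):
    """Per-group mean of (value + offset) via explicit loops."""
    groups = list(dict.fromkeys(sample_groups))
    out = np.zeros((values.shape[0], len(groups)))
    for gi, g in enumerate(groups):
        cols = [k for k, lab in enumerate(sample_groups) if lab == g]
        for i in range(values.shape[0]):
            out[i, gi] = sum(values[i, c] + offset for c in cols) / len(cols)
    return out, groups


def pairwise_distances(X):
    """All pairwise Euclidean distances of rows."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1])))
    return D
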