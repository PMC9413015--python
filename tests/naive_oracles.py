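"""Deliberately slow, loop-based reference evaluations of the four measures.

These follow the defining formulas term by term and share no code with the
vectorized implementations they check.
"""

import math

import numpy as np


def naive_enmonz(x, y, z):
    out = []
    for xi, yi, zi in zip(x, y, z):
        out.append(max(math.sqrt(xi * xi + yi * yi + zi * zi) - 1.0, 0.0))
    return np.array(out)


def naive_mad(x, y, z, n_window):
    """One value per full non-overlapping window of n_window samples."""
    en = [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]
    out = []
    for start in range(0, len(en) - n_window + 1, n_window):
        w = en[start : start + n_window]
        mean = sum(w) / len(w)
        out.append(sum(abs(v - mean) for v in w) / len(w))
    return np.array(out)


def naive_activity_index(x, y, z, n_window, noise_variance=0.0):
    out = []
    for start in range(0, len(x) - n_window + 1, n_window):
        total = 0.0
        for axis in (x, y, z):
            w = axis[start : start + n_window]
            mean = sum(w) / len(w)
            total += sum((v - mean) ** 2 for v in w) / len(w)  # population form
        out.append(max(total / 3.0 - noise_variance, 0.0))
    return np.array(out)


def naive_rocam(x, y, z, n_median):
    diffs = [
        math.sqrt(
            (x[t] - x[t - 1]) ** 2 + (y[t] - y[t - 1]) ** 2 + (z[t] - z[t - 1]) ** 2
        )
        for t in range(1, len(x))
    ]
    series = [diffs[0]] + diffs
    left = (n_median - 1) // 2
    right = n_median // 2
    out = []
    for i in range(len(series)):
        w = sorted(series[max(0, i - left) : min(len(series), i + right + 1)])
        out.append(w[(len(w) - 1) // 2])  # lower median
    return np.array(out)


def naive_spearman(values, codes):
    """Rank both inputs with average ranks for ties, then Pearson."""

    def avg_ranks(a):
        order = sorted(range(len(a)), key=lambda i: a[i])
        ranks = [0.0] * len(a)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and a[order[j + 1]] == a[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rv, rc = avg_ranks(list(values)), avg_ranks(list(codes))
    n = len(rv)
    mv, mc = sum(rv) / n, sum(rc) / n
    num = sum((a - mv) * (b - mc) for a, b in zip(rv, rc))
    den = math.sqrt(
        sum((a - mv) ** 2 for a in rv) * sum((b - mc) ** 2 for b in rc)
    )
    return num / den


def naive_ks_statistic(a, b):
    """Supremum ECDF distance by exhaustive scan over all jump points."""

    def ecdf(sample, x):
        return sum(1 for v in sample if v <= x) / len(sample)

    points = sorted(set(a) | set(b))
    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in points)
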