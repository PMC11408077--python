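"""Independent straight-from-formula reimplementations used as test oracles.

Deliberately naive (pure-Python loops, itertools enumeration) and kept
separate from the package code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import chi2


def naive_class_stats(values, labels):
    """Per-gene class means/SDs via explicit loops; SD with n-1 denominator."""
    out = []
    for j in range(values.shape[1]):
        col = values[:, j]
        stats = {}
        for k in (0, 1):
            xs = [float(v) for v, l in zip(col, labels) if l == k]
            m = sum(xs) / len(xs)
            var = sum((x - m) ** 2 for x in xs) / (len(xs) - 1)
            stats[k] = (len(xs), m, math.sqrt(var))
        stats["mu"] = sum(float(v) for v in col) / len(col)
        out.append(stats)
    return out


def naive_snr(values, labels, eps_sd=1e-12):
    out = []
    for s in naive_class_stats(values, labels):
        (_, m0, s0), (_, m1, s1) = s[0], s[1]
        out.append(abs(m0 - m1) / (s0 + s1 + eps_sd))
    return np.array(out)


def naive_fisher(values, labels, eps_sd=1e-12):
    out = []
    for s in naive_class_stats(values, labels):
        (n0, m0, s0), (n1, m1, s1) = s[0], s[1]
        mu = s["mu"]
        num = n0 * (m0 - mu) ** 2 + n1 * (m1 - mu) ** 2
        den = n0 * s0**2 + n1 * s1**2
        out.append(num / (den + eps_sd))
    return np.array(out)


def naive_mood(values, labels, continuity=False):
    """Mood's median test by explicit counting; degenerate tables -> P = 1."""
    n = len(labels)
    out = []
    for j in range(values.shape[1]):
        col = sorted(float(v) for v in values[:, j])
        if n % 2:
            med = col[n // 2]
        else:
            med = (col[n // 2 - 1] + col[n // 2]) / 2.0
        a = sum(1 for v, l in zip(values[:, j], labels) if l == 0 and v > med)
        b = sum(1 for v, l in zip(values[:, j], labels) if l == 1 and v > med)
        c = sum(1 for v, l in zip(values[:, j], labels) if l == 0 and v <= med)
        d = sum(1 for v, l in zip(values[:, j], labels) if l == 1 and v <= med)
        if (a + b) == 0 or (c + d) == 0:
            out.append(1.0)
            continue
        diff = abs(a * d - b * c)
        if continuity:
            diff = max(diff - n / 2.0, 0.0)
        stat = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
        out.append(min(1.0, float(chi2.sf(stat, 1))))
    return np.array(out)


def _midranks(xs):
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def naive_wilcoxon_exact(x0, x1):
    """Two-sided exact rank-sum P by enumerating all label assignments."""
    pooled = list(x0) + list(x1)
    ranks = _midranks(pooled)
    n0 = len(x0)
    t_obs = sum(ranks[:n0])
    ts = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n0)
    ]
    lo = sum(1 for t in ts if t <= t_obs + 1e-9) / len(ts)
    hi = sum(1 for t in ts if t >= t_obs - 1e-9) / len(ts)
    return min(1.0, 2.0 * min(lo, hi))
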