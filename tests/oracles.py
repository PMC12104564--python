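"""Independent naive reimplementations used as test oracles.

Deliberately written with plain Python loops / sorting so they share no
code path with the package implementations they check.
"""

import math

import numpy as np


def naive_bh(p):
    """Benjamini–Hochberg step-up, computed by explicit rank iteration."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def naive_robust_z(before, after):
    def mad(x):
        m = np.median(sorted(x))
        return np.median([abs(v - m) for v in x])

    pooled = math.sqrt((mad(before) ** 2 + mad(after) ** 2) / 2)
    d = np.median(after) - np.median(before)
    if pooled == 0:
        return 0.0 if d == 0 else math.copysign(math.inf, d)
    return d / pooled


def naive_cohen_d(before, after):
    n1, n2 = len(before), len(after)
    m1, m2 = sum(before) / n1, sum(after) / n2
    v1 = sum((x - m1) ** 2 for x in before) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in after) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    return (m2 - m1) / sp if sp > 0 else 0.0
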