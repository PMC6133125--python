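"""Independent reference implementations used only as test oracles.

Deliberately written as explicit element-by-element loops, kept separate
from the library code they cross-check.
"""

import math


def stepwise_winsorized_mean(values, tol=1e-4, max_iter=100):
    """Literal transcription of the iterative winsorization procedure."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def median(xs):
        xs = sorted(xs)
        mid = len(xs) // 2
        return xs[mid] if len(xs) % 2 else 0.5 * (xs[mid - 1] + xs[mid])

    m = median(v)
    if all(x == v[0] for x in v):
        return m, 0.0
    s = 1.483 * median([abs(x - m) for x in v])
    if s == 0.0:
        mean = sum(v) / n
        s = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    for _ in range(max_iter):
        lo, hi = m - 1.5 * s, m + 1.5 * s
        w = [min(max(x, lo), hi) for x in v]
        m_new = sum(w) / n
        sd = math.sqrt(sum((x - m_new) ** 2 for x in w) / (n - 1))
        s_new = 1.134 * sd
        done = (
            abs(m_new - m) / max(abs(m_new), abs(m), 1e-12) < tol
            and abs(s_new - s) / max(abs(s_new), abs(s), 1e-12) < tol
        )
        m, s = m_new, s_new
        if done or s == 0.0:
            break
    return m, s


def brute_force_anova(groups):
    """Two-loop one-way ANOVA decomposition (within / between labs)."""
    p = len(groups)
    N = sum(len(g) for g in groups)
    grand = sum(x for g in groups for x in g) / N
    ss_within = 0.0
    ss_between = 0.0
    for g in groups:
        mean = sum(g) / len(g)
        for x in g:
            ss_within += (x - mean) ** 2
        ss_between += len(g) * (mean - grand) ** 2
    s_w2 = ss_within / (N - p)
    ms_between = ss_between / (p - 1)
    n_bar = (N - sum(len(g) ** 2 for g in groups) / N) / (p - 1)
    s_L2 = max(0.0, (ms_between - s_w2) / n_bar)
    return math.sqrt(s_w2), math.sqrt(s_L2)
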