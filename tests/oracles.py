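"""Independent brute-force oracles used by the test suite.

These implement the operations straight from their definitions — tail
sums, step-up rules, naive O(n^3) agglomeration, exhaustive distance
scans — and stay independent of the package's implementation paths.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np


def bh_fdr_brute(p):
    """BH step-up by definition: q_i = min_{j: p_(j) >= p_i} min(1, p_(j) m / j)."""
    p = list(p)
    m = len(p)
    ps = sorted(p)
    out = []
    for pi in p:
        cands = [min(1.0, ps[j - 1] * m / j) for j in range(1, m + 1) if ps[j - 1] >= pi]
        out.append(min(cands))
    return np.array(out)


def hypergeom_tail_brute(f, N, F, n):
    """P(X >= f) for X ~ Hypergeom(N, F, n), by full enumeration."""
    denom = comb(N, n)
    total = 0
    for k in range(f, min(F, n) + 1):
        if n - k <= N - F:
            total += comb(F, k) * comb(N - F, n - k)
    return total / denom


def fisher_right_tail_brute(a, b, c, d):
    """Right-tailed Fisher exact p of [[a, b], [c, d]] via the hypergeometric tail."""
    N = a + b + c + d
    return hypergeom_tail_brute(a, N, a + c, a + b)


def average_linkage_heights_brute(x):
    """Naive O(n^3) average-linkage agglomeration; returns merge heights."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if dist < best[0]:
                    best = (dist, (i, j))
        dist, (i, j) = best
        heights.append(dist)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


def validation_measures_brute(x, labels, n_neighbors=10):
    """Connectivity / Dunn / mean silhouette from their definitions."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    L = min(n_neighbors, n - 1)

    conn = 0.0
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (d[i, j], j))
        for rank, j in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                conn += 1.0 / rank

    inter = [d[i, j] for i in range(n) for j in range(n) if labels[i] != labels[j]]
    intra = [d[i, j] for i in range(n) for j in range(n) if i != j and labels[i] == labels[j]]
    dunn = (min(inter) / max(intra)) if intra and max(intra) > 0 else np.inf

    sils = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            sils.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        bs = []
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            bs.append(np.mean([d[i, j] for j in other]))
        b = min(bs)
        sils.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return conn, dunn, float(np.mean(sils))


def classical_t_brute(xt, xc):
    """Pooled two-sample t and two-sided p, by the textbook formulas."""
    from scipy import stats

    n1, n2 = xt.shape[1], xc.shape[1]
    beta = xt.mean(1) - xc.mean(1)
    s2 = (xt.var(1, ddof=1) * (n1 - 1) + xc.var(1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
    t = beta / np.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    return t, p
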