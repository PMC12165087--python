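"""Independent oracle implementations used to cross-check the package.

Everything here is written as a direct, naive transcription of the defining
formulas — no code is shared with the package internals.
"""

from __future__ import annotations

import numpy as np


def dstat_direct(p1, p2, p3, p_out):
    """Direct-sum ABBA/BABA evaluation: returns (D, f_d)."""
    abba = baba = num_d = 0.0
    for a, b, c, o in zip(p1, p2, p3, p_out):
        abba += (1 - a) * b * c * (1 - o)
        baba += a * (1 - b) * c * (1 - o)
        pd = b if b > c else c
        num_d += (1 - a) * pd * pd * (1 - o) - a * (1 - pd) * pd * (1 - o)
    den = abba + baba
    d = (abba - baba) / den if den != 0 else float("nan")
    if np.isnan(d):
        return d, float("nan")
    if d < 0:
        return d, 0.0
    fd = (abba - baba) / num_d if num_d != 0 else float("nan")
    return d, fd


def wc_fst_direct(n, p, h):
    """Weir & Cockerham (1984) theta for one site, component by component."""
    n = [float(x) for x in n]
    p = [float(x) for x in p]
    h = [float(x) for x in h]
    r = len(n)
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(x * x for x in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    den = a + b + c
    return (a, b, c, a / den if den != 0 else float("nan"))


def jackknife_direct(values, weights=None):
    """Classic delete-one (optionally weighted) jackknife Z for a mean."""
    d = np.asarray(values, dtype=float)
    g = d.size
    if weights is None:
        w = np.ones(g)
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    theta = np.sum(w * d) / total
    pseudo = np.empty(g)
    theta_j = 0.0
    loo = np.empty(g)
    for j in range(g):
        loo[j] = (np.sum(w * d) - w[j] * d[j]) / (total - w[j])
    theta_j = g * theta - np.sum((1 - w / total) * loo)
    h = total / w
    pseudo = h * theta - (h - 1) * loo
    var = np.sum((pseudo - theta_j) ** 2 / (h - 1)) / g
    se = np.sqrt(var)
    return theta / se if se > 0 else np.sign(theta) * np.inf


def pearson_r2(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = np.mean((x - mx) * (y - my))
    vx, vy = np.mean((x - mx) ** 2), np.mean((y - my) ** 2)
    return cov * cov / (vx * vy)


def ibd_runs_brute(hap_a, hap_b, max_mismatch, edge_buffer, min_run_sites=1):
    """Brute-force enumeration of maximal identity runs between two
    haplotype vectors (missing = -1 treated as mismatch).

    Returns (first_site, last_site) pairs by testing every candidate
    interval for validity and maximality — O(n^2) but obviously correct.
    """
    n = len(hap_a)
    mismatch = [
        (hap_a[i] != hap_b[i]) or hap_a[i] < 0 or hap_b[i] < 0 for i in range(n)
    ]

    def valid(s, e):
        inner = [i for i in range(s, e + 1) if mismatch[i]]
        if len(inner) > max_mismatch:
            return False
        for m in inner:
            if m - s < edge_buffer or e - m < edge_buffer:
                return False
        if (e - s + 1 - len(inner)) < min_run_sites:
            return False
        return True

    runs = []
    for s in range(n):
        for e in range(s, n):
            if valid(s, e):
                runs.append((s, e))
    maximal = [
        (s, e)
        for s, e in runs
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in runs)
    ]
    return sorted(maximal)


def interval_union_length(intervals):
    marks = set()
    for s, e in intervals:
        marks.update(range(s, e))
    return len(marks)


def interval_intersection_brute(set_a, set_b, hi):
    """Point-wise intersection of two interval sets over [0, hi)."""
    in_a = [False] * hi
    in_b = [False] * hi
    for s, e in set_a:
        for i in range(s, min(e, hi)):
            in_a[i] = True
    for s, e in set_b:
        for i in range(s, min(e, hi)):
            in_b[i] = True
    out = []
    i = 0
    while i < hi:
        if in_a[i] and in_b[i]:
            j = i
            while j < hi and in_a[j] and in_b[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def mst_weight_brute(dist):
    """Minimum spanning tree total weight by Prim's algorithm on a dense
    distance matrix."""
    n = len(dist)
    in_tree = [0]
    total = 0
    while len(in_tree) < n:
        best = None
        for u in in_tree:
            for v in range(n):
                if v in in_tree:
                    continue
                if best is None or dist[u][v] < best[0]:
                    best = (dist[u][v], v)
        total += best[0]
        in_tree.append(best[1])
    return total
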