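"""Independent brute-force oracles used by the test suite.

Each function here is a deliberately naive, loop-based implementation of
an operation the package provides, kept free of any package internals so
the two routes stay independent.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def median_polish_oracle(x, n_iter=200):
    """Literal scalar Tukey sweep run for many iterations."""
    z = [list(map(float, row)) for row in x]
    nr, nc = len(z), len(z[0])
    overall = 0.0
    row = [0.0] * nr
    col = [0.0] * nc
    for _ in range(n_iter):
        for i in range(nr):
            med = statistics.median(z[i])
            for j in range(nc):
                z[i][j] -= med
            row[i] += med
        d = statistics.median(col)
        col = [c - d for c in col]
        overall += d
        for j in range(nc):
            med = statistics.median(z[i][j] for i in range(nr))
            for i in range(nr):
                z[i][j] -= med
            col[j] += med
        d = statistics.median(row)
        row = [r - d for r in row]
        overall += d
    return overall, row, col, z


def quantile_normalize_oracle(x):
    """Column-by-column rank replacement with mean order statistics."""
    x = np.asarray(x, dtype=float)
    mean_sorted = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = sorted(range(x.shape[0]), key=lambda i: (x[i, j], i))
        for rank, i in enumerate(order):
            out[i, j] = mean_sorted[rank]
    return out


def bh_oracle(p):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def fourier_score_oracle(x, t, period=24.0):
    """Textbook single-frequency DFT magnitude of the standardized series."""
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    z = [(v - mean) / sd for v in x]
    re = sum(zj * math.cos(2 * math.pi * tj / period) for zj, tj in zip(z, t))
    im = sum(zj * math.sin(2 * math.pi * tj / period) for zj, tj in zip(z, t))
    return math.sqrt(re * re + im * im) / n


def abundance_iqr_oracle(values, gene_ids, min_value, min_fraction, min_iqr):
    """Double-loop abundance/IQR gene filter."""
    selected = []
    for gi, row in zip(gene_ids, values):
        n_above = sum(1 for v in row if v > min_value)
        iqr = float(np.percentile(row, 75) - np.percentile(row, 25))
        if n_above / len(row) >= min_fraction and iqr >= min_iqr:
            selected.append(gi)
    return selected


def rbh_oracle(scores_ab, scores_ba):
    """Double-argmax reciprocal best hits; ties yield no pair."""
    pairs = []
    for ia in range(scores_ab.shape[0]):
        row = scores_ab[ia]
        best = row.max()
        hits = [j for j in range(len(row)) if row[j] == best]
        if len(hits) != 1:
            continue
        jb = hits[0]
        back = scores_ba[jb]
        best_back = back.max()
        back_hits = [i for i in range(len(back)) if back[i] == best_back]
        if len(back_hits) == 1 and back_hits[0] == ia:
            pairs.append((ia, jb))
    return pairs


def complete_linkage_oracle(d, k):
    """O(n^3) agglomeration with complete linkage; returns the partition at
    k clusters and the sequence of merge heights."""
    n = d.shape[0]
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    labels = [0] * n
    for lab, members in enumerate(clusters, start=1):
        for i in members:
            labels[i] = lab
    return labels, heights


def snr_detect_oracle(values, threshold, fraction=0.05):
    """Per-chip background + ANY-rule detection, all loops."""
    values = np.asarray(values, dtype=float)
    n_genes, n_chips = values.shape
    detected = []
    for g in range(n_genes):
        hit = False
        for c in range(n_chips):
            col = sorted(values[:, c])
            kk = math.ceil(fraction * n_genes)
            bg = sum(col[:kk]) / kk
            if (values[g, c] - bg) / bg >= threshold:
                hit = True
        detected.append(hit)
    return detected


def stineman_oracle(t, x, q):
    """Scalar implementation of Stineman's published interpolation formulas
    (circle-tangent slopes with sign-preserving endpoints)."""
    t = list(map(float, t))
    x = list(map(float, x))
    n = len(t)
    dt = [t[i + 1] - t[i] for i in range(n - 1)]
    dx = [x[i + 1] - x[i] for i in range(n - 1)]
    m = [dx[i] / dt[i] for i in range(n - 1)]
    yp = [0.0] * n
    for i in range(1, n - 1):
        c0 = dt[i - 1] ** 2 + dx[i - 1] ** 2
        c1 = dt[i] ** 2 + dx[i] ** 2
        num = dx[i - 1] * c1 + dx[i] * c0
        den = dt[i - 1] * c1 + dt[i] * c0
        yp[i] = num / den

    def endpoint(s, yp_next):
        if (s >= 0 and s >= yp_next) or (s <= 0 and s <= yp_next):
            return 2.0 * s - yp_next
        denom = abs(s) + abs(s - yp_next)
        return s + abs(s) * (s - yp_next) / denom if denom else s

    if n > 2:
        yp[0] = endpoint(m[0], yp[1])
        yp[-1] = endpoint(m[-1], yp[-2])
    else:
        yp[0] = yp[1] = m[0]
    # limit each slope to 3x the smaller adjacent secant, matching sign
    for i in range(n):
        left = m[i - 1] if i > 0 else m[0]
        right = m[i] if i < n - 1 else m[-1]
        if left * right < 0:
            yp[i] = 0.0
            continue
        cap = 3.0 * min(abs(left), abs(right))
        yp[i] = max(-cap, min(cap, yp[i]))
        if (left + right) != 0 and yp[i] * (left + right) < 0:
            yp[i] = 0.0
    out = []
    for qq in q:
        i = max(0, min(n - 2, next((j for j in range(n - 1) if t[j] <= qq <= t[j + 1]), n - 2)))
        s = m[i]
        base = x[i] + s * (qq - t[i])
        d0 = (yp[i] - s) * (qq - t[i])
        d1 = (yp[i + 1] - s) * (qq - t[i + 1])
        prod = d0 * d1
        if prod > 0:
            base += prod / (d0 + d1)
        elif prod < 0:
            base += prod * (2 * qq - t[i] - t[i + 1]) / ((d0 - d1) * (t[i + 1] - t[i]))
        out.append(base)
    return out
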