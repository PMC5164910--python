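"""Naive scalar-loop reference implementations used as independent oracles.

These deliberately avoid numpy vectorisation and mirror the defining
formulas term by term, so they are slow but transparently correct on the
tiny instances the tests use.
"""

from __future__ import annotations

import math


def memberships_naive(x, centers, m):
    """u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)), crisp at zero distance."""
    C, N = len(centers), len(x)
    u = [[0.0] * N for _ in range(C)]
    for j in range(N):
        d = [abs(centers[i] - x[j]) for i in range(C)]
        if 0.0 in d:
            u[d.index(0.0)][j] = 1.0
            continue
        for i in range(C):
            u[i][j] = 1.0 / sum((d[i] / d[k]) ** (2.0 / (m - 1.0)) for k in range(C))
    return u


def centers_naive(x, u, m):
    """c_i = sum_j u_ij^m x_j / sum_j u_ij^m."""
    C, N = len(u), len(x)
    out = []
    for i in range(C):
        num = sum(u[i][j] ** m * x[j] for j in range(N))
        den = sum(u[i][j] ** m for j in range(N))
        if den == 0:
            raise ZeroDivisionError(f"cluster {i} has zero mass")
        out.append(num / den)
    return out


def cost_naive(x, centers, u, m):
    """J = sum_i sum_j u_ij^m (c_i - x_j)^2."""
    total = 0.0
    for i in range(len(centers)):
        for j in range(len(x)):
            total += u[i][j] ** m * (centers[i] - x[j]) ** 2
    return total


def spatial_naive(u, height, width, window):
    """h_ij = sum of u_i over the truncated square window around pixel j."""
    C = len(u)
    r = window // 2
    h = [[0.0] * (height * width) for _ in range(C)]
    for i in range(C):
        for row in range(height):
            for col in range(width):
                acc = 0.0
                for dr in range(-r, r + 1):
                    for dc in range(-r, r + 1):
                        rr, cc = row + dr, col + dc
                        if 0 <= rr < height and 0 <= cc < width:
                            acc += u[i][rr * width + cc]
                h[i][row * width + col] = acc
    return h


def spatial_membership_naive(u, h, p, q):
    """u'_ij = u_ij^p h_ij^q / sum_k u_kj^p h_kj^q, with 0^0 == 1."""
    C, N = len(u), len(u[0])
    out = [[0.0] * N for _ in range(C)]
    for j in range(N):
        terms = [u[i][j] ** p * h[i][j] ** q for i in range(C)]
        s = sum(terms)
        for i in range(C):
            out[i][j] = terms[i] / s
    return out


def argmax_naive(u):
    """Per-pixel hard label: lowest index among maximal memberships."""
    C, N = len(u), len(u[0])
    labels = []
    for j in range(N):
        best, best_val = 0, u[0][j]
        for i in range(1, C):
            if u[i][j] > best_val:
                best, best_val = i, u[i][j]
        labels.append(best)
    return labels


def confusion_naive(pred, truth):
    """Per-pixel TP/TN/FP/FN counts over two flat binary sequences."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth, strict=True):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def fcm_fixed_point_naive(x, centers, m, iterations=500):
    """Long-run alternating updates, entirely in scalar arithmetic."""
    c = list(centers)
    for _ in range(iterations):
        u = memberships_naive(x, c, m)
        c = centers_naive(x, u, m)
    return c


def brightest_k_naive(labels, centers, k):
    """Mask of pixels whose cluster center ranks among the k largest."""
    order = sorted(range(len(centers)), key=lambda i: (-centers[i], i))
    selected = set(order[:k])
    return [lab in selected for lab in labels]
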