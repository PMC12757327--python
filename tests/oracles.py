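"""Brute-force reference implementations used as independent oracles."""

import numpy as np


def fps_oracle(pts, m, seed_index):
    """Plain-python greedy maximin with explicit lowest-index tie-break."""
    n = len(pts)
    sel = [seed_index]
    d = [float(np.sum((pts[i] - pts[seed_index]) ** 2)) for i in range(n)]
    d[seed_index] = -1.0
    for _ in range(m - 1):
        best, j = -np.inf, None
        for i in range(n):
            if d[i] > best:  # strict: first (lowest-index) max wins
                best, j = d[i], i
        sel.append(j)
        d[j] = -1.0
        for i in range(n):
            if d[i] >= 0.0:
                d[i] = min(d[i], float(np.sum((pts[i] - pts[j]) ** 2)))
    return sel


def knn_oracle(query, reference, K):
    out = []
    for q in query:
        d2 = [float(np.sum((q - r) ** 2)) for r in reference]
        order = sorted(range(len(reference)), key=lambda j: (d2[j], j))
        out.append(order[:K])
    return np.array(out)


def mask_oracle(gen, part, K):
    """Brute-force union of K-nearest-generated neighborhoods."""
    keep = set()
    for b in part:
        d2 = [float(np.sum((b - g) ** 2)) for g in gen]
        order = sorted(range(len(gen)), key=lambda j: (d2[j], j))
        keep.update(order[:K])
    return sorted(keep)


def metric_oracle(metric, x, y, tau=None):
    """O(nm) reference metric implementations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dxy = np.sqrt(((x[:, None] - y[None]) ** 2).sum(-1))
    dx = dxy.min(1)  # x -> y
    dy = dxy.min(0)  # y -> x
    if metric == "cd_t":
        return (dx ** 2).mean() + (dy ** 2).mean()
    if metric == "cd_p":
        return (dx.mean() + dy.mean()) / 2
    if metric == "ucd":
        return (dx ** 2).mean()
    if metric == "uhd":
        return dx.max()
    if metric == "f":
        p = (dx <= tau).mean()
        r = (dy <= tau).mean()
        return 0.0 if p + r == 0 else 100 * 2 * p * r / (p + r)
    raise ValueError(metric)
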