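"""Independent brute-force oracles used only by the tests.

These are deliberately naive (nested Python loops, direct formulas) and share
no code with the package implementation they check.
"""

from __future__ import annotations

import numpy as np


def conv2d_loops(x, weights, bias, strides=(1, 1)):
    """Quadruple-nested-loop valid strided convolution; x (C_in, H, W),
    weights (C_in, C_out, K_h, K_w)."""
    c_in, h, w = x.shape
    _, c_out, kh, kw = weights.shape
    hs, ws = strides
    ho = (h - kh) // hs + 1
    wo = (w - kw) // ws + 1
    out = np.zeros((c_out, ho, wo))
    for o in range(c_out):
        for i in range(ho):
            for j in range(wo):
                acc = bias[o]
                for c in range(c_in):
                    for u in range(kh):
                        for v in range(kw):
                            acc += weights[c, o, u, v] * x[c, i * hs + u, j * ws + v]
                out[o, i, j] = acc
    return out


def maxpool_loops(x, pool):
    """Per-tile max by explicit loops; x (C, H, W)."""
    c, h, w = x.shape
    ph, pw = pool
    out = np.zeros((c, h // ph, w // pw))
    for ci in range(c):
        for i in range(h // ph):
            for j in range(w // pw):
                out[ci, i, j] = x[ci, i * ph : (i + 1) * ph, j * pw : (j + 1) * pw].max()
    return out


def enumerate_window_starts(n, window, step):
    """All window starts by direct scan, the oracle for the count formula."""
    starts = []
    s = 0
    while s + window <= n:
        starts.append(s)
        s += step
    return starts


def weighted_f1_by_hand(counts):
    """Support-weighted F1 straight from the defining formula, with explicit
    per-class precision/recall ratios."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    score = 0.0
    for i in range(counts.shape[0]):
        tp = counts[i, i]
        support = counts[i, :].sum()
        pred = counts[:, i].sum()
        precision = tp / pred if pred else 0.0
        recall = tp / support if support else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        score += (support / total) * f1
    return score
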