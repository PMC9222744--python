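"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, direct summation) and
shares no code with the package implementation it checks.
"""

import math

import numpy as np


def brute_erode(P, footprint, anchor):
    """Min filter by explicit looping with symmetric (edge-mirroring) padding."""
    fp = np.asarray(footprint, dtype=bool)
    h, w = fp.shape
    a0, a1 = anchor
    ph, pw = max(a0, h - 1 - a0), max(a1, w - 1 - a1)
    Pp = np.pad(np.asarray(P, dtype=float), ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.empty(np.shape(P), dtype=float)
    offs = [(u - a0, v - a1) for u in range(h) for v in range(w) if fp[u, v]]
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = min(Pp[ph + i + du, pw + j + dv] for du, dv in offs)
    return out


def brute_dilate(P, footprint, anchor):
    """Max filter over the reflected footprint, via the erosion duality."""
    fp = np.asarray(footprint, dtype=bool)[::-1, ::-1]
    h, w = fp.shape
    a = (h - 1 - anchor[0], w - 1 - anchor[1])
    return -brute_erode(-np.asarray(P, dtype=float), fp, a)


def brute_close(P, footprint, anchor):
    return brute_erode(brute_dilate(P, footprint, anchor), footprint, anchor)


def brute_gradient(P, footprint, anchor):
    return brute_dilate(P, footprint, anchor) - brute_erode(P, footprint, anchor)


def rescale01(M):
    """Min-max normalization; returns None when the matrix is constant."""
    M = np.asarray(M, dtype=float)
    lo, hi = M.min(), M.max()
    if hi - lo < 1e-12:
        return None
    return (M - lo) / (hi - lo)


def direct_entropy(t, i, f):
    """Entropy of one neutrosophic point, written out term by term."""
    fuzz = (t - f) ** 2 / 2.0
    intuit = (abs(1.0 - 2.0 * i) / 2.0) ** 2
    return 1.0 - (2.0 / math.sqrt(3.0)) * math.sqrt(fuzz + intuit)


def direct_scalar_entropy(T, I, F):
    """Aggregate entropy as an explicit 1/n sum over all elements."""
    T, I, F = (np.asarray(a).ravel() for a in (T, I, F))
    return sum(direct_entropy(t, i, f) for t, i, f in zip(T, I, F)) / T.size


def textbook_em(x, mu, var, pi, n_iter, var_floor=1e-8):
    """Plain GMM-EM sweeps (global mixing weights); yields per-iteration params."""
    x = np.asarray(x, dtype=float).ravel()
    mu, var, pi = (np.array(a, dtype=float).ravel() for a in (mu, var, pi))
    for _ in range(n_iter):
        lg = -0.5 * ((x[:, None] - mu) ** 2 / var + np.log(2 * np.pi * var))
        lw = lg + np.log(pi)
        lw -= lw.max(axis=1, keepdims=True)
        r = np.exp(lw)
        r /= r.sum(axis=1, keepdims=True)
        nk = r.sum(axis=0)
        mu = r.T @ x / nk
        var = np.maximum(
            np.einsum("ij,ij->j", r, (x[:, None] - mu) ** 2) / nk, var_floor
        )
        pi = nk / nk.sum()
        yield mu.copy(), var.copy(), pi.copy(), r.copy()


def isolated_islands(labels):
    """Pixels whose label differs from every 8-connected neighbor."""
    labels = np.asarray(labels)
    h, w = labels.shape
    count = 0
    for i in range(h):
        for j in range(w):
            neigh = labels[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if (neigh == labels[i, j]).sum() == 1:  # only the pixel itself
                count += 1
    return count
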