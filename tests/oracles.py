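"""Independent brute-force oracles used by the test suite.

Everything here is written as literal, loop-based evaluation of the
defining formulas — deliberately sharing no code with the package — so
that agreement between package and oracle pins the implementation to the
mathematics rather than to itself.
"""

import math

import numpy as np


def fcm_loop(points, c, m, delta, max_iter, U0):
    """Literal alternating FCM iteration on a small point set.

    ``points`` is (n, dim); ``U0`` the initial membership matrix (n, c).
    Returns (U, centers, objective_trace) with clusters in fit order.
    """
    pts = [list(map(float, p)) for p in np.atleast_2d(np.asarray(points, float))]
    n, dim = len(pts), len(pts[0])
    U = [list(map(float, row)) for row in U0]
    trace = []
    centers = [[0.0] * dim for _ in range(c)]
    for _q in range(max_iter):
        # center update: v_k = sum_i u_ik^m s_i / sum_i u_ik^m
        for k in range(c):
            num = [0.0] * dim
            den = 0.0
            for i in range(n):
                w = U[i][k] ** m
                den += w
                for d in range(dim):
                    num[d] += w * pts[i][d]
            centers[k] = [v / den for v in num]
        # membership update: u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1))
        U_new = [[0.0] * c for _ in range(n)]
        for i in range(n):
            dists = []
            for k in range(c):
                d2 = sum((pts[i][d] - centers[k][d]) ** 2 for d in range(dim))
                dists.append(math.sqrt(d2))
            if any(d < 1e-12 for d in dists):
                hits = [k for k in range(c) if dists[k] < 1e-12]
                for k in hits:
                    U_new[i][k] = 1.0 / len(hits)
            else:
                for k in range(c):
                    s = 0.0
                    for j in range(c):
                        s += (dists[k] / dists[j]) ** (2.0 / (m - 1.0))
                    U_new[i][k] = 1.0 / s
        obj = 0.0
        for i in range(n):
            for k in range(c):
                d2 = sum((pts[i][d] - centers[k][d]) ** 2 for d in range(dim))
                obj += (U_new[i][k] ** m) * d2
        trace.append(obj)
        change = max(abs(U[i][k] - U_new[i][k]) for i in range(n) for k in range(c))
        U = U_new
        if change <= delta:
            break
    return np.asarray(U), np.asarray(centers), np.asarray(trace)


def centers_loop(points, memberships, m):
    """Direct evaluation of the center-update formula."""
    pts = np.atleast_2d(np.asarray(points, float))
    U = np.asarray(memberships, float)
    n, c = U.shape
    out = []
    for k in range(c):
        num = np.zeros(pts.shape[1])
        den = 0.0
        for i in range(n):
            num += (U[i, k] ** m) * pts[i]
            den += U[i, k] ** m
        out.append(num / den)
    return np.asarray(out)


def memberships_loop(points, centers, m):
    """Direct evaluation of the membership-update formula."""
    pts = np.atleast_2d(np.asarray(points, float))
    V = np.atleast_2d(np.asarray(centers, float))
    n, c = pts.shape[0], V.shape[0]
    U = np.zeros((n, c))
    for i in range(n):
        dists = [math.dist(pts[i], V[k]) for k in range(c)]
        for k in range(c):
            U[i, k] = 1.0 / sum((dists[k] / dists[j]) ** (2.0 / (m - 1.0))
                                for j in range(c))
    return U


def maxmin_loop(U):
    """Exhaustive max-min fuzzy-relation composition with unit diagonal."""
    U = np.asarray(U, float)
    n, c = U.shape
    F = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                F[i, j] = 1.0
            else:
                F[i, j] = max(min(U[i, k], U[j, k]) for k in range(c))
    return F


def glcm_pairs_loop(quantised, dy, dx, symmetric=True):
    """Brute-force co-occurrence counting for one pixel offset."""
    q = np.asarray(quantised, int)
    levels = q.max() + 1
    H, W = q.shape
    M = np.zeros((levels, levels), dtype=int)
    for y in range(H):
        for x in range(W):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < H and 0 <= x2 < W:
                M[q[y, x], q[y2, x2]] += 1
    if symmetric:
        M = M + M.T
    return M


def lstm_step_loop(Wi, Wr, b, z, h_prev, c_prev):
    """Scalar-loop LSTM step: gates (u, f, w, e) stacked along rows of Wi/Wr/b."""
    H = len(h_prev)

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    pre = []
    for row in range(4 * H):
        s = b[row]
        for j in range(len(z)):
            s += Wi[row][j] * z[j]
        for j in range(H):
            s += Wr[row][j] * h_prev[j]
        pre.append(s)
    u = [sig(pre[k]) for k in range(H)]
    f = [sig(pre[H + k]) for k in range(H)]
    w = [math.tanh(pre[2 * H + k]) for k in range(H)]
    e = [sig(pre[3 * H + k]) for k in range(H)]
    c = [f[k] * c_prev[k] + u[k] * w[k] for k in range(H)]
    h = [e[k] * math.tanh(c[k]) for k in range(H)]
    return np.asarray(h), np.asarray(c)
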