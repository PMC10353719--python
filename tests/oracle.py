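"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit Python double loops,
summation formulas, generic numerical quadrature — and shares no code path
with the package, so agreement is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

from scipy.integrate import quad


def dist_loop(x):
    n = len(x)
    return [[abs(x[j] - x[k]) for k in range(n)] for j in range(n)]


def joint_dist_loop(block):
    """Euclidean distances between rows of a list-of-rows block."""
    n = len(block)
    d = [[0.0] * n for _ in range(n)]
    for j in range(n):
        for k in range(n):
            s = 0.0
            for a, b in zip(block[j], block[k]):
                s += (a - b) ** 2
            d[j][k] = math.sqrt(s)
    return d


def center_loop(d):
    n = len(d)
    rm = [sum(d[j]) / n for j in range(n)]
    cm = [sum(d[j][k] for j in range(n)) / n for k in range(n)]
    gm = sum(sum(row) for row in d) / (n * n)
    return [[d[j][k] - rm[j] - cm[k] + gm for k in range(n)] for j in range(n)]


def dcov2_loop(A, B):
    n = len(A)
    return sum(A[j][k] * B[j][k] for j in range(n) for k in range(n)) / (n * n)


def dcor_loop(x, y):
    """Full univariate distance-correlation pipeline by double loops."""
    A = center_loop(dist_loop(list(x)))
    B = center_loop(dist_loop(list(y)))
    v = dcov2_loop(A, B)
    vx = dcov2_loop(A, A)
    vy = dcov2_loop(B, B)
    return math.sqrt(max(v, 0.0)) / (vx * vy) ** 0.25


def one_to_all_loop(values, i):
    """One-to-all dCor for column i of a list-of-rows matrix."""
    x = [row[i] for row in values]
    block = [[row[j] for j in range(len(values[0])) if j != i]
             for row in values]
    A = center_loop(dist_loop(x))
    B = center_loop(joint_dist_loop(block))
    v = dcov2_loop(A, B)
    vx = dcov2_loop(A, A)
    vy = dcov2_loop(B, B)
    return math.sqrt(max(v, 0.0)) / (vx * vy) ** 0.25


def pearson_loop(x, y):
    """Product-moment correlation by direct summation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def t_pdf(u, df):
    c = math.exp(math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0)) \
        / math.sqrt(df * math.pi)
    return c * (1.0 + u * u / df) ** (-(df + 1) / 2.0)


def t_sf(t, df):
    """Upper-tail t probability by adaptive quadrature (no scipy.stats)."""
    if math.isinf(t):
        return 0.0
    val, _ = quad(t_pdf, 0.0, abs(t), args=(df,), epsabs=1e-13, epsrel=1e-13)
    sf = 0.5 - val
    return sf if t >= 0 else 1.0 - sf


def norm_sf(x):
    """Upper-tail standard normal probability via the error function."""
    return 0.5 * math.erfc(x / math.sqrt(2.0))
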