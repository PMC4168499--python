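"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: entropy by pure
Python enumeration and double-loop pair counting, triangle overlap by
numerical quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def brute_force_msampen(X, m, tau, r):
    """Multivariate sample entropy by exhaustive enumeration.

    Builds base and extended composite delay vectors index by index over the
    common range N - max_k(m_k tau_k) and counts unordered Chebyshev-ball
    pairs with a double loop. Returns None when either frequency is zero.
    """
    X = [list(map(float, row)) for row in np.atleast_2d(X)]
    p = len(X)
    N = len(X[0])
    span = max(m[k] * tau[k] for k in range(p))
    count = N - span

    base = []
    for i in range(count):
        vec = []
        for k in range(p):
            for j in range(m[k]):
                vec.append(X[k][i + j * tau[k]])
        base.append(tuple(vec))

    ext = []
    for h in range(p):
        for i in range(count):
            vec = []
            for k in range(p):
                mk = m[k] + (1 if k == h else 0)
                for j in range(mk):
                    vec.append(X[k][i + j * tau[k]])
            ext.append(tuple(vec))

    def pair_fraction(vectors):
        n = len(vectors)
        hits = 0
        for i in range(n):
            for j in range(i + 1, n):
                if max(abs(a - b) for a, b in zip(vectors[i], vectors[j])) <= r:
                    hits += 1
        return hits / (n * (n - 1) / 2)

    b_m = pair_fraction(base)
    b_m1 = pair_fraction(ext)
    if b_m == 0 or b_m1 == 0:
        return None
    return -math.log(b_m1 / b_m)


def quadrature_triangle_similarity(cf, sf, fuzz=0.5):
    """Fuzzy local similarity by numerical integration of min(mu1, mu2)."""
    hw1 = fuzz * abs(cf)
    hw2 = fuzz * abs(sf)
    if hw1 == 0 or hw2 == 0:
        return 1.0 if cf == sf else 0.0

    def mu(x, c, hw):
        return max(0.0, 1.0 - abs(x - c) / hw)

    lo = min(cf - hw1, sf - hw2)
    hi = max(cf + hw1, sf + hw2)
    breakpoints = sorted(
        x for x in (cf - hw1, cf, cf + hw1, sf - hw2, sf, sf + hw2) if lo < x < hi
    )
    om, _ = quad(
        lambda x: min(mu(x, cf, hw1), mu(x, sf, hw2)),
        lo,
        hi,
        points=breakpoints,
        limit=200,
        epsabs=1e-13,
        epsrel=1e-13,
    )
    return max(om / hw1, om / hw2)


def periodogram_peak_hz(x, fs):
    """Dominant frequency of a series by a plain periodogram argmax."""
    from scipy.signal import periodogram

    freqs, power = periodogram(np.asarray(x, dtype=float), fs=fs)
    return float(freqs[np.argmax(power)])
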