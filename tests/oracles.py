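"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths under test: the least-squares oracle
minimises the summed squared log10 residuals numerically (coarse grid plus
simplex refinement) instead of using the closed-form normal equations.
"""

import numpy as np
from scipy.optimize import minimize


def brute_force_loglog(pairs, span: float = 6.0, steps: int = 61):
    """Minimise sum((log10 y - a - b log10 x)^2) by grid + simplex search."""
    arr = np.asarray(pairs, dtype=float)
    lx, ly = np.log10(arr[:, 0]), np.log10(arr[:, 1])

    def sse(theta):
        a, b = theta
        r = ly - (a + b * lx)
        return float(r @ r)

    # coarse grid centred on a crude moment-based guess
    b0 = (ly.max() - ly.min()) / max(lx.max() - lx.min(), 1e-9)
    grid_b = np.linspace(b0 - span, b0 + span, steps)
    best = None
    for b in grid_b:
        a = float(np.mean(ly - b * lx))  # optimal intercept given b
        val = sse((a, b))
        if best is None or val < best[0]:
            best = (val, a, b)
    res = minimize(
        sse,
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    return float(res.x[0]), float(res.x[1])


def pearson_formula(x, y):
    """Textbook product-moment correlation computed term by term."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den
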