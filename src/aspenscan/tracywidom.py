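"""Tracy-Widom (beta = 1, GOE) distribution.

The CDF F1(s) is computed as the Fredholm determinant of the integral
operator with kernel K(x, y) = Ai((x + y)/2) / 2 on L^2(s, inf),
evaluated with Nystrom/Gauss-Legendre quadrature (Bornemann's method).
A cached spline over a fixed grid serves repeated p-value queries.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import det
from scipy.special import airy, roots_legendre

_UPPER = 12.0  # the Airy kernel is negligible beyond this
_NODES = 60


def tw1_cdf_exact(s: float) -> float:
    """F1(s) by direct Fredholm-determinant evaluation."""
    if s >= _UPPER:
        return 1.0
    x, w = roots_legendre(_NODES)
    a, b = s, _UPPER
    x = 0.5 * (b - a) * x + 0.5 * (a + b)
    w = 0.5 * (b - a) * w
    sw = np.sqrt(w)
    K = 0.5 * airy(0.5 * (x[:, None] + x[None, :]))[0]
    M = np.eye(_NODES) - sw[:, None] * K * sw[None, :]
    return float(det(M))


_grid = None


def _spline() -> CubicSpline:
    global _grid
    if _grid is None:
        s = np.linspace(-13.0, 6.0, 240)
        f = np.clip([tw1_cdf_exact(v) for v in s], 0.0, 1.0)
        _grid = CubicSpline(s, f)
    return _grid


def tw1_cdf(s) -> np.ndarray:
    """F1(s), vectorized (spline-interpolated)."""
    s = np.asarray(s, dtype=float)
    out = np.clip(_spline()(np.clip(s, -13.0, 6.0)), 0.0, 1.0)
    out = np.where(s >= 6.0, 1.0, out)
    return np.where(s <= -13.0, 0.0, out)


def tw1_sf(s) -> np.ndarray:
    """Upper-tail probability P(TW1 > s)."""
    return 1.0 - tw1_cdf(s)
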