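"""Pixel-integrated Gaussian point-spread-function helpers.

A camera pixel records the integral of the PSF over its area, not a point
sample.  For a 2D Gaussian this integral separates into a product of 1D
error-function differences, which is what both the renderer and the spot
fitter use.  Coordinates follow the half-open pixel convention: pixel
``(i, j)`` covers ``[j, j+1) x [i, i+1)`` with the origin at the top-left
pixel corner.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)


def erf_profile(edges: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Integral of a unit-mass 1D Gaussian over consecutive intervals.

    Parameters
    ----------
    edges : array of interval edges (length m+1)
    center, sigma : Gaussian mean and standard deviation (same units as edges)

    Returns the m per-interval masses.
    """
    z = (np.asarray(edges, dtype=float) - center) / (_SQRT2 * sigma)
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def pixel_gaussian(
    x0: float,
    y0: float,
    photons: float,
    sx: float,
    sy: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Render one pixel-integrated 2D Gaussian onto a ``(height, width)`` frame.

    Returns the expected photon count per pixel; the total over an infinite
    frame equals ``photons``.
    """
    h, w = shape
    gx = erf_profile(np.arange(w + 1, dtype=float), x0, sx)
    gy = erf_profile(np.arange(h + 1, dtype=float), y0, sy)
    return photons * np.outer(gy, gx)


def central_pixel_fraction(sx, sy):
    """Mass fraction of a unit 2D Gaussian inside a 1x1 pixel centered at its peak.

    Closed form ``erf(1/(2*sqrt(2)*sx)) * erf(1/(2*sqrt(2)*sy))``; this is the
    signal term of the signal-to-background ratio.
    """
    sx = np.asarray(sx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    return erf(0.5 / (_SQRT2 * sx)) * erf(0.5 / (_SQRT2 * sy))
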