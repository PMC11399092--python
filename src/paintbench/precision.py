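"""Localization-precision estimators.

Two complementary notions of precision are used in DNA-PAINT:

* **Per-localization** precision from the Mortensen closed form for
  least-squares fitting of a pixelated Gaussian PSF: with the effective PSF
  variance ``s_a^2 = s^2 + a^2/12`` (``s`` fitted PSF sigma, ``a`` pixel
  size), ``N`` photons and ``b`` background photons per pixel,

      sigma^2 = (s_a^2 / N) * (16/9 + 8*pi*s_a^2*b / (N*a^2))

* **Per-measurement** precision from the nearest-neighbor analysis (NeNA):
  localizations of the same binding event in adjacent frames are independent
  draws around the same true position, so their distance follows the 2D
  distribution of the difference of two Gaussians of width sigma — a
  Rayleigh-type curve with scale ``sqrt(2)*sigma``.  Fitting that curve plus
  a slowly varying false-pair term to the histogram of adjacent-frame
  nearest-neighbor distances yields the average precision of the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .exceptions import InsufficientDataError, ParameterError


def mortensen_sigma(photons, bg, psf_sigma, pixel_size=1.0):
    """Per-localization precision for least-squares Gaussian fitting.

    Parameters
    ----------
    photons : fitted photon count N (> 0)
    bg : background photons per pixel
    psf_sigma : fitted PSF standard deviation (pixels, or any length unit)
    pixel_size : pixel edge length in the same unit as ``psf_sigma``
        (1.0 when working in pixel units)

    Returns the precision sigma in the same unit.  Vectorized over inputs.
    """
    N = np.asarray(photons, dtype=float)
    b = np.asarray(bg, dtype=float)
    s = np.asarray(psf_sigma, dtype=float)
    a = float(pixel_size)
    if np.any(N <= 0):
        raise ParameterError("photon count must be positive")
    if np.any(b < 0):
        raise ParameterError("background must be non-negative")
    if np.any(s <= 0) or a <= 0:
        raise ParameterError("PSF sigma and pixel size must be positive")
    sa2 = s**2 + a**2 / 12.0
    var = (sa2 / N) * (16.0 / 9.0 + 8.0 * np.pi * sa2 * b / (N * a**2))
    return np.sqrt(var)


@dataclass
class NeNAResult:
    """Outcome of the nearest-neighbor precision fit."""

    sigma_nm: float
    sigma_px: float
    amplitude: float  # weight of the same-emitter term, in [0, 1]
    n_pairs: int
    bin_centers: np.ndarray
    counts: np.ndarray
    model_counts: np.ndarray

    def __repr__(self) -> str:  # compact, the arrays are bulky
        return (
            f"NeNAResult(sigma_nm={self.sigma_nm:.3g}, amplitude={self.amplitude:.3g}, "
            f"n_pairs={self.n_pairs})"
        )


def _nn_distances(x, y, frame, frame_gap: int, max_distance: float) -> np.ndarray:
    """Distance from each localization to its nearest neighbor ``frame_gap`` frames later."""
    frame = np.asarray(frame)
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    order = np.argsort(frame, kind="stable")
    frame = frame[order]
    pts = pts[order]
    uniq, starts = np.unique(frame, return_index=True)
    slices = dict(zip(uniq, np.split(np.arange(len(frame)), starts[1:])))
    dists = []
    for f in uniq:
        nxt = slices.get(f + frame_gap)
        if nxt is None or len(nxt) == 0:
            continue
        tree = cKDTree(pts[nxt])
        d, _ = tree.query(pts[slices[f]], k=1, distance_upper_bound=max_distance)
        d = d[np.isfinite(d)]
        if len(d):
            dists.append(d)
    if not dists:
        return np.empty(0)
    return np.concatenate(dists)


def nena_sigma(
    table,
    max_distance: float = 1.0,
    frame_gap: int = 1,
    bin_width: float | None = 0.02,
    min_pairs: int = 1000,
) -> NeNAResult:
    """Average localization precision of a measurement by nearest-neighbor analysis.

    Parameters
    ----------
    table : LocalizationTable (or any object with ``locs`` and ``pixel_size``)
    max_distance : pair-distance window in pixels; pairs beyond it are dropped
    frame_gap : temporal offset between paired frames (adjacent frames by default)
    bin_width : histogram bin width in pixels; ``None`` picks a width fine
        enough to resolve the observed distance scale (median distance / 25,
        floored at ``max_distance``/2000)
    min_pairs : minimum number of retained pairs before fitting

    The distance histogram is fitted with
    ``A * d/(2 sigma^2) * exp(-d^2/(4 sigma^2)) + (1-A) * 2 d / W^2``
    where ``W`` is the distance window; the second (linear-density) term
    absorbs false pairs from unrelated emitters.
    """
    d = _nn_distances(
        table.locs["x"], table.locs["y"], table.locs["frame"], frame_gap, max_distance
    )
    if len(d) < min_pairs:
        raise InsufficientDataError(
            f"only {len(d)} nearest-neighbor pairs (need >= {min_pairs}); "
            "simulate or measure longer"
        )
    W = max_distance
    if bin_width is None:
        bin_width = max(W / 2000.0, float(np.median(d)) / 25.0)
    edges = np.arange(0.0, W + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = len(d)

    def model(r, sigma, A):
        same = r / (2.0 * sigma**2) * np.exp(-(r**2) / (4.0 * sigma**2))
        false = 2.0 * r / W**2
        return n * bin_width * (A * same + (1.0 - A) * false)

    sigma0 = max(np.sqrt(np.mean(d**2) / 4.0), bin_width / 10.0)
    popt, _ = curve_fit(
        model,
        centers,
        counts,
        p0=[sigma0, 0.9],
        bounds=([1e-6, 0.0], [W, 1.0]),
        maxfev=10000,
    )
    sigma_px, amp = popt
    return NeNAResult(
        sigma_nm=float(sigma_px * table.pixel_size),
        sigma_px=float(sigma_px),
        amplitude=float(amp),
        n_pairs=n,
        bin_centers=centers,
        counts=counts,
        model_counts=model(centers, *popt),
    )
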