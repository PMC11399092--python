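"""Spot detection and Gaussian least-squares fitting on raw movies.

Detection finds local maxima of a *net gradient* score: over a square box
around each pixel, the sum of the dot products of the local intensity
gradient with the unit vector pointing from each box pixel toward the box
center.  A bright spot pulls all surrounding gradients inward, giving a large
positive score; flat background or isolated noise does not.  Candidates above
a threshold survive non-maximum suppression within one box.

Fitting models the box as a pixel-integrated 2D Gaussian (separable
error-function differences, not point samples) plus a constant per-pixel
offset, fit by least squares.  The integrated Gaussian mass is the photon
count; the offset is the per-pixel background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import least_squares

from .exceptions import ParameterError
from .psf import erf_profile


@dataclass
class SpotCandidate:
    """A detection-stage candidate: integer box center plus its net-gradient score."""

    frame: int
    x: int
    y: int
    box: int
    net_gradient: float

    def __post_init__(self) -> None:
        if self.box < 3 or self.box % 2 == 0:
            raise ParameterError("box side must be an odd integer >= 3")


def net_gradient_map(image: np.ndarray, box: int) -> np.ndarray:
    """Net-gradient score of every pixel (border pixels where the box does not fit are 0)."""
    if box < 3 or box % 2 == 0:
        raise ParameterError("box side must be an odd integer >= 3")
    h, w = image.shape
    if box > min(h, w):
        raise ParameterError("box larger than frame")
    gy, gx = np.gradient(image.astype(float))
    half = box // 2
    score = np.zeros_like(image, dtype=float)
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            if dx == 0 and dy == 0:
                continue
            norm = np.hypot(dx, dy)
            ux, uy = -dx / norm, -dy / norm  # unit vector from box pixel toward center
            # contribution of the pixel at offset (dy, dx) relative to each center
            shifted_gx = np.roll(gx, (-dy, -dx), axis=(0, 1))
            shifted_gy = np.roll(gy, (-dy, -dx), axis=(0, 1))
            score += ux * shifted_gx + uy * shifted_gy
    score[:half, :] = 0
    score[-half:, :] = 0
    score[:, :half] = 0
    score[:, -half:] = 0
    return score


def detect_spots(
    frame_image: np.ndarray,
    box: int = 7,
    min_net_gradient: float = 0.0,
    frame: int = 0,
) -> list[SpotCandidate]:
    """Local maxima of the net-gradient map above threshold, one per box."""
    score = net_gradient_map(frame_image, box)
    local_max = score == maximum_filter(score, size=box, mode="constant", cval=-np.inf)
    ok = local_max & (score > min_net_gradient)
    ys, xs = np.nonzero(ok)
    return [
        SpotCandidate(frame=frame, x=int(x), y=int(y), box=box, net_gradient=float(score[y, x]))
        for y, x in zip(ys, xs)
    ]


def _box_slice(image: np.ndarray, candidate: SpotCandidate) -> tuple[np.ndarray, int, int]:
    half = candidate.box // 2
    h, w = image.shape
    x0, y0 = candidate.x - half, candidate.y - half
    if x0 < 0 or y0 < 0 or x0 + candidate.box > w or y0 + candidate.box > h:
        raise ParameterError("candidate box extends beyond the frame")
    return image[y0 : y0 + candidate.box, x0 : x0 + candidate.box].astype(float), x0, y0


def fit_spot(
    frame_image: np.ndarray,
    candidate: SpotCandidate,
    psf_sigma_init: float = 1.0,
    max_nfev: int = 700,
) -> dict:
    """Least-squares fit of a pixel-integrated Gaussian + offset over the box.

    Returns a localization record: ``x, y`` (pixels, frame coordinates),
    ``photons`` (integrated Gaussian mass), ``bg`` (offset per pixel),
    ``sx, sy`` (fitted PSF sigmas) and a ``converged`` flag; non-converged
    records are excluded downstream.
    """
    data, x0, y0 = _box_slice(frame_image, candidate)
    b = candidate.box
    edges = np.arange(b + 1, dtype=float)

    def model(params):
        cx, cy, n, sx, sy, off = params
        return n * np.outer(erf_profile(edges, cy, sy), erf_profile(edges, cx, sx)) + off

    def residuals(params):
        return (model(params) - data).ravel()

    # init: brightest pixel for the center, median-subtracted sum for the mass
    iy, ix = np.unravel_index(np.argmax(data), data.shape)
    off0 = float(np.median(data))
    n0 = max(float(data.sum() - off0 * data.size), 1.0)
    p0 = [ix + 0.5, iy + 0.5, n0, psf_sigma_init, psf_sigma_init, max(off0, 0.0)]
    lower = [0.0, 0.0, 1e-3, 0.05, 0.05, 0.0]
    upper = [b, b, np.inf, float(b), float(b), np.inf]
    result = least_squares(
        residuals, p0, bounds=(lower, upper), max_nfev=max_nfev, method="trf"
    )
    cx, cy, n, sx, sy, off = result.x
    return {
        "frame": candidate.frame,
        "x": float(x0 + cx),
        "y": float(y0 + cy),
        "photons": float(n),
        "bg": float(off),
        "sx": float(sx),
        "sy": float(sy),
        "converged": bool(result.status > 0),
        "cost": float(result.cost),
    }


def localize_movie(
    movie: np.ndarray,
    box: int = 7,
    min_net_gradient: float = 0.0,
    psf_sigma_init: float = 1.0,
) -> list[dict]:
    """Detect and fit spots in every frame; non-converged fits are dropped."""
    records = []
    for f, img in enumerate(movie):
        for cand in detect_spots(img, box=box, min_net_gradient=min_net_gradient, frame=f):
            try:
                rec = fit_spot(img, cand, psf_sigma_init=psf_sigma_init)
            except ParameterError:
                continue
            if rec["converged"]:
                records.append(rec)
    return records
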