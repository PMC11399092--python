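"""Multi-channel registration and cross-talk.

Spectrally split channels of a multi-camera microscope are related by an
affine transform (shift, rotation, scale, skew) estimated from matched bead
localizations; the fitted matrices are then applied to all subsequent data.
Cross-talk quantifies how many localizations a round's dye produces in the
wrong spectral channel, measured around known docking-site positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .exceptions import ParameterError


@dataclass
class AffineTransform2D:
    """2x3 affine matrix; convention ``dst = A @ [x, y, 1]^T`` (pixels)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ParameterError("linear part of the affine transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform2D":
        lin = np.linalg.inv(self.matrix[:, :2])
        t = -lin @ self.matrix[:, 2]
        return AffineTransform2D(np.column_stack([lin, t]))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "convention": "dst = A @ [x y 1]^T, row-major",
            "matrix": [float(v) for v in self.matrix.ravel()],
        }
        with open(path, "w") as f:
            yaml.safe_dump(payload, f)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AffineTransform2D":
        with open(path) as f:
            payload = yaml.safe_load(f)
        return cls(np.array(payload["matrix"], dtype=float).reshape(2, 3))


def fit_affine(src_points, dst_points) -> tuple[AffineTransform2D, float]:
    """Least-squares affine transform mapping matched source to destination points.

    Requires at least three non-collinear pairs; returns the transform and
    the RMS residual in pixels.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ParameterError("src and dst must be matched (n, 2) arrays")
    if len(src) < 3:
        raise ParameterError("at least 3 matched pairs required")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ParameterError("matched points are collinear; affine transform underdetermined")
    coef, _, _, _ = np.linalg.lstsq(design, dst, rcond=None)
    transform = AffineTransform2D(coef.T)
    resid = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms


def apply_affine(transform: AffineTransform2D, table):
    """Map a localization table's coordinates; all other columns are preserved."""
    locs = table.locs.copy()
    xy = transform.apply(locs[["x", "y"]].to_numpy())
    locs["x"] = xy[:, 0]
    locs["y"] = xy[:, 1]
    return table.copy(locs=locs)


def match_beads(src_points, dst_points, gate: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor bead matching across channels with a distance gate (pixels)."""
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    tree = cKDTree(dst)
    d, idx = tree.query(src, k=1, distance_upper_bound=gate)
    keep = np.isfinite(d)
    return np.flatnonzero(keep), idx[keep]


def crosstalk(
    channel_tables: Mapping[str, object],
    site_positions,
    radius: float,
    correct_channel: str,
) -> dict[str, float]:
    """Per-channel cross-talk ratios around known docking sites.

    For each incorrect channel, the number of its localizations within
    ``radius`` of any site is divided by the same count in the correct
    channel.  A zero correct-channel count leaves the ratios undefined (NaN).
    """
    if correct_channel not in channel_tables:
        raise ParameterError(f"correct channel '{correct_channel}' not among the tables")
    positions = np.atleast_2d(np.asarray(site_positions, dtype=float))
    tree = cKDTree(positions)

    def near_site_count(table) -> int:
        pts = table.locs[["x", "y"]].to_numpy()
        if not len(pts):
            return 0
        d, _ = tree.query(pts, k=1, distance_upper_bound=radius)
        return int(np.isfinite(d).sum())

    n_correct = near_site_count(channel_tables[correct_channel])
    out: dict[str, float] = {}
    for name, table in channel_tables.items():
        if name == correct_channel:
            continue
        n = near_site_count(table)
        out[name] = n / n_correct if n_correct > 0 else float("nan")
    return out
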