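"""Localization-table and region I/O.

The localization table is the lingua franca of the pipeline: one record per
fitted single-molecule localization with the column names used by Picasso
(``frame, x, y, photons, sx, sy, bg, lpx, lpy``) so that exported tables from
real acquisitions can be ingested directly.  Positions are in camera pixels
(continuous, origin at the top-left pixel corner, frames 0-based); photons and
background are in photoelectron counts; ``lpx/lpy`` are per-axis localization
precisions in pixels.

Two on-disk dialects are supported and round-trip exactly:

* HDF5 — a single structured dataset ``"locs"`` with the acquisition metadata
  stored as attributes on the dataset.
* CSV — RFC-4180 with a header row, plus a YAML sidecar (same stem, ``.yaml``)
  carrying the metadata.

Regions (circular picks or raster masks) localize the signal/background
bookkeeping used by the specificity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ParameterError, SchemaError

REQUIRED_COLUMNS = ("frame", "x", "y", "photons", "sx", "sy", "bg")
OPTIONAL_COLUMNS = ("lpx", "lpy")
METADATA_KEYS = ("exposure", "pixel_size", "width", "height")


@dataclass
class LocalizationTable:
    """Per-localization records plus acquisition metadata.

    Parameters
    ----------
    locs : DataFrame with at least ``frame, x, y, photons, sx, sy, bg``
    exposure : frame time in seconds
    pixel_size : nm per camera pixel
    width, height : image dimensions in pixels
    """

    locs: pd.DataFrame
    exposure: float
    pixel_size: float
    width: int
    height: int

    def __post_init__(self) -> None:
        self.locs = self.locs.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.locs.columns:
                raise SchemaError(f"missing required column '{col}'")
        for key in METADATA_KEYS:
            if getattr(self, key) is None:
                raise SchemaError(f"missing metadata field '{key}'")
        df = self.locs
        if len(df):
            if (df["frame"] < 0).any():
                raise SchemaError("column 'frame' contains negative values")
            if (df["photons"] < 0).any():
                raise SchemaError("column 'photons' contains negative values")
            if (df["bg"] < 0).any():
                raise SchemaError("column 'bg' contains negative values")
            if (df["sx"] <= 0).any() or (df["sy"] <= 0).any():
                raise SchemaError("PSF widths 'sx'/'sy' must be positive")
            if ((df["x"] < 0) | (df["x"] >= self.width)).any():
                raise SchemaError("column 'x' outside [0, width)")
            if ((df["y"] < 0) | (df["y"] >= self.height)).any():
                raise SchemaError("column 'y' outside [0, height)")

    def __len__(self) -> int:
        return len(self.locs)

    @property
    def metadata(self) -> dict:
        return {
            "exposure": float(self.exposure),
            "pixel_size": float(self.pixel_size),
            "width": int(self.width),
            "height": int(self.height),
        }

    @property
    def duration(self) -> float:
        """Measurement duration in seconds implied by the highest frame index."""
        if not len(self.locs):
            return 0.0
        return (int(self.locs["frame"].max()) + 1) * self.exposure

    def copy(self, locs: pd.DataFrame | None = None) -> "LocalizationTable":
        return LocalizationTable(
            locs=self.locs.copy() if locs is None else locs,
            **self.metadata,
        )


def _table_to_records(table: LocalizationTable) -> np.ndarray:
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.locs.columns]
    dtypes = [(c, np.int64 if c == "frame" else np.float64) for c in cols]
    rec = np.zeros(len(table.locs), dtype=dtypes)
    for c in cols:
        rec[c] = table.locs[c].to_numpy()
    return rec


def write_table(table: LocalizationTable, path: str | Path) -> Path:
    """Write a localization table to ``.hdf5``/``.h5`` or ``.csv`` (+YAML sidecar)."""
    path = Path(path)
    if path.suffix in (".hdf5", ".h5"):
        rec = _table_to_records(table)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("locs", data=rec)
            for k, v in table.metadata.items():
                ds.attrs[k] = v
    elif path.suffix == ".csv":
        cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.locs.columns]
        table.locs[cols].to_csv(path, index=False, lineterminator="\r\n")
        sidecar = path.with_suffix(".yaml")
        with open(sidecar, "w") as f:
            yaml.safe_dump(table.metadata, f)
    else:
        raise ParameterError(f"unsupported table format '{path.suffix}'")
    return path


def read_table(path: str | Path) -> LocalizationTable:
    """Read a localization table written by :func:`write_table`."""
    path = Path(path)
    if path.suffix in (".hdf5", ".h5"):
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise SchemaError("HDF5 file lacks a 'locs' dataset")
            ds = f["locs"]
            meta = {k: ds.attrs[k] for k in METADATA_KEYS if k in ds.attrs}
            rec = ds[()]
        df = pd.DataFrame({name: rec[name] for name in rec.dtype.names})
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise SchemaError(f"missing metadata sidecar '{sidecar.name}'")
        with open(sidecar) as f:
            meta = yaml.safe_load(f)
    else:
        raise ParameterError(f"unsupported table format '{path.suffix}'")
    missing = [k for k in METADATA_KEYS if k not in meta]
    if missing:
        raise SchemaError(f"missing metadata field(s) {missing}")
    df["frame"] = df["frame"].astype(np.int64)
    return LocalizationTable(
        locs=df,
        exposure=float(meta["exposure"]),
        pixel_size=float(meta["pixel_size"]),
        width=int(meta["width"]),
        height=int(meta["height"]),
    )


# ---------------------------------------------------------------------------
# Regions


@dataclass
class CircularRegion:
    """A circular pick: center in pixels, diameter in pixels, role label."""

    x: float
    y: float
    diameter: float
    role: str = "signal"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ParameterError("pick diameter must be positive")


@dataclass
class RegionSet:
    """Either a list of circular picks or a raster mask with two roles.

    For masks, nonzero pixels form the ``inside_role`` region; if
    ``outside_role`` is set the complement forms a second region.
    """

    circles: list[CircularRegion] = field(default_factory=list)
    mask: np.ndarray | None = None
    inside_role: str = "signal"
    outside_role: str | None = None

    @classmethod
    def from_circles(cls, circles: Sequence[CircularRegion]) -> "RegionSet":
        return cls(circles=list(circles))

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        inside_role: str = "signal",
        outside_role: str | None = "background",
    ) -> "RegionSet":
        return cls(mask=np.asarray(mask), inside_role=inside_role, outside_role=outside_role)

    @property
    def is_mask(self) -> bool:
        return self.mask is not None


@dataclass
class RegionAssignment:
    """One region's share of a localization table."""

    role: str
    indices: np.ndarray  # integer row indices into table.locs
    area_um2: float

    @property
    def count(self) -> int:
        return len(self.indices)

    def density(self) -> float:
        """Localizations per µm²."""
        return self.count / self.area_um2


def assign_to_regions(table: LocalizationTable, regions: RegionSet) -> list[RegionAssignment]:
    """Assign localizations to regions and compute region areas in µm².

    Circle membership is strict (``distance < radius``); a localization inside
    several overlapping circles is assigned to the nearest center (with a
    warning).  Mask membership tests the pixel under the localization; areas
    come from the analytic circle area or the mask pixel count.
    """
    x = table.locs["x"].to_numpy()
    y = table.locs["y"].to_numpy()
    px_um = table.pixel_size / 1000.0
    out: list[RegionAssignment] = []

    if regions.is_mask:
        mask = regions.mask
        if mask.shape != (table.height, table.width):
            raise ParameterError(
                f"mask shape {mask.shape} does not match table dimensions "
                f"({table.height}, {table.width})"
            )
        inside = mask[np.floor(y).astype(int), np.floor(x).astype(int)] != 0
        n_inside_px = int(np.count_nonzero(mask))
        out.append(
            RegionAssignment(
                role=regions.inside_role,
                indices=np.flatnonzero(inside),
                area_um2=n_inside_px * px_um**2,
            )
        )
        if regions.outside_role is not None:
            out.append(
                RegionAssignment(
                    role=regions.outside_role,
                    indices=np.flatnonzero(~inside),
                    area_um2=(mask.size - n_inside_px) * px_um**2,
                )
            )
        return out

    if not regions.circles:
        return out
    centers = np.array([[c.x, c.y] for c in regions.circles])
    radii = np.array([c.diameter / 2.0 for c in regions.circles])
    d = np.hypot(x[:, None] - centers[None, :, 0], y[:, None] - centers[None, :, 1])
    member = d < radii[None, :]
    n_hits = member.sum(axis=1)
    if (n_hits > 1).any():
        warnings.warn(
            "overlapping circular picks: localizations assigned to nearest center",
            stacklevel=2,
        )
    # nearest member circle; non-members masked out
    d_member = np.where(member, d, np.inf)
    best = np.argmin(d_member, axis=1)
    assigned = np.where(n_hits > 0, best, -1)
    for i, circ in enumerate(regions.circles):
        out.append(
            RegionAssignment(
                role=circ.role,
                indices=np.flatnonzero(assigned == i),
                area_um2=np.pi * (radii[i] * px_um) ** 2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pick / mask files


def write_picks(regions: RegionSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "picks": [
            {"x": float(c.x), "y": float(c.y), "diameter": float(c.diameter), "role": c.role}
            for c in regions.circles
        ]
    }
    with open(path, "w") as f:
        yaml.safe_dump(payload, f)
    return path


def read_picks(path: str | Path) -> RegionSet:
    with open(path) as f:
        payload = yaml.safe_load(f)
    if not isinstance(payload, dict) or "picks" not in payload:
        raise SchemaError("pick file lacks a 'picks' list")
    circles = [
        CircularRegion(x=p["x"], y=p["y"], diameter=p["diameter"], role=p.get("role", "signal"))
        for p in payload["picks"]
    ]
    return RegionSet.from_circles(circles)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
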