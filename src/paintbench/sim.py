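"""Synthetic DNA-PAINT data generation.

DNA-PAINT blinking arises from transient hybridization of dye-labeled imager
strands to target-bound docking strands: a docking site alternates between a
dark (unbound) state with exponential mean dwell ``tau_d`` and a bright
(bound) state with exponential mean dwell ``tau_b``.  The generative model
implemented here produces, per docking site:

1. an alternating renewal process of binding events (optionally truncated by
   site destruction, optionally with an exponentially decaying effective
   on-rate to mimic progressive photodamage of concatenated docking
   sequences);
2. per-frame photon counts — events rarely align with camera frames, so a
   frame only collects the fraction of the bright period that overlaps it,
   with Poisson photon noise on top;
3. localizations — the site position plus isotropic Gaussian jitter whose
   sigma is the Mortensen precision at that localization's photon count and
   background.

Off-target "sticking" events (single-frame localizations at uniformly random
positions) can be added at a chosen density.  The same event/photon stream
can also be rendered into a raw movie (pixel-integrated Gaussian spots plus
Poisson background) to exercise the detection/fitting stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ParameterError
from .locio import LocalizationTable
from .precision import mortensen_sigma
from .psf import pixel_gaussian


# ---------------------------------------------------------------------------
# Site geometries


@dataclass
class SiteLayout:
    """Docking-site geometry: positions in pixels plus geometry metadata."""

    kind: str  # one of {"grid20", "crosshair", "npc", "custom"}
    positions: np.ndarray  # (n_sites, 2) continuous pixel coordinates
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            raise ParameterError("layout has no sites")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ParameterError("layout positions must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def single_sites(
        cls, n: int, fov: tuple[float, float], margin: float = 2.0, min_spacing: float = 2.0
    ) -> "SiteLayout":
        """``n`` isolated docking sites on a jittered grid covering the field of view."""
        w, h = fov
        cols = int(np.ceil(np.sqrt(n * w / h)))
        rows = int(np.ceil(n / cols))
        if cols * min_spacing > w - 2 * margin or rows * min_spacing > h - 2 * margin:
            raise ParameterError("field of view too small for requested site count")
        xs = np.linspace(margin, w - margin, cols)
        ys = np.linspace(margin, h - margin, rows)
        gx, gy = np.meshgrid(xs, ys)
        pos = np.column_stack([gx.ravel(), gy.ravel()])[:n]
        return cls(kind="custom", positions=pos, metadata={"n": n})

    @classmethod
    def grid20(
        cls,
        n_structures: int,
        fov: tuple[float, float],
        pixel_size: float = 130.0,
        rows: int = 4,
        cols: int = 3,
        spacing_nm: float = 20.0,
        margin: float = 3.0,
    ) -> "SiteLayout":
        """Origami structures each carrying a rows x cols grid of 20-nm-spaced sites."""
        centers = cls.single_sites(n_structures, fov, margin=margin).positions
        pitch = spacing_nm / pixel_size
        offx = (np.arange(cols) - (cols - 1) / 2.0) * pitch
        offy = (np.arange(rows) - (rows - 1) / 2.0) * pitch
        ox, oy = np.meshgrid(offx, offy)
        offsets = np.column_stack([ox.ravel(), oy.ravel()])
        pos = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        return cls(
            kind="grid20",
            positions=pos,
            metadata={
                "n_structures": n_structures,
                "sites_per_structure": rows * cols,
                "spacing_nm": spacing_nm,
            },
        )

    @classmethod
    def crosshair(
        cls,
        n_structures: int,
        fov: tuple[float, float],
        pixel_size: float = 130.0,
        arm_nm: float = 50.0,
        margin: float = 3.0,
    ) -> "SiteLayout":
        """Crosshair origami: one center site (the dye-of-interest docking site)
        plus four barcode arms; a complete structure shows exactly five clusters."""
        centers = cls.single_sites(n_structures, fov, margin=margin).positions
        arm = arm_nm / pixel_size
        offsets = np.array([[0.0, 0.0], [arm, 0.0], [-arm, 0.0], [0.0, arm], [0.0, -arm]])
        pos = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        return cls(
            kind="crosshair",
            positions=pos,
            metadata={
                "n_structures": n_structures,
                "sites_per_structure": 5,
                "arm_nm": arm_nm,
                "target_offset": (0.0, 0.0),  # the center cluster carries the dye of interest
            },
        )

    @classmethod
    def npc(
        cls,
        n_structures: int,
        fov: tuple[float, float],
        pixel_size: float = 130.0,
        ring_radius_nm: float = 53.7,
        pair_sep_nm: float = 12.0,
        margin: float = 3.0,
    ) -> "SiteLayout":
        """NPC-like geometry: eightfold radially symmetric Nup96 pairs on a ring
        (nuclear and cytoplasmic rings coincide in 2D projection)."""
        centers = cls.single_sites(n_structures, fov, margin=margin).positions
        r = ring_radius_nm / pixel_size
        half = pair_sep_nm / 2.0 / pixel_size
        base = np.arange(8) * (2 * np.pi / 8)
        dphi = half / r
        ang = np.concatenate([base - dphi, base + dphi])
        offsets = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        pos = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        return cls(
            kind="npc",
            positions=pos,
            metadata={
                "n_structures": n_structures,
                "sites_per_structure": 16,
                "ring_radius_nm": ring_radius_nm,
            },
        )


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimConfig:
    """Full generative-model parameter set.

    Defaults correspond to a well-behaved green-absorbing dye measured at
    100 ms exposure on a 130-nm-pixel camera; kinetics, photon budget and
    photodamage are all overridable per run.
    """

    tau_b: float = 0.35  # mean bright time, s
    tau_d: float = 5.0  # mean dark time, s
    photon_rate: float = 23195.0  # expected photons per fully bound 100 ms
    bg_rate: float = 50.0  # expected background photons per pixel per frame
    exposure: float = 0.1  # frame time, s
    n_frames: int = 10000
    pixel_size: float = 130.0  # nm per pixel
    psf_sigma: float = 0.85  # PSF standard deviation, pixels
    destroy_fraction: float = 0.0  # fraction of sites destroyed during acquisition
    destroy_at_start: bool = False  # destruction at t=0 instead of a uniform random time
    onrate_decay: float = 0.0  # 1/s; 0 = stable effective on-rate
    sticking_density: float = 0.0  # off-target one-frame events per um^2 per frame
    min_photons: float = 100.0  # detection limit: dimmer spots yield no localization
    width: int = 64  # image width, pixels
    height: int = 64  # image height, pixels
    layout: SiteLayout | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_b <= 0 or self.tau_d <= 0:
            raise ParameterError("tau_b and tau_d must be positive")
        if self.exposure <= 0:
            raise ParameterError("exposure must be positive")
        if not 0.0 <= self.destroy_fraction <= 1.0:
            raise ParameterError("destroy_fraction must lie in [0, 1]")
        if self.photon_rate < 0 or self.bg_rate < 0:
            raise ParameterError("photon_rate and bg_rate must be non-negative")
        if self.layout is None:
            self.layout = SiteLayout.single_sites(
                25, fov=(self.width, self.height), margin=2.0
            )

    @property
    def duration(self) -> float:
        """Measurement duration in seconds."""
        return self.n_frames * self.exposure


@dataclass
class GroundTruth:
    """Simulation bookkeeping: what was actually generated.

    ``sites`` has one row per docking site (id, x, y, destruction_time with
    NaN = never destroyed); ``events`` maps site id to its (start, end)
    intervals in seconds; ``origin`` holds, per localization-table row, the
    originating site id or -1 for a sticking event.
    """

    sites: pd.DataFrame
    events: dict[int, list[tuple[float, float]]]
    origin: np.ndarray

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "sites": self.sites.to_dict(orient="list"),
            "events": {str(k): [list(map(float, ev)) for ev in v] for k, v in self.events.items()},
            "origin": self.origin.tolist(),
        }
        with open(path, "w") as f:
            json.dump(payload, f)
        return path


# ---------------------------------------------------------------------------
# Event stream


def generate_event_stream(
    tau_b: float,
    tau_d: float,
    duration_s: float,
    destruction_time: float | None = None,
    onrate_decay: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Sample one site's binding events as an alternating renewal process.

    The process starts unbound at t=0.  Dark gaps are drawn from an
    inhomogeneous exponential with instantaneous rate
    ``(1/tau_d) * exp(-onrate_decay * t)`` (progressive loss of effective
    on-rate); bright durations are exponential with mean ``tau_b``.  Events
    are truncated at ``min(duration_s, destruction_time)``.
    """
    if tau_b <= 0 or tau_d <= 0:
        raise ParameterError("tau_b and tau_d must be positive")
    if duration_s < 0:
        raise ParameterError("duration_s must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    t_stop = duration_s if destruction_time is None else min(duration_s, destruction_time)
    events: list[tuple[float, float]] = []
    t = 0.0
    lam0 = 1.0 / tau_d
    k = onrate_decay
    while t < t_stop:
        u = rng.exponential(1.0)  # -log of a uniform
        if k == 0.0:
            wait = u * tau_d
        else:
            # survival: integral of lam0*exp(-k s) over [t, t+w] equals u
            rhs = np.exp(-k * t) - k * u / lam0
            if rhs <= 0.0:
                break  # the on-rate has decayed away; no further binding
            wait = -np.log(rhs) / k - t
        t_start = t + wait
        if t_start >= t_stop:
            break
        t_end = min(t_start + rng.exponential(tau_b), t_stop)
        events.append((t_start, t_end))
        t = t_end
    return events


def discretize_events(
    events: list[tuple[float, float]],
    exposure: float,
    photon_rate: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Map binding events onto camera frames and draw per-frame photon counts.

    For every frame a bright period overlaps, the covered fraction of the
    frame is ``overlap / exposure`` in (0, 1]; the photon count is Poisson
    with mean ``photon_rate * (exposure / 0.1 s) * fraction`` (``photon_rate``
    is referenced to a fully bound 100 ms).  Consecutive frames of one event
    share an event id.

    Returns a DataFrame with columns ``event_id, frame, fraction, photons``.
    """
    if exposure <= 0:
        raise ParameterError("exposure must be positive")
    rng = np.random.default_rng() if rng is None else rng
    rows_event, rows_frame, rows_frac = [], [], []
    for eid, (t0, t1) in enumerate(events):
        first = int(np.floor(t0 / exposure))
        last = int(np.ceil(t1 / exposure)) - 1
        if last < first:
            last = first
        frames = np.arange(first, last + 1)
        lo = np.maximum(t0, frames * exposure)
        hi = np.minimum(t1, (frames + 1) * exposure)
        frac = np.clip((hi - lo) / exposure, 0.0, 1.0)  # guard float round-off
        keep = frac > 0
        rows_event.append(np.full(keep.sum(), eid))
        rows_frame.append(frames[keep])
        rows_frac.append(frac[keep])
    if rows_event:
        event_id = np.concatenate(rows_event)
        frame = np.concatenate(rows_frame)
        fraction = np.concatenate(rows_frac)
    else:
        event_id = np.empty(0, dtype=int)
        frame = np.empty(0, dtype=int)
        fraction = np.empty(0)
    mean_photons = photon_rate * (exposure / 0.1) * fraction
    photons = rng.poisson(mean_photons)
    return pd.DataFrame(
        {
            "event_id": event_id.astype(np.int64),
            "frame": frame.astype(np.int64),
            "fraction": fraction,
            "photons": photons.astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# Full generative model


def emit_localizations(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[LocalizationTable, GroundTruth]:
    """Run the full generative model and return a localization table + ground truth.

    Per docking site the bright/dark process is sampled, discretized into
    frames and converted into localizations: position = site position plus
    isotropic Gaussian jitter with the Mortensen sigma at that localization's
    photons and background.  Frames whose Poisson photon draw is zero produce
    no localization.  Sticking events are one-frame localizations placed
    uniformly over the field of view.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    layout = config.layout
    if layout is None or len(layout) == 0:
        raise ParameterError("layout must contain at least one site")
    duration = config.duration

    destroyed = rng.random(len(layout)) < config.destroy_fraction
    draw = 0.0 if config.destroy_at_start else rng.uniform(0.0, duration, len(layout))
    destruction_times = np.where(destroyed, draw, np.nan)

    frames_all, x_all, y_all, photons_all, origin_all = [], [], [], [], []
    events_by_site: dict[int, list[tuple[float, float]]] = {}
    for sid, (sx_pos, sy_pos) in enumerate(layout.positions):
        dt = destruction_times[sid]
        ev = generate_event_stream(
            config.tau_b,
            config.tau_d,
            duration,
            destruction_time=None if np.isnan(dt) else float(dt),
            onrate_decay=config.onrate_decay,
            rng=rng,
        )
        events_by_site[sid] = ev
        rec = discretize_events(ev, config.exposure, config.photon_rate, rng=rng)
        # a sub-frame dark gap puts two events into one frame: one spot on camera
        rec = rec.groupby("frame", as_index=False)["photons"].sum()
        rec = rec[rec["photons"] >= max(config.min_photons, 1.0)]
        n = len(rec)
        if n == 0:
            continue
        sig = mortensen_sigma(
            rec["photons"].to_numpy(), config.bg_rate, config.psf_sigma, pixel_size=1.0
        )
        jitter = rng.normal(size=(n, 2)) * sig[:, None]
        frames_all.append(rec["frame"].to_numpy())
        x_all.append(sx_pos + jitter[:, 0])
        y_all.append(sy_pos + jitter[:, 1])
        photons_all.append(rec["photons"].to_numpy())
        origin_all.append(np.full(n, sid))

    # off-target sticking: single-frame events, uniform in space and time,
    # with a uniform partial-frame photon fraction (sub-frame dwell)
    if config.sticking_density > 0:
        area_um2 = (config.width * config.pixel_size / 1000.0) * (
            config.height * config.pixel_size / 1000.0
        )
        n_stick = rng.poisson(config.sticking_density * area_um2 * config.n_frames)
        if n_stick > 0:
            sf = rng.integers(0, config.n_frames, n_stick)
            sx = rng.uniform(0.0, config.width, n_stick)
            sy = rng.uniform(0.0, config.height, n_stick)
            frac = rng.uniform(0.0, 1.0, n_stick)
            sp = rng.poisson(config.photon_rate * (config.exposure / 0.1) * frac)
            keep = sp >= max(config.min_photons, 1.0)
            if keep.any():
                frames_all.append(sf[keep])
                x_all.append(sx[keep])
                y_all.append(sy[keep])
                photons_all.append(sp[keep])
                origin_all.append(np.full(keep.sum(), -1))

    if frames_all:
        frame = np.concatenate(frames_all)
        x = np.concatenate(x_all)
        y = np.concatenate(y_all)
        photons = np.concatenate(photons_all).astype(float)
        origin = np.concatenate(origin_all)
    else:
        frame = np.empty(0, dtype=np.int64)
        x = y = photons = np.empty(0)
        origin = np.empty(0, dtype=np.int64)

    # keep localizations on the sensor (jitter can nudge edge sites out)
    eps = 1e-9
    x = np.clip(x, 0.0, config.width - eps)
    y = np.clip(y, 0.0, config.height - eps)

    lp = (
        mortensen_sigma(photons, config.bg_rate, config.psf_sigma, pixel_size=1.0)
        if len(photons)
        else np.empty(0)
    )
    df = pd.DataFrame(
        {
            "frame": frame.astype(np.int64),
            "x": x,
            "y": y,
            "photons": photons,
            "sx": np.full(len(x), config.psf_sigma),
            "sy": np.full(len(x), config.psf_sigma),
            "bg": np.full(len(x), float(config.bg_rate)),
            "lpx": lp,
            "lpy": lp,
        }
    )
    order = np.lexsort((origin, df["frame"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    origin = origin[order]

    table = LocalizationTable(
        locs=df,
        exposure=config.exposure,
        pixel_size=config.pixel_size,
        width=config.width,
        height=config.height,
    )
    truth = GroundTruth(
        sites=pd.DataFrame(
            {
                "site_id": np.arange(len(layout)),
                "x": layout.positions[:, 0],
                "y": layout.positions[:, 1],
                "destruction_time": destruction_times,
            }
        ),
        events=events_by_site,
        origin=origin,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Raw-movie rendering


def render_movie(
    table: LocalizationTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    shot_noise: bool = False,
) -> np.ndarray:
    """Render a localization table into a raw movie (photon-count pixel units).

    Each frame is the sum of pixel-integrated 2D Gaussians (mass = the
    localization's photon count, width = its fitted PSF sigma) plus Poisson
    background at ``config.bg_rate`` per pixel.  With ``shot_noise=True`` the
    Poisson draw is applied to signal+background jointly (full photon shot
    noise); otherwise the signal enters at its expected value.  No camera
    gain, offset or read noise is modeled.
    """
    shape = (config.height, config.width)
    movie = np.zeros((config.n_frames, *shape))
    locs = table.locs
    for f, sub in locs.groupby("frame"):
        img = movie[int(f)]
        for row in sub.itertuples(index=False):
            img += pixel_gaussian(row.x, row.y, row.photons, row.sx, row.sy, shape)
    if shot_noise:
        rng = np.random.default_rng() if rng is None else rng
        movie = rng.poisson(movie + config.bg_rate).astype(float)
    elif config.bg_rate > 0:
        rng = np.random.default_rng() if rng is None else rng
        movie += rng.poisson(config.bg_rate, size=movie.shape)
    return movie


def write_movie(movie: np.ndarray, path: str | Path) -> Path:
    """Write a movie as a multi-page TIFF (float32 photon counts)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
    return path


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable echo of a configuration (provenance logging)."""
    d = asdict(config)
    layout = d.pop("layout")
    if layout is not None:
        d["layout"] = {
            "kind": layout["kind"],
            "n_sites": len(layout["positions"]),
            "metadata": layout["metadata"],
        }
    return d
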