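"""Binding-event kinetics and photometry.

Successive localizations from one docking site almost certainly stem from a
single imager binding event, so runs of consecutive frames are linked into
events.  From the events the module derives the quantities a dye benchmark
reports:

* mean bright and dark times per site, via a single-exponential fit to the
  empirical CDF of the observed durations;
* photon output per 100 ms from "center frames" — frames of events at least
  three frames long that are neither first nor last, the only frames
  guaranteed to have recorded a continuously bound imager;
* signal-to-background ratio — the fitted PSF integrated over a 1x1 pixel
  centered at its maximum, divided by the per-pixel background offset;
* sampling stability (localizations per site per time window) and the
  localization drop over the measurement;
* the docking-site destruction statistic: per site, the ratio
  ``r = t_end / tau_d`` of the time from the last event to the end of the
  measurement over the site's mean dark time.  Without destruction the
  ``r`` histogram is exponential with mean 1; the excess beyond ``4*mu``
  (minus the 1/e^4 = 1.83% an exponential places there) estimates the
  destroyed-site percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .exceptions import DegenerateFitError, InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

TAIL_CORRECTION_PCT = 100.0 * np.exp(-4.0)  # share of a unit exponential beyond 4x its mean


@dataclass
class BindingEvent:
    """A maximal run of consecutive-frame localizations at one docking site."""

    site_id: int
    start: int  # first frame, inclusive
    end: int  # last frame, inclusive
    photons: np.ndarray  # per-frame photon counts

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_center_eligible(self) -> bool:
        return self.length >= 3

    def center_photons(self) -> np.ndarray:
        return self.photons[1:-1]


def link_events(
    frames,
    photons=None,
    site_id: int = 0,
    max_dark_frames: int = 0,
) -> list[BindingEvent]:
    """Partition one site's localizations into binding events.

    ``frames`` must be sorted; a gap larger than ``max_dark_frames`` empty
    frames starts a new event (strict consecutiveness by default).  Duplicate
    frames at one site are an error: the simulator never emits them and on
    real data they indicate a linking problem upstream.
    """
    frames = np.asarray(frames, dtype=np.int64)
    if len(frames) == 0:
        return []
    photons = np.zeros(len(frames)) if photons is None else np.asarray(photons, dtype=float)
    d = np.diff(frames)
    if (d <= 0).any():
        if (d == 0).any():
            raise ParameterError(f"duplicate frame at site {site_id}")
        raise ParameterError("frames must be sorted ascending")
    breaks = np.flatnonzero(d > max_dark_frames + 1) + 1
    events = []
    for chunk_f, chunk_p in zip(np.split(frames, breaks), np.split(photons, breaks)):
        events.append(
            BindingEvent(
                site_id=site_id,
                start=int(chunk_f[0]),
                end=int(chunk_f[-1]),
                photons=chunk_p,
            )
        )
    return events


def fit_mean_time(
    durations_s,
    min_events: int = 10,
    min_duration: float | None = None,
    max_quantile: float = 1.0,
    full: bool = False,
):
    """Mean dwell time from a single-exponential fit to the empirical CDF.

    The empirical CDF is evaluated at every sorted observed duration and
    ``F(t) = 1 - A*exp(-t/tau)`` is fitted by unweighted least squares.

    Camera discretization makes observed durations whole numbers of frames;
    for an exponential dwell the multi-frame duration classes still fall
    exactly on a single-exponential CDF with the true mean (and a non-unit
    amplitude), but the one-frame class does not and would bias the fit.
    ``min_duration`` (typically 1.5 frame times) therefore restricts the
    fitted abscissae to longer durations while the ECDF itself is computed
    from all of them; the free amplitude absorbs the discretization offset.
    ``max_quantile`` < 1 likewise excludes the extreme upper tail from the
    fitted abscissae — two binding events separated by a sub-frame dark gap
    are recorded by the camera as one long event, and those rare merged
    durations contaminate only the tail (for an exponential the trimmed fit
    stays exact).  On continuous exponential data A fits to ~1 and tau
    matches the sample-mean MLE.

    Raises ``InsufficientDataError`` below ``min_events`` durations and
    ``DegenerateFitError`` when the fit is degenerate (e.g. all durations
    identical).
    """
    t = np.sort(np.asarray(durations_s, dtype=float))
    if len(t) < min_events:
        raise InsufficientDataError(
            f"{len(t)} durations; need at least {min_events} for a CDF fit"
        )
    if t[0] == t[-1]:
        raise DegenerateFitError("all durations identical; exponential fit degenerate")
    ecdf = np.arange(1, len(t) + 1) / len(t)
    keep = np.ones(len(t), dtype=bool)
    if min_duration is not None:
        keep &= t >= min_duration
    if max_quantile < 1.0:
        keep &= ecdf <= max_quantile
    if keep.sum() < 3 or len(np.unique(t[keep])) < 2:
        raise DegenerateFitError("too few distinct durations in the fit range for a CDF fit")
    t_fit, ecdf_fit = t[keep], ecdf[keep]

    def model(x, tau, amp):
        return 1.0 - amp * np.exp(-x / tau)

    tau0 = float(np.mean(t))
    popt, _ = curve_fit(
        model, t_fit, ecdf_fit, p0=[tau0, 1.0], bounds=([1e-12, 0.0], [np.inf, 10.0]),
        maxfev=10000,
    )
    tau, amp = float(popt[0]), float(popt[1])
    if full:
        return tau, amp
    return tau


def camera_merge_probability(tau_d: float, exposure: float) -> float:
    """Probability that a dark gap leaves no empty frame on camera.

    Two binding events separated by such a gap are recorded as one event.
    For an exponential gap of mean ``tau_d`` starting uniformly within a
    frame of length ``exposure``, the gap is invisible iff it ends before
    the end of the following frame:
    ``p = 1 - exp(-2 e/tau_d) * (tau_d/e) * (exp(e/tau_d) - 1)``.
    """
    x = exposure / tau_d
    return float(1.0 - np.exp(-2.0 * x) * np.expm1(x) / x)


def correct_merged_bright_time(tau_b_obs: float, tau_d: float, exposure: float) -> float:
    """Remove the camera-merge inflation from an observed mean bright time.

    An observed event concatenates a geometric number of true bright periods
    joined by invisible gaps, so to first order in the merge probability p
    the observed mean is ``tau_b/(1-p) + p/(1-p) * g`` with ``g = 7e/9`` the
    mean invisible gap; inverting gives the true bright time.
    """
    p = camera_merge_probability(tau_d, exposure)
    return max(tau_b_obs * (1.0 - p) - p * (7.0 * exposure / 9.0), exposure / 2.0)


@dataclass
class SiteTrace:
    """One docking site with its events and kinetic estimates."""

    site_id: int
    position: tuple[float, float]
    events: list[BindingEvent]
    tau_b: float = np.nan  # mean bright time, s (camera-merge corrected)
    tau_b_observed: float = np.nan  # mean bright time before merge correction
    tau_d: float = np.nan  # mean dark time, s
    t_end: float = np.nan  # time from last event end to measurement end, s
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def n_locs(self) -> int:
        return sum(ev.length for ev in self.events)

    @property
    def r(self) -> float:
        """Destruction ratio t_end / tau_d (NaN when tau_d is unavailable)."""
        if not np.isfinite(self.tau_d) or self.tau_d <= 0:
            return np.nan
        return self.t_end / self.tau_d

    def bright_durations(self, exposure: float) -> np.ndarray:
        return np.array([ev.length * exposure for ev in self.events])

    def dark_durations(self, exposure: float) -> np.ndarray:
        """Gaps between consecutive events (first-event lead-in excluded)."""
        if len(self.events) < 2:
            return np.empty(0)
        starts = np.array([ev.start for ev in self.events[1:]])
        ends = np.array([ev.end for ev in self.events[:-1]])
        return (starts - ends - 1) * exposure


def assign_localizations_to_sites(table, positions, radius: float = 0.75) -> np.ndarray:
    """Map each localization to the nearest known site within ``radius`` pixels.

    Returns per-row site indices (-1 = unassigned, e.g. sticking).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    pts = table.locs[["x", "y"]].to_numpy()
    tree = cKDTree(positions)
    d, idx = tree.query(pts, k=1, distance_upper_bound=radius)
    idx = np.where(np.isfinite(d), idx, -1)
    return idx.astype(np.int64)


def build_site_traces(
    table,
    positions,
    radius: float = 0.75,
    min_events: int = 10,
    max_dark_frames: int = 0,
    duration_s: float | None = None,
) -> list[SiteTrace]:
    """Link events and fit per-site kinetics for every known docking site.

    ``duration_s`` is the measurement length used for ``t_end``; by default it
    is inferred from the highest observed frame.  Sites with too few bright or
    dark durations for the CDF fit are retained but marked ``excluded`` (and
    logged); downstream estimators skip them.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    assignment = assign_localizations_to_sites(table, positions, radius=radius)
    frames = table.locs["frame"].to_numpy()
    photons = table.locs["photons"].to_numpy()
    duration = table.duration if duration_s is None else float(duration_s)
    traces: list[SiteTrace] = []
    for sid in range(len(positions)):
        sel = np.flatnonzero(assignment == sid)
        sel = sel[np.argsort(frames[sel], kind="stable")]
        events = link_events(
            frames[sel], photons[sel], site_id=sid, max_dark_frames=max_dark_frames
        )
        tr = SiteTrace(
            site_id=sid, position=(float(positions[sid, 0]), float(positions[sid, 1])), events=events
        )
        if events:
            tr.t_end = duration - (events[-1].end + 1) * table.exposure
        # exclude the discretization-corrupted 1-frame class and the merged-event tail
        min_dur = 1.5 * table.exposure
        try:
            tr.tau_b = fit_mean_time(
                tr.bright_durations(table.exposure),
                min_events=min_events,
                min_duration=min_dur,
                max_quantile=0.95,
            )
        except (InsufficientDataError, DegenerateFitError) as exc:
            tr.excluded = True
            tr.exclusion_reason = f"bright: {exc}"
        try:
            tr.tau_d = fit_mean_time(
                tr.dark_durations(table.exposure),
                min_events=min_events,
                min_duration=min_dur,
                max_quantile=0.95,
            )
        except (InsufficientDataError, DegenerateFitError) as exc:
            tr.excluded = True
            tr.exclusion_reason = (tr.exclusion_reason or "") + f" dark: {exc}"
        tr.tau_b_observed = tr.tau_b
        if np.isfinite(tr.tau_b) and np.isfinite(tr.tau_d):
            tr.tau_b = correct_merged_bright_time(tr.tau_b, tr.tau_d, table.exposure)
        if tr.excluded:
            logger.debug("site %d excluded: %s", sid, tr.exclusion_reason)
        traces.append(tr)
    n_exc = sum(t.excluded for t in traces)
    if n_exc:
        logger.info("excluded %d/%d sites with too few events", n_exc, len(traces))
    return traces


def mean_bright_time(traces: list[SiteTrace]) -> float:
    """Measurement-level mean bright time: unweighted mean of per-site fits."""
    vals = [t.tau_b for t in traces if not t.excluded and np.isfinite(t.tau_b)]
    if not vals:
        raise InsufficientDataError("no site with a valid bright-time fit")
    return float(np.mean(vals))


def mean_dark_time(traces: list[SiteTrace]) -> float:
    vals = [t.tau_d for t in traces if not t.excluded and np.isfinite(t.tau_d)]
    if not vals:
        raise InsufficientDataError("no site with a valid dark-time fit")
    return float(np.mean(vals))


def center_frame_photons(events: list[BindingEvent], exposure: float) -> tuple[float, int]:
    """Mean photons per 100 ms over all center frames.

    Center frames are the non-terminal frames of events at least three frames
    long; their photon counts are scaled by ``0.1 s / exposure``.  Returns
    ``(mean, n_frames)``; the mean is NaN (flagged) when no frame qualifies.
    """
    if exposure <= 0:
        raise ParameterError("exposure must be positive")
    chunks = [ev.center_photons() for ev in events if ev.is_center_eligible]
    if not chunks:
        return np.nan, 0
    vals = np.concatenate(chunks) * (0.1 / exposure)
    return float(np.mean(vals)), len(vals)


def compute_sbr(photons, bg, sx, sy):
    """Per-localization signal-to-background ratio.

    The fitted PSF (total mass = photon count) is integrated over a 1x1 pixel
    centered at its maximum and divided by the per-pixel background offset;
    the area term cancels, leaving a unitless ratio.  Vectorized.
    """
    from .psf import central_pixel_fraction

    photons = np.asarray(photons, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if np.any(bg <= 0):
        raise ParameterError("background must be positive for an SBR")
    return photons * central_pixel_fraction(sx, sy) / bg


def measurement_sbr(table, center_mask) -> tuple[float, int]:
    """Mean SBR over center-frame localizations with positive background.

    ``center_mask`` selects the center-frame rows of ``table.locs``;
    localizations with non-positive background are excluded (logged).
    """
    sub = table.locs[np.asarray(center_mask, dtype=bool)]
    ok = sub["bg"] > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("excluding %d localizations with non-positive background", n_bad)
    sub = sub[ok]
    if not len(sub):
        return np.nan, 0
    vals = compute_sbr(sub["photons"], sub["bg"], sub["sx"], sub["sy"])
    return float(np.mean(vals)), len(sub)


def center_frame_mask(table, assignment, max_dark_frames: int = 0) -> np.ndarray:
    """Boolean mask over table rows marking center frames of site-linked events."""
    frames = table.locs["frame"].to_numpy()
    mask = np.zeros(len(frames), dtype=bool)
    for sid in np.unique(assignment):
        if sid < 0:
            continue
        sel = np.flatnonzero(assignment == sid)
        sel = sel[np.argsort(frames[sel], kind="stable")]
        f = frames[sel]
        d = np.diff(f)
        breaks = np.flatnonzero(d > max_dark_frames + 1) + 1
        for chunk in np.split(sel, breaks):
            if len(chunk) >= 3:
                mask[chunk[1:-1]] = True
    return mask


@dataclass
class StabilityResult:
    """Localizations per docking site per time window, and the drop over time."""

    window_s: float
    per_window_mean: np.ndarray  # mean localizations per site, one entry per window
    drop_pct: float  # 100*(1 - last/first), clamped to [0, 100]
    drop_pct_raw: float  # unclamped value


def stability_trace(
    traces: list[SiteTrace],
    duration_s: float,
    exposure: float,
    window_s: float = 20.0,
) -> StabilityResult:
    """Average per-site localization counts in consecutive time windows.

    The localization drop compares the last full window with the first:
    ``100*(1 - last/first)``.  Requires at least two full windows; a zero
    first-window mean leaves the drop undefined.
    """
    n_windows = int(np.floor(duration_s / window_s))
    if n_windows < 2:
        raise ParameterError(
            f"duration {duration_s:.3g}s holds {n_windows} window(s); need at least 2"
        )
    frames_per_window = window_s / exposure
    counts = np.zeros((len(traces), n_windows))
    for i, tr in enumerate(traces):
        for ev in tr.events:
            for f in range(ev.start, ev.end + 1):
                w = int(f / frames_per_window)
                if w < n_windows:
                    counts[i, w] += 1
    per_window = counts.mean(axis=0)
    if per_window[0] == 0:
        raise InsufficientDataError("no localizations in the first window; drop undefined")
    raw = 100.0 * (1.0 - per_window[-1] / per_window[0])
    return StabilityResult(
        window_s=window_s,
        per_window_mean=per_window,
        drop_pct=float(np.clip(raw, 0.0, 100.0)),
        drop_pct_raw=float(raw),
    )


@dataclass
class DestructionResult:
    """Exponential fit of the r-histogram and the corrected destroyed-site share."""

    mu: float  # fitted mean of the exponential decay
    amplitude: float
    destroyed_pct: float  # after subtracting the 1/e^4 exponential tail share
    tail_pct_raw: float  # uncorrected % of sites with r > tail_factor*mu
    bin_edges: np.ndarray
    counts: np.ndarray
    r_values: np.ndarray
    n_sites: int


def destruction_statistic(
    traces: list[SiteTrace],
    bin_width: float = 0.25,
    tail_factor: float = 4.0,
    min_sites: int = 100,
    skip_first_bin: bool = True,
) -> DestructionResult:
    """Destroyed-docking-site percentage from the last-event-to-end statistic.

    Per site ``r = t_end / tau_d``; the histogram of ``r`` (bin width 0.25
    over [0, max(10, max r)]) is fitted with ``a*exp(-(1/mu)*r)`` by least
    squares over its non-empty bins.  Sites with ``r > tail_factor*mu`` are
    counted as destroyed; since a unit exponential itself places 1/e^4 = 1.83%
    of sites beyond 4x its mean, that share is subtracted (floored at zero).

    Sites still sampling when the measurement ends (an imager bound at, or
    binding right before, the cutoff) pile up at ``r ~ 0`` on top of the
    exponential; ``skip_first_bin`` therefore drops the first histogram bin
    from the fit (the free amplitude makes the truncated fit exact for an
    exponential).
    """
    r = np.array([t.r for t in traces if not t.excluded])
    r = r[np.isfinite(r)]
    if len(r) < min_sites:
        raise InsufficientDataError(f"{len(r)} usable sites; need at least {min_sites}")
    upper = max(10.0, float(r.max()))
    edges = np.arange(0.0, upper + bin_width, bin_width)
    counts, edges = np.histogram(r, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonzero = counts > 0
    if skip_first_bin and np.count_nonzero(counts[1:]) >= 2:
        nonzero[0] = False

    def model(x, a, mu):
        return a * np.exp(-x / mu)

    if np.count_nonzero(nonzero) < 2:
        # all mass in one bin: effectively no spread in r
        (only,) = np.flatnonzero(nonzero)
        mu = max(float(centers[only]), bin_width / 10.0)
        tail_pct = 100.0 * float(np.mean(r > tail_factor * mu))
        return DestructionResult(
            mu=mu,
            amplitude=float(counts[only]),
            destroyed_pct=max(0.0, tail_pct - TAIL_CORRECTION_PCT),
            tail_pct_raw=tail_pct,
            bin_edges=edges,
            counts=counts,
            r_values=r,
            n_sites=len(r),
        )

    try:
        popt, _ = curve_fit(
            model,
            centers[nonzero],
            counts[nonzero],
            p0=[float(counts.max()), 1.0],
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        err = DegenerateFitError(f"r-histogram fit failed: {exc}")
        err.histogram = (edges, counts)
        raise err
    a_fit, mu = float(popt[0]), float(popt[1])
    tail_pct = 100.0 * float(np.mean(r > tail_factor * mu))
    destroyed = max(0.0, tail_pct - TAIL_CORRECTION_PCT)
    return DestructionResult(
        mu=mu,
        amplitude=a_fit,
        destroyed_pct=destroyed,
        tail_pct_raw=tail_pct,
        bin_edges=edges,
        counts=counts,
        r_values=r,
        n_sites=len(r),
    )
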