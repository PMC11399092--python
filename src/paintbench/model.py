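"""Top-level modelling interface: one object per measurement.

`DyePerformanceModel` wraps a localization table plus the known (or
identified) docking-site positions and, on ``fit()``, runs the complete
benchmarking analysis — event linking, bright/dark-time CDF fits,
center-frame photometry, SBR, NeNA precision, sampling stability and the
destruction statistic — returning a `DyePerformanceResults` object that
carries the estimates, their across-site spreads and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics, precision
from .exceptions import InsufficientDataError, ParameterError
from .kinetics import (
    DestructionResult,
    SiteTrace,
    StabilityResult,
    build_site_traces,
    center_frame_mask,
    center_frame_photons,
    measurement_sbr,
)
from .locio import LocalizationTable
from .precision import NeNAResult


class DyePerformanceModel:
    """Dye-performance analysis of one DNA-PAINT measurement.

    Parameters
    ----------
    table : LocalizationTable
    site_positions : (n, 2) array of docking-site positions in pixels
    site_radius : assignment radius around each site, pixels
    min_events : minimum bright/dark durations per site for the kinetics fit
    min_sites : minimum usable sites for the destruction statistic
    window_s : stability window length, seconds
    duration_s : measurement duration; inferred from the data when omitted
    """

    def __init__(
        self,
        table: LocalizationTable,
        site_positions,
        *,
        site_radius: float = 0.75,
        min_events: int = 10,
        min_sites: int = 100,
        window_s: float = 20.0,
        duration_s: float | None = None,
        nena_min_pairs: int = 1000,
        nena_bin_width: float | None = None,
        destruction_bin_width: float = 0.25,
        tail_factor: float = 4.0,
    ) -> None:
        self.table = table
        self.site_positions = np.atleast_2d(np.asarray(site_positions, dtype=float))
        if self.site_positions.size == 0:
            raise ParameterError("at least one docking-site position required")
        self.site_radius = site_radius
        self.min_events = min_events
        self.min_sites = min_sites
        self.window_s = window_s
        self.duration_s = table.duration if duration_s is None else float(duration_s)
        self.nena_min_pairs = nena_min_pairs
        self.nena_bin_width = nena_bin_width
        self.destruction_bin_width = destruction_bin_width
        self.tail_factor = tail_factor
        self.sim_config = None
        self.ground_truth = None

    @classmethod
    def from_simulation(cls, config, **kwargs) -> "DyePerformanceModel":
        """Simulate a measurement and analyze it against the ground-truth sites."""
        from .sim import emit_localizations

        table, truth = emit_localizations(config)
        model = cls(
            table,
            truth.sites[["x", "y"]].to_numpy(),
            duration_s=config.duration,
            **kwargs,
        )
        model.sim_config = config
        model.ground_truth = truth
        return model

    def fit(self) -> "DyePerformanceResults":
        table = self.table
        traces = build_site_traces(
            table,
            self.site_positions,
            radius=self.site_radius,
            min_events=self.min_events,
            duration_s=self.duration_s,
        )
        valid = [t for t in traces if not t.excluded]

        def site_mean(attr):
            vals = np.array([getattr(t, attr) for t in valid])
            vals = vals[np.isfinite(vals)]
            if not len(vals):
                return np.nan, np.nan
            return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan

        tau_b, tau_b_sd = site_mean("tau_b")
        tau_d, tau_d_sd = site_mean("tau_d")

        all_events = [ev for t in traces for ev in t.events]
        photons_mean, n_center = center_frame_photons(all_events, table.exposure)

        assignment = kinetics.assign_localizations_to_sites(
            table, self.site_positions, radius=self.site_radius
        )
        cmask = center_frame_mask(table, assignment)
        sbr_mean, n_sbr = measurement_sbr(table, cmask)

        nena: NeNAResult | None
        try:
            nena = precision.nena_sigma(
                table, min_pairs=self.nena_min_pairs, bin_width=self.nena_bin_width
            )
        except InsufficientDataError:
            nena = None

        stability: StabilityResult | None
        try:
            stability = kinetics.stability_trace(
                traces, self.duration_s, table.exposure, window_s=self.window_s
            )
        except (ParameterError, InsufficientDataError):
            stability = None

        destruction: DestructionResult | None
        try:
            destruction = kinetics.destruction_statistic(
                traces,
                bin_width=self.destruction_bin_width,
                tail_factor=self.tail_factor,
                min_sites=self.min_sites,
            )
        except InsufficientDataError:
            destruction = None

        return DyePerformanceResults(
            model=self,
            traces=traces,
            tau_b=tau_b,
            tau_b_sd=tau_b_sd,
            tau_d=tau_d,
            tau_d_sd=tau_d_sd,
            photons_per_100ms=photons_mean,
            n_center_frames=n_center,
            sbr=sbr_mean,
            n_sbr=n_sbr,
            nena=nena,
            stability=stability,
            destruction=destruction,
        )


class DyePerformanceResults:
    """Estimates from one fitted measurement.

    Attributes mirror the benchmark's reported metrics; ``nena``,
    ``stability`` and ``destruction`` hold the full component results (or
    None when the measurement could not support them).
    """

    def __init__(
        self,
        model: DyePerformanceModel,
        traces: list[SiteTrace],
        tau_b: float,
        tau_b_sd: float,
        tau_d: float,
        tau_d_sd: float,
        photons_per_100ms: float,
        n_center_frames: int,
        sbr: float,
        n_sbr: int,
        nena: NeNAResult | None,
        stability: StabilityResult | None,
        destruction: DestructionResult | None,
    ) -> None:
        self.model = model
        self.traces = traces
        self.tau_b = tau_b
        self.tau_b_sd = tau_b_sd
        self.tau_d = tau_d
        self.tau_d_sd = tau_d_sd
        self.photons_per_100ms = photons_per_100ms
        self.n_center_frames = n_center_frames
        self.sbr = sbr
        self.n_sbr = n_sbr
        self.nena = nena
        self.stability = stability
        self.destruction = destruction

    @property
    def n_sites(self) -> int:
        return len(self.traces)

    @property
    def n_sites_used(self) -> int:
        return sum(not t.excluded for t in self.traces)

    @property
    def sigma_nena_nm(self) -> float:
        return self.nena.sigma_nm if self.nena is not None else np.nan

    @property
    def loc_drop_pct(self) -> float:
        return self.stability.drop_pct if self.stability is not None else np.nan

    @property
    def destroyed_pct(self) -> float:
        return self.destruction.destroyed_pct if self.destruction is not None else np.nan

    def to_frame(self) -> pd.DataFrame:
        """One-row DataFrame with the six benchmark metrics."""
        return pd.DataFrame(
            [
                {
                    "sigma_nena_nm": self.sigma_nena_nm,
                    "photons_per_100ms": self.photons_per_100ms,
                    "tau_b_s": self.tau_b,
                    "sbr": self.sbr,
                    "loc_drop_pct": self.loc_drop_pct,
                    "destroyed_pct": self.destroyed_pct,
                }
            ]
        )

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "DNA-PAINT dye performance",
            "=" * 46,
            f"{'Sites (used/total)':32s} {self.n_sites_used}/{self.n_sites}",
            f"{'Localizations':32s} {len(self.model.table)}",
            f"{'Precision sigma_NeNA (nm)':32s} {self.sigma_nena_nm:.2f}",
            f"{'Photons per 100 ms':32s} {self.photons_per_100ms:,.0f}  (n={self.n_center_frames})",
            f"{'Mean bright time (s)':32s} {self.tau_b:.3f} +/- {self.tau_b_sd:.3f} (site sd)",
            f"{'Mean dark time (s)':32s} {self.tau_d:.3f} +/- {self.tau_d_sd:.3f} (site sd)",
            f"{'SBR':32s} {self.sbr:.2f}  (n={self.n_sbr})",
            f"{'Localization drop (%)':32s} {self.loc_drop_pct:.1f}",
            f"{'Destroyed docking sites (%)':32s} {self.destroyed_pct:.2f}",
        ]
        if self.destruction is not None:
            lines.append(
                f"{'r-histogram fitted mu':32s} {self.destruction.mu:.3f} "
                f"(n={self.destruction.n_sites} sites)"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<DyePerformanceResults: {self.n_sites_used}/{self.n_sites} sites, "
            f"tau_b={self.tau_b:.3g}s, photons/100ms={self.photons_per_100ms:.4g}>"
        )
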