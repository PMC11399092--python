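"""Docking-site and structure identification, and region-based specificity.

Single docking sites are found by a density-based clusterer (DBSCAN-style
core/neighbor scheme with the two benchmark parameters: minimum 15
localizations within a 0.04-pixel radius).  Crosshair origami — one
dye-of-interest docking site plus four barcode sites — are accepted only when
a picked region contains exactly five clusters, i.e. the structure folded
completely and no site is missing or spurious.

For cellular data, specificity is quantified as a density ratio over
identical regions: (signal localizations per area / background localizations
per area) for the dye round divided by the same quantity for the reference
round, cancelling imager concentration and sample-dependent sticking common
to both rounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InsufficientDataError, ParameterError
from .locio import LocalizationTable, RegionSet, assign_to_regions


@dataclass
class Cluster:
    """A density-connected group of localizations."""

    members: np.ndarray  # indices into the input coordinate arrays
    centroid: tuple[float, float]

    @property
    def n_locs(self) -> int:
        return len(self.members)


def cluster_smlm(x, y, radius: float = 0.04, min_locs: int = 15) -> list[Cluster]:
    """Density-based clustering of localizations.

    A localization is a *core* point when at least ``min_locs`` localizations
    (itself included) lie within ``radius``.  Clusters are the connected
    components of core points (cores within ``radius`` of each other), plus
    every non-core localization within ``radius`` of a core ("border"
    points).  The result is independent of input order: points are processed
    in a canonical (x, y) sort, cluster ids follow the first core in that
    order, and a border point reachable from several clusters joins the one
    with the smallest id.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if min_locs < 1:
        raise ParameterError("min_locs must be at least 1")
    pts = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    n = len(pts)
    if n == 0:
        return []
    canonical = np.lexsort((pts[:, 1], pts[:, 0]))
    pts_c = pts[canonical]
    tree = cKDTree(pts_c)
    neighbors = tree.query_ball_tree(tree, r=radius)
    core = np.array([len(nb) >= min_locs for nb in neighbors])

    labels = np.full(n, -1, dtype=int)
    next_id = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # BFS over the core graph
        labels[i] = next_id
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core[k] and labels[k] == -1:
                    labels[k] = next_id
                    stack.append(k)
        next_id += 1

    # border points: smallest cluster id among in-radius cores
    for i in range(n):
        if core[i] or not neighbors[i]:
            continue
        ids = [labels[k] for k in neighbors[i] if core[k]]
        if ids:
            labels[i] = min(ids)

    clusters = []
    for cid in range(next_id):
        members_c = np.flatnonzero(labels == cid)
        members = canonical[members_c]
        cx, cy = pts[members].mean(axis=0)
        clusters.append(Cluster(members=np.sort(members), centroid=(float(cx), float(cy))))
    return clusters


def find_crosshairs(
    pick_clusters: list[list[Cluster]],
    pick_centers,
    target_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Select complete crosshair structures and locate their target docking site.

    A pick is accepted iff it contains exactly five clusters (a correctly
    folded, complete crosshair); incomplete (destroyed site) or contaminated
    (spurious sticking cluster) structures are rejected.  Per accepted pick
    the returned position is the centroid of the cluster closest to
    ``pick center + target_offset`` (the layout's dye-of-interest site; the
    center cluster by default).

    Returns ``(positions, accepted_indices, n_rejected)``.
    """
    pick_centers = np.atleast_2d(np.asarray(pick_centers, dtype=float))
    if len(pick_clusters) != len(pick_centers):
        raise ParameterError("one center per pick required")
    positions, accepted = [], []
    for i, clusters in enumerate(pick_clusters):
        if len(clusters) != 5:
            continue
        target = pick_centers[i] + np.asarray(target_offset, dtype=float)
        cents = np.array([c.centroid for c in clusters])
        j = int(np.argmin(np.hypot(cents[:, 0] - target[0], cents[:, 1] - target[1])))
        positions.append(cents[j])
        accepted.append(i)
    n_rejected = len(pick_clusters) - len(accepted)
    pos = np.array(positions) if positions else np.empty((0, 2))
    return pos, np.array(accepted, dtype=int), n_rejected


@dataclass
class SpecificityResult:
    """Signal/background density ratios for an imaging and a reference round."""

    s_imaging: float  # signal density / background density, imaging round
    s_reference: float  # same, reference round
    r_dye: float  # s_imaging / s_reference
    signal_area_um2: float
    background_area_um2: float
    counts: dict


def _density_ratio(table: LocalizationTable, signal: RegionSet, background: RegionSet):
    sig = assign_to_regions(table, signal)
    bgd = assign_to_regions(table, background)
    n_sig = sum(a.count for a in sig)
    n_bg = sum(a.count for a in bgd)
    area_sig = sum(a.area_um2 for a in sig)
    area_bg = sum(a.area_um2 for a in bgd)
    if n_bg == 0:
        raise InsufficientDataError(
            "no localizations in the background regions; enlarge or add regions"
        )
    return (n_sig / area_sig) / (n_bg / area_bg), n_sig, n_bg, area_sig, area_bg


def relative_specificity(
    imaging_table: LocalizationTable,
    reference_table: LocalizationTable,
    signal_regions: RegionSet,
    background_regions: RegionSet,
) -> SpecificityResult:
    """Unitless relative specificity of a dye against a reference round.

    The identical signal and background regions are applied to both tables;
    each round's specificity is its signal density over background density,
    and the ratio of the two removes imager-concentration and
    sample-heterogeneity bias shared by the rounds.
    """
    s_img, n_si, n_bi, a_s, a_b = _density_ratio(imaging_table, signal_regions, background_regions)
    s_ref, n_sr, n_br, _, _ = _density_ratio(reference_table, signal_regions, background_regions)
    return SpecificityResult(
        s_imaging=s_img,
        s_reference=s_ref,
        r_dye=s_img / s_ref,
        signal_area_um2=a_s,
        background_area_um2=a_b,
        counts={
            "imaging_signal": n_si,
            "imaging_background": n_bi,
            "reference_signal": n_sr,
            "reference_background": n_br,
        },
    )


def mask_specificity(
    imaging_table: LocalizationTable,
    reference_table: LocalizationTable,
    mask: np.ndarray,
) -> SpecificityResult:
    """Mask-based relative specificity: inside-mask = signal, outside = background."""
    inside = RegionSet.from_mask(mask, inside_role="signal", outside_role=None)
    outside = RegionSet.from_mask(
        np.where(np.asarray(mask) != 0, 0, 1), inside_role="background", outside_role=None
    )
    return relative_specificity(imaging_table, reference_table, inside, outside)
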