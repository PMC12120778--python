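"""Synaptic-property statistics and synapse-mitochondrion distances.

Positions: presynaptic sites sit at active-zone centroids; postsynaptic
sites inherit the same active-zone centroid, one site per (zone, partner)
pair, measured against the *partner* cell's mitochondria. All distances
are Euclidean between centroids in physical nm.

The randomization null follows the reconstruction literature's recipe:
instead of the nearest mitochondrion, each site is assigned one uniformly
random mitochondrion from its own cell; 1000 such configurations yield a
mean distance histogram with a percentile-based 95% band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core import (
    ActiveZone,
    DistanceRecord,
    MitoToSynapseRecord,
    NullDistribution,
    SynapticSite,
)

DEFAULT_BIN_WIDTH_NM = 100.0  # 0.1 um


# ---------------------------------------------------------------------------
# degrees / fan-out
# ---------------------------------------------------------------------------

def degrees(zones: Iterable[ActiveZone]) -> tuple[dict[int, int], dict[int, int]]:
    """Per-cell out- and in-degree.

    Out-degree of a cell sums the fan-outs of its active zones (a zone with
    3 postsynaptic partners contributes 3); in-degree counts (zone,
    partner) incidences received. Cells with a zero degree are simply
    absent from the corresponding mapping, matching the convention that
    cells with 0 out- or in-degree are neglected from those analyses.
    """
    out_deg: dict[int, int] = {}
    in_deg: dict[int, int] = {}
    for z in zones:
        out_deg[z.presyn_cell_id] = out_deg.get(z.presyn_cell_id, 0) + z.fanout
        for p in z.partners:
            in_deg[p] = in_deg.get(p, 0) + 1
    return out_deg, in_deg


def fanout(zone: ActiveZone) -> int:
    """Number of postsynaptic partners of one active zone."""
    return zone.fanout


# ---------------------------------------------------------------------------
# sites and distances
# ---------------------------------------------------------------------------

def build_sites(zones: Sequence[ActiveZone]) -> list[SynapticSite]:
    """One pre site per zone plus one post site per (zone, partner)."""
    sites = []
    sid = 0
    for z in zones:
        sites.append(SynapticSite(site_id=sid, kind="pre", zone_id=z.zone_id,
                                  cell_id=z.presyn_cell_id, position=z.centroid))
        sid += 1
        for p in z.partners:
            sites.append(SynapticSite(site_id=sid, kind="post", zone_id=z.zone_id,
                                      cell_id=p, position=z.centroid))
            sid += 1
    return sites


MitosByCell = Mapping[int, Sequence[tuple[int, tuple[float, float, float]]]]


def nearest_mito_distances(
    sites: Sequence[SynapticSite], mitos_by_cell: MitosByCell,
) -> tuple[list[DistanceRecord], list[tuple[SynapticSite, str]]]:
    """Distance from each site to its cell's nearest mitochondrion centroid.

    Sites whose cell holds no mitochondria are excluded with a reason code
    rather than silently dropped.
    """
    records, excluded = [], []
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cell_id, entries in mitos_by_cell.items():
        if entries:
            ids = np.array([e[0] for e in entries])
            pos = np.array([e[1] for e in entries], dtype=float)
            cache[cell_id] = (ids, pos)
    for s in sites:
        got = cache.get(s.cell_id)
        if got is None:
            excluded.append((s, "no_mitochondria_in_cell"))
            continue
        ids, pos = got
        d = np.linalg.norm(pos - np.asarray(s.position), axis=1)
        k = int(np.argmin(d))
        records.append(DistanceRecord(
            site_id=s.site_id, kind=s.kind, zone_id=s.zone_id, cell_id=s.cell_id,
            nearest_mito_id=int(ids[k]), distance=float(d[k])))
    return records, excluded


def mito_to_synapse_distances(
    sites: Sequence[SynapticSite], mitos_by_cell: MitosByCell,
) -> list[MitoToSynapseRecord]:
    """Per-mitochondrion distance to the nearest pre and post site of its cell."""
    pre_pos: dict[int, list] = {}
    post_pos: dict[int, list] = {}
    for s in sites:
        (pre_pos if s.kind == "pre" else post_pos).setdefault(
            s.cell_id, []).append(s.position)
    out = []
    for cell_id, entries in mitos_by_cell.items():
        pre = np.array(pre_pos.get(cell_id, []), dtype=float).reshape(-1, 3)
        post = np.array(post_pos.get(cell_id, []), dtype=float).reshape(-1, 3)
        for mito_id, centroid in entries:
            c = np.asarray(centroid, dtype=float)
            d_pre = float(np.linalg.norm(pre - c, axis=1).min()) if len(pre) else float("nan")
            d_post = float(np.linalg.norm(post - c, axis=1).min()) if len(post) else float("nan")
            out.append(MitoToSynapseRecord(mito_id=mito_id, cell_id=cell_id,
                                           d_syn_pre=d_pre, d_syn_post=d_post))
    return out


# ---------------------------------------------------------------------------
# randomization null
# ---------------------------------------------------------------------------

def randomization_null(
    sites: Sequence[SynapticSite], mitos_by_cell: MitosByCell,
    n_config: int = 1000, seed: int = 0,
    bin_width_nm: float = DEFAULT_BIN_WIDTH_NM,
    bin_edges: np.ndarray | None = None,
) -> NullDistribution:
    """Null distance distribution under random within-cell assignment.

    Per configuration, every site (whose cell has mitochondria) is paired
    with one uniformly drawn mitochondrion of its own cell. The summary is
    a density histogram (area 1): mean across configurations with the
    2.5-97.5 percentile band.
    """
    rng = np.random.default_rng(seed)
    usable = []
    dmats = []
    for s in sites:
        entries = mitos_by_cell.get(s.cell_id)
        if not entries:
            continue
        pos = np.array([e[1] for e in entries], dtype=float)
        usable.append(s)
        dmats.append(np.linalg.norm(pos - np.asarray(s.position), axis=1))
    n_sites = len(usable)
    if n_sites == 0:
        raise ValueError("no site has mitochondria in its cell")
    samples = np.empty((n_config, n_sites))
    for j, dvec in enumerate(dmats):
        draws = rng.integers(len(dvec), size=n_config)
        samples[:, j] = dvec[draws]
    if bin_edges is None:
        top = float(np.ceil(samples.max() / bin_width_nm)) * bin_width_nm
        bin_edges = np.arange(0.0, top + bin_width_nm, bin_width_nm)
    dens = np.empty((n_config, len(bin_edges) - 1))
    for c in range(n_config):
        dens[c], _ = np.histogram(samples[c], bins=bin_edges, density=True)
    return NullDistribution(
        samples=samples,
        site_ids=np.array([s.site_id for s in usable]),
        bin_edges=np.asarray(bin_edges, dtype=float),
        mean_density=dens.mean(axis=0),
        lo95=np.percentile(dens, 2.5, axis=0),
        hi95=np.percentile(dens, 97.5, axis=0),
        seed=seed)


def band_coverage(distances_nm: Sequence[float], null: NullDistribution) -> float:
    """Fraction of histogram bins where the distances' density lies inside
    the null's 95% band (only bins where either side is nonzero count)."""
    dens, _ = np.histogram(np.asarray(distances_nm, dtype=float),
                           bins=null.bin_edges, density=True)
    active = (dens > 0) | (null.mean_density > 0)
    inside = (dens >= null.lo95) & (dens <= null.hi95)
    if not active.any():
        return 1.0
    return float(inside[active].mean())


# ---------------------------------------------------------------------------
# saturation threshold / near-far partition
# ---------------------------------------------------------------------------

def saturation_threshold(
    distances_nm: Sequence[float], bin_width_nm: float = DEFAULT_BIN_WIDTH_NM,
) -> tuple[float, bool]:
    """Distance where the cumulative distance distribution saturates.

    Distances are histogrammed in fixed-width bins from 0; the threshold is
    the upper edge of the first bin at which the cumulative fraction
    reaches >= 95% - i.e. where the remaining tail drops below the 5%
    saturation criterion. Returns (threshold_nm, degenerate) where
    ``degenerate`` flags saturation already inside the first bin (the
    threshold then equals one bin width).
    """
    d = np.asarray(list(distances_nm), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one distance")
    n_bins = int(np.ceil((d.max() + 1e-9) / bin_width_nm))
    n_bins = max(n_bins, 1)
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width_nm))
    cum = np.cumsum(counts) / d.size
    idx = int(np.argmax(cum >= 0.95 - 1e-12))
    threshold = float(edges[idx + 1])
    return threshold, idx == 0


@dataclass
class NearFarGroups:
    """Values associated with near (distance <= threshold, tie-inclusive)
    and far records; ``skipped_reason`` set when a group is empty."""

    near: list[float]
    far: list[float]
    skipped_reason: str | None = None

    @property
    def comparison_possible(self) -> bool:
        return self.skipped_reason is None


def near_far_partition(
    records: Sequence, threshold_nm: float,
    value: Callable[[object], float],
    distance: Callable[[object], float] = lambda r: r.distance,
) -> NearFarGroups:
    """Split records at the threshold and emit the associated size values.

    ``value`` extracts the quantity compared downstream (active-zone size
    for the site-side analysis, mitochondrion volume for the mito-side
    analysis).
    """
    if threshold_nm <= 0:
        raise ValueError("threshold must be > 0")
    near = [float(value(r)) for r in records if distance(r) <= threshold_nm]
    far = [float(value(r)) for r in records if distance(r) > threshold_nm]
    reason = None
    if not near:
        reason = "near_group_empty"
    elif not far:
        reason = "far_group_empty"
    return NearFarGroups(near=near, far=far, skipped_reason=reason)
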