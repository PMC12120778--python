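"""Core domain types shared across the pipeline.

Conventions
-----------
* Label arrays are stored in ``zyx`` order (section axis first); label 0 is
  background.
* ``resolution`` is nm per axis in ``(x, y, z)`` order, matching how EM
  volumes advertise their voxel size.
* Physical positions are voxel-center positions: ``index * resolution +
  offset`` in nm, reported in ``(x, y, z)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CELL_CLASSES = ("sensory", "inter", "motor", "muscle", "other")
NEUROTRANSMITTERS = ("ACh", "Glu", "GABA", "DA", "OA", "unknown")


class ValidationError(ValueError):
    """Malformed input that a reader/constructor refuses to repair."""


class CapacityError(RuntimeError):
    """Synthetic placement failed after bounded retries (overcrowded spec)."""


@dataclass
class VoxelGrid:
    """Labeled 3D volume with anisotropic physical resolution.

    ``labels`` is a non-negative integer array in zyx order. ``resolution``
    and ``offset`` are nm in (x, y, z) order.
    """

    labels: np.ndarray
    resolution: tuple[float, float, float]
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D array (zyx)")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValidationError("labels must be an integer array")
        self.resolution = tuple(float(r) for r in self.resolution)
        if len(self.resolution) != 3 or any(r <= 0 for r in self.resolution):
            raise ValidationError("resolution must be 3 positive nm values (x, y, z)")
        self.offset = tuple(float(o) for o in self.offset)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in nm^3."""
        rx, ry, rz = self.resolution
        return rx * ry * rz

    @property
    def resolution_zyx(self) -> tuple[float, float, float]:
        rx, ry, rz = self.resolution
        return (rz, ry, rx)

    def positions_nm(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) nm positions of voxel indices given in zyx."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        rx, ry, rz = self.resolution
        ox, oy, oz = self.offset
        out = np.empty_like(idx)
        out[:, 0] = idx[:, 2] * rx + ox
        out[:, 1] = idx[:, 1] * ry + oy
        out[:, 2] = idx[:, 0] * rz + oz
        return out


@dataclass
class CellRecord:
    """One segmented cell with its classification metadata."""

    cell_id: int
    name: str
    cell_class: str
    neurotransmitter: str
    cell_volume: float  # nm^3

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValidationError("cell_id must be a positive label")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"unknown cell_class {self.cell_class!r}")
        if self.neurotransmitter not in NEUROTRANSMITTERS:
            raise ValidationError(f"unknown neurotransmitter {self.neurotransmitter!r}")
        if self.cell_volume <= 0:
            raise ValidationError("cell_volume must be > 0")


@dataclass
class ActiveZone:
    """A presynaptic active zone with its ordered postsynaptic partners.

    ``size`` is the physical active-zone size (voxel_count x voxel volume,
    nm^3); the paper uses it interchangeably with "synapse size".
    """

    zone_id: int
    presyn_cell_id: int
    voxel_count: int
    size: float  # nm^3
    centroid: tuple[float, float, float]  # nm, (x, y, z)
    partners: tuple[int, ...]

    def __post_init__(self) -> None:
        self.partners = tuple(int(p) for p in self.partners)
        if len(self.partners) < 1:
            raise ValidationError(
                f"zone {self.zone_id}: polyadic synapse needs >= 1 partner"
            )
        self.centroid = tuple(float(c) for c in self.centroid)

    @property
    def fanout(self) -> int:
        return len(self.partners)


@dataclass
class Skeleton:
    """A forest of centerline trees: nodes in nm with local radius, edges."""

    positions: np.ndarray  # (n, 3) nm, (x, y, z)
    radii: np.ndarray  # (n,) nm
    edges: np.ndarray  # (m, 2) int node indices
    roots: tuple[int, ...]
    length: float = 0.0  # total physical length, nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.any(self.radii < 0):
            raise ValidationError("skeleton node radius must be >= 0")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass
class MitochondrionRecord:
    """One reconstructed mitochondrion instance with its morphometrics."""

    mito_id: int
    cell_id: int
    voxel_count: int
    volume: float  # nm^3
    surface_area: float  # nm^2
    centroid: tuple[float, float, float]  # nm (x, y, z)
    length: float = 0.0  # nm, skeleton length
    mci: float = float("nan")
    skeleton_id: int = -1
    assignment_fraction: float = 1.0
    ambiguous: bool = False


@dataclass
class SynapticSite:
    """A pre- or postsynaptic site, positioned at its active-zone centroid.

    ``kind`` is ``"pre"`` (one per zone, cell = presynaptic cell) or
    ``"post"`` (one per (zone, partner), cell = partner cell).
    """

    site_id: int
    kind: str
    zone_id: int
    cell_id: int
    position: tuple[float, float, float]  # nm (x, y, z)

    def __post_init__(self) -> None:
        if self.kind not in ("pre", "post"):
            raise ValidationError("site kind must be 'pre' or 'post'")


@dataclass
class DistanceRecord:
    """Nearest-mitochondrion distance for one synaptic site."""

    site_id: int
    kind: str
    zone_id: int
    cell_id: int
    nearest_mito_id: int
    distance: float  # nm


@dataclass
class MitoToSynapseRecord:
    """Per-mitochondrion distances to the nearest pre/post site of its cell."""

    mito_id: int
    cell_id: int
    d_syn_pre: float  # nm; NaN if the cell has no pre sites
    d_syn_post: float  # nm; NaN if the cell has no post sites


@dataclass
class NullDistribution:
    """Randomization null for site-to-mitochondrion distances.

    Each of ``n_config`` configurations assigns every site one uniformly
    drawn mitochondrion from the site's own cell. ``samples[c, s]`` is the
    distance for site ``s`` in configuration ``c``. The histogram summary
    (density, area 1) carries the across-configuration mean and the
    percentile-based 95% band.
    """

    samples: np.ndarray  # (n_config, n_sites) nm
    site_ids: np.ndarray
    bin_edges: np.ndarray  # nm
    mean_density: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    seed: int

    @property
    def n_config(self) -> int:
        return self.samples.shape[0]


@dataclass
class CellMitoSummary:
    """Per-cell mitochondria summary (cells with zero mitochondria are
    excluded upstream, never summarized)."""

    cell_id: int
    n_mito: int
    total_volume: float
    mean_volume: float
    total_surface_area: float
    mean_surface_area: float
    total_length: float
    mean_length: float
    volume_fraction: float
    sav: float
    mean_mci: float
    pooled_mci: float
    branch_count_mean: float = float("nan")


@dataclass
class TestResult:
    """Statistical test outcome with the paper's display convention."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")

    @property
    def p_display(self) -> str:
        """Format p; values below 1e-20 are reported as 'P ~ 0'."""
        if self.p_value < 1e-20:
            return "~0"
        return f"{self.p_value:.3g}"
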