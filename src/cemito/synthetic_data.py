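"""Ground-truthed synthetic worlds for end-to-end pipeline testing.

The generator emulates the structural statistics the downstream analyses
assume, without claiming anatomical realism:

* Neurites are straight tubes running along the sectioning (z) axis,
  arranged on a lattice with guaranteed inter-tube gaps. Neurite
  mitochondria are capsules (cylinder + hemispherical caps) centered on
  the tube centerline, so true volume, surface area and tip-to-tip length
  are analytically known.
* Active zones are polyadic: each has 1-5 ordered postsynaptic partners
  drawn from neighboring tubes, and a physical size log-linear in fan-out.
* Placement coupling: a fraction ``coupling_kappa`` of a cell's
  mitochondria are centered within a window of a uniformly chosen synaptic
  site of that cell (path distance along the centerline); postsynaptic
  windows are ``pre_post_asymmetry`` times wider, reproducing the
  pre-closer-than-post ordering.
* Body-wall-muscle stand-ins are axis-aligned slabs containing one
  reticular mitochondrion: a spine strand along z plus comb branches,
  yielding multi-strand cross-sections for branch counting.
* 2D training pairs: textured background, darker striped ellipses, exact
  ellipse masks - enough signal for the mitochondria detector, no EM
  texture realism.

All randomness derives from one spec seed through ``numpy`` seed
sequences, so a world is a pure function of its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    ActiveZone,
    CapacityError,
    CellRecord,
    ValidationError,
    VoxelGrid,
)

# Fan-out pmf over 1..5 follows the adult per-fan-out site counts
# (514, 2303, 698, 125, 35), normalized.
DEFAULT_FANOUT_PMF = (0.14, 0.627, 0.19, 0.034, 0.009)


@dataclass(frozen=True)
class CountLaw:
    """Per-cell mitochondrion count distribution.

    kinds: ``constant`` (value), ``poisson`` (mean, min 1), and
    ``degree_coupled`` - counts targeting a Pearson correlation
    ``target_r`` with the cell's out-degree, with marginal mean/sd.
    """

    kind: str = "degree_coupled"
    value: int = 3
    mean: float = 8.0
    sd: float = 3.0
    target_r: float = 0.6


@dataclass(frozen=True)
class LengthLaw:
    """Capsule tip-to-tip length distribution: clipped lognormal, nm."""

    median_nm: float = 800.0
    sigma: float = 0.35
    min_nm: float = 400.0
    max_nm: float = 2400.0


@dataclass(frozen=True)
class SyntheticSpec:
    grid_shape: tuple[int, int, int] | None = None  # zyx voxels; None = auto
    resolution: tuple[float, float, float] = (16.0, 16.0, 32.0)  # nm (x,y,z)
    n_neurites: int = 25
    neurite_radius: float = 160.0  # nm
    mito_radius: float = 80.0  # nm
    n_muscles: int = 4
    tube_length_voxels: int = 800
    zones_per_neurite_mean: float = 12.0
    mito_count_law: CountLaw = field(default_factory=CountLaw)
    mito_length_law: LengthLaw = field(default_factory=LengthLaw)
    coupling_kappa: float = 0.6
    coupling_radius: float = 500.0  # nm, along-centerline window
    pre_post_asymmetry: float = 2.0
    fanout_pmf: tuple[float, ...] = DEFAULT_FANOUT_PMF
    size_fanout_slope: float = 0.5  # d log(zone voxels) / d fanout
    zone_size_base_voxels: float = 30.0
    zone_size_noise: float = 0.4
    muscle_branch_mean: float = 6.0
    pair_noise_scale: float = 0.05
    pair_density_band: tuple[float, float] = (0.03, 0.18)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.coupling_kappa <= 1.0):
            raise ValidationError("coupling_kappa must lie in [0, 1]")
        for name in ("neurite_radius", "mito_radius", "coupling_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.mito_radius >= self.neurite_radius:
            raise ValidationError("mito_radius must be smaller than neurite_radius")
        if self.pre_post_asymmetry < 1.0:
            raise ValidationError("pre_post_asymmetry must be >= 1")
        if abs(sum(self.fanout_pmf) - 1.0) > 1e-9 or len(self.fanout_pmf) != 5:
            raise ValidationError("fanout_pmf must be 5 probabilities summing to 1")
        if self.mito_length_law.min_nm <= 2 * self.mito_radius:
            raise ValidationError("capsule length must exceed its diameter")


@dataclass
class TrueMito:
    """Generator bookkeeping for one mitochondrion instance."""

    mito_id: int
    cell_id: int
    length_nm: float
    centroid: tuple[float, float, float]  # nm (x, y, z), voxel-mean
    nearest_zone_nm: float  # NaN when the cell has no synaptic sites
    coupled: bool


@dataclass
class SyntheticTruth:
    cell_labels: VoxelGrid
    mito_labels: VoxelGrid
    active_zones: list[ActiveZone]
    cells: list[CellRecord]
    mitochondria: list[TrueMito]
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# rasterization primitives
# ---------------------------------------------------------------------------

def rasterize_capsule(labels: np.ndarray, resolution: tuple[float, float, float],
                      p0_nm: np.ndarray, p1_nm: np.ndarray, radius_nm: float,
                      value: int) -> int:
    """Paint a capsule (all points within ``radius_nm`` of segment p0-p1)
    into ``labels`` by exact point-in-capsule tests at voxel centers.

    Points are (x, y, z) nm; returns the number of voxels painted.
    """
    rx, ry, rz = resolution
    res = np.array([rx, ry, rz])
    lo = np.minimum(p0_nm, p1_nm) - radius_nm
    hi = np.maximum(p0_nm, p1_nm) + radius_nm
    nz, ny, nx = labels.shape
    ix0 = max(0, int(math.floor(lo[0] / rx)))
    iy0 = max(0, int(math.floor(lo[1] / ry)))
    iz0 = max(0, int(math.floor(lo[2] / rz)))
    ix1 = min(nx - 1, int(math.ceil(hi[0] / rx)))
    iy1 = min(ny - 1, int(math.ceil(hi[1] / ry)))
    iz1 = min(nz - 1, int(math.ceil(hi[2] / rz)))
    if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
        return 0
    zz, yy, xx = np.meshgrid(np.arange(iz0, iz1 + 1) * rz,
                             np.arange(iy0, iy1 + 1) * ry,
                             np.arange(ix0, ix1 + 1) * rx, indexing="ij")
    d = p1_nm - p0_nm
    seg_len2 = float(d @ d)
    px, py, pz = xx - p0_nm[0], yy - p0_nm[1], zz - p0_nm[2]
    if seg_len2 == 0.0:
        t = np.zeros_like(px)
    else:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / seg_len2, 0.0, 1.0)
    ddx, ddy, ddz = px - t * d[0], py - t * d[1], pz - t * d[2]
    inside = ddx * ddx + ddy * ddy + ddz * ddz <= radius_nm * radius_nm
    view = labels[iz0:iz1 + 1, iy0:iy1 + 1, ix0:ix1 + 1]
    view[inside] = value
    return int(np.count_nonzero(inside))


def make_capsule_mask(length_nm: float, radius_nm: float,
                      resolution: tuple[float, float, float],
                      pad_voxels: int = 3) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Standalone axis-aligned (z) capsule mask with padding.

    Returns (mask zyx, center nm). Used as an analytically known fixture:
    true tip-to-tip length ``length_nm``, volume pi r^2 (L-2r) + 4/3 pi r^3.
    """
    rx, ry, rz = resolution
    nz = int(math.ceil(length_nm / rz)) + 2 * pad_voxels
    nxy = int(math.ceil(2 * radius_nm / min(rx, ry))) + 2 * pad_voxels
    labels = np.zeros((nz, nxy, nxy), dtype=np.uint8)
    cx, cy = (nxy // 2) * rx, (nxy // 2) * ry
    cz = (nz // 2) * rz
    h = length_nm / 2.0 - radius_nm
    p0 = np.array([cx, cy, cz - h])
    p1 = np.array([cx, cy, cz + h])
    rasterize_capsule(labels, resolution, p0, p1, radius_nm, 1)
    return labels.astype(bool), (cx, cy, cz)


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def _layout(spec: SyntheticSpec):
    """Lattice layout of neurite axes and muscle slabs, in voxel units."""
    rx, ry, rz = spec.resolution
    r_vox_x = spec.neurite_radius / rx
    r_vox_y = spec.neurite_radius / ry
    gap = 4  # voxels between tube surfaces: instances can never touch across
    pitch_x = int(math.ceil(2 * r_vox_x)) + gap
    pitch_y = int(math.ceil(2 * r_vox_y)) + gap
    n_cols = int(math.ceil(math.sqrt(spec.n_neurites)))
    n_rows = int(math.ceil(spec.n_neurites / n_cols))
    margin = gap
    centers = []
    for i in range(spec.n_neurites):
        row, col = divmod(i, n_cols)
        centers.append((margin + pitch_x // 2 + col * pitch_x,
                        margin + pitch_y // 2 + row * pitch_y))  # (x_vox, y_vox)
    nx = margin * 2 + n_cols * pitch_x
    ny_neur = margin * 2 + n_rows * pitch_y
    slab_thickness = 14  # voxels in y
    slab_gap = 4
    ny = ny_neur + spec.n_muscles * (slab_thickness + slab_gap)
    slabs = []
    for m in range(spec.n_muscles):
        y0 = ny_neur + slab_gap + m * (slab_thickness + slab_gap)
        slabs.append((y0, y0 + slab_thickness))
    nz = spec.tube_length_voxels
    shape = (nz, ny, nx)
    if spec.grid_shape is not None:
        if any(g < s for g, s in zip(spec.grid_shape, shape)):
            raise ValidationError(
                f"grid_shape {spec.grid_shape} too small for layout {shape}")
        shape = tuple(spec.grid_shape)
    return shape, centers, slabs


def _sample_fanout(rng: np.random.Generator, pmf) -> int:
    return int(rng.choice(5, p=np.asarray(pmf) / np.sum(pmf))) + 1


def generate_world(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate a fully labeled world; deterministic given ``spec.seed``."""
    spec.validate()
    rx, ry, rz = spec.resolution
    voxvol = rx * ry * rz
    shape, centers, slabs = _layout(spec)
    nz, ny, nx = shape

    ss = np.random.SeedSequence(spec.seed)
    rng_zone, rng_count, rng_place, rng_muscle, rng_meta = (
        np.random.default_rng(s) for s in ss.spawn(5))

    cell_labels = np.zeros(shape, dtype=np.uint32)
    mito_labels = np.zeros(shape, dtype=np.uint32)

    # --- neurite tubes -----------------------------------------------------
    yy, xx = np.meshgrid(np.arange(ny) * ry, np.arange(nx) * rx, indexing="ij")
    z_margin_vox = 4
    for i, (cx_vox, cy_vox) in enumerate(centers):
        cxn, cyn = cx_vox * rx, cy_vox * ry
        disc = (xx - cxn) ** 2 + (yy - cyn) ** 2 <= spec.neurite_radius**2
        cell_labels[z_margin_vox:nz - z_margin_vox, disc] = i + 1

    # --- muscle slabs ------------------------------------------------------
    muscle_ids = []
    for m, (y0, y1) in enumerate(slabs):
        cid = spec.n_neurites + m + 1
        cell_labels[z_margin_vox:nz - z_margin_vox, y0:y1, 2:nx - 2] = cid
        muscle_ids.append(cid)

    # --- active zones ------------------------------------------------------
    z_lo_nm = (z_margin_vox + 2) * rz + 1000.0
    z_hi_nm = (nz - z_margin_vox - 2) * rz - 1000.0
    neighbor_order = []
    cxy = np.array([(c[0] * rx, c[1] * ry) for c in centers])
    for i in range(spec.n_neurites):
        d = np.linalg.norm(cxy - cxy[i], axis=1)
        neighbor_order.append(np.argsort(d)[1:7])  # six nearest tubes
    zones: list[ActiveZone] = []
    zone_id = 0
    mean_fanout = sum((k + 1) * p for k, p in enumerate(spec.fanout_pmf))
    for i in range(spec.n_neurites):
        n_zones = max(1, int(rng_zone.poisson(spec.zones_per_neurite_mean)))
        z_positions = np.sort(rng_zone.uniform(z_lo_nm, z_hi_nm, size=n_zones))
        for zpos in z_positions:
            fo = _sample_fanout(rng_zone, spec.fanout_pmf)
            nbrs = neighbor_order[i]
            if len(nbrs) == 0:
                # single-neurite world: autapse-like self-partnered zone
                partners = (i + 1,)
                direction = np.array([1.0, 0.0])
            else:
                fo = min(fo, len(nbrs))
                partners = tuple(int(p) + 1 for p in
                                 rng_zone.choice(nbrs, size=fo, replace=False))
                # centroid on the tube surface, leaning toward the first partner
                direction = cxy[partners[0] - 1] - cxy[i]
                direction = direction / (np.linalg.norm(direction) + 1e-12)
            offset = spec.neurite_radius - 1.5 * max(rx, ry)
            cx_nm = cxy[i][0] + direction[0] * offset
            cy_nm = cxy[i][1] + direction[1] * offset
            log_vox = (math.log(spec.zone_size_base_voxels)
                       + spec.size_fanout_slope * (fo - mean_fanout)
                       + spec.zone_size_noise * rng_zone.standard_normal())
            voxel_count = max(4, int(round(math.exp(log_vox))))
            zone_id += 1
            zones.append(ActiveZone(
                zone_id=zone_id, presyn_cell_id=i + 1, voxel_count=voxel_count,
                size=voxel_count * voxvol,
                centroid=(float(cx_nm), float(cy_nm), float(zpos)),
                partners=partners))

    # synaptic sites per cell: (zone centroid, placement window)
    sites_by_cell: dict[int, list[tuple[np.ndarray, float]]] = {
        i + 1: [] for i in range(spec.n_neurites)}
    for z in zones:
        pos = np.asarray(z.centroid)
        sites_by_cell[z.presyn_cell_id].append((pos, spec.coupling_radius))
        for p in z.partners:
            sites_by_cell[p].append(
                (pos, spec.coupling_radius * spec.pre_post_asymmetry))

    # --- per-cell mitochondrion counts ------------------------------------
    law = spec.mito_count_law
    if law.kind == "constant":
        counts = np.full(spec.n_neurites, law.value, dtype=int)
    elif law.kind == "poisson":
        counts = np.maximum(1, rng_count.poisson(law.mean, size=spec.n_neurites))
    elif law.kind == "degree_coupled":
        out_degree = np.zeros(spec.n_neurites)
        for z in zones:
            out_degree[z.presyn_cell_id - 1] += z.fanout
        sd = out_degree.std()
        zscore = (out_degree - out_degree.mean()) / (sd if sd > 0 else 1.0)
        latent = (law.target_r * zscore
                  + math.sqrt(max(0.0, 1 - law.target_r**2))
                  * rng_count.standard_normal(spec.n_neurites))
        counts = np.maximum(1, np.round(law.mean + law.sd * latent).astype(int))
    else:
        raise ValidationError(f"unknown count law kind {law.kind!r}")

    # --- neurite mitochondria ---------------------------------------------
    mitos: list[TrueMito] = []
    law_len = spec.mito_length_law
    mito_id = 0
    gap_nm = 2.5 * rz  # >= 2 empty z voxels between capsules in one tube
    z_cap_lo = (z_margin_vox + 1) * rz
    z_cap_hi = (nz - z_margin_vox - 2) * rz
    for i in range(spec.n_neurites):
        cxn, cyn = cxy[i]
        placed: list[tuple[float, float]] = []  # (z_start, z_end) nm
        cell_sites = sites_by_cell[i + 1]
        for _ in range(int(counts[i])):
            ok = False
            for _attempt in range(200):
                length = float(np.clip(
                    rng_place.lognormal(math.log(law_len.median_nm), law_len.sigma),
                    law_len.min_nm, law_len.max_nm))
                lo, hi = z_cap_lo + length / 2, z_cap_hi - length / 2
                if lo >= hi:
                    continue
                coupled = bool(cell_sites) and rng_place.random() < spec.coupling_kappa
                if coupled:
                    site_pos, window = cell_sites[rng_place.integers(len(cell_sites))]
                    cz = site_pos[2] + rng_place.uniform(-window, window)
                    cz = float(np.clip(cz, lo, hi))
                else:
                    cz = float(rng_place.uniform(lo, hi))
                z0, z1 = cz - length / 2, cz + length / 2
                if all(z1 + gap_nm < a or z0 - gap_nm > b for a, b in placed):
                    ok = True
                    break
            if not ok:
                raise CapacityError(
                    f"could not place mitochondrion in neurite {i + 1}: "
                    "spec overcrowds the tube")
            placed.append((z0, z1))
            mito_id += 1
            h = length / 2 - spec.mito_radius
            p0 = np.array([cxn, cyn, cz - h])
            p1 = np.array([cxn, cyn, cz + h])
            nvox = rasterize_capsule(mito_labels, spec.resolution, p0, p1,
                                     spec.mito_radius, mito_id)
            if nvox == 0:
                raise CapacityError(f"capsule rasterized empty in neurite {i + 1}")
            mitos.append(TrueMito(
                mito_id=mito_id, cell_id=i + 1, length_nm=length,
                centroid=(float(cxn), float(cyn), cz),
                nearest_zone_nm=float("nan"), coupled=coupled))

    # --- muscle reticula ---------------------------------------------------
    strand_r = 60.0
    for m, (y0, y1) in enumerate(slabs):
        cid = muscle_ids[m]
        mito_id += 1
        y_mid = (y0 + y1) / 2 * ry
        x_lo_nm, x_hi_nm = (2 + 5) * rx, (nx - 2 - 5) * rx
        pad = min(500.0, 0.2 * (x_hi_nm - x_lo_nm))
        spine_x = float(rng_muscle.uniform(x_lo_nm + pad, x_hi_nm - pad))
        sp0 = np.array([spine_x, y_mid, z_cap_lo + strand_r])
        sp1 = np.array([spine_x, y_mid, z_cap_hi - strand_r])
        total_len = float(sp1[2] - sp0[2])
        rasterize_capsule(mito_labels, spec.resolution, sp0, sp1, strand_r, mito_id)
        n_branches = int(rng_muscle.poisson(spec.muscle_branch_mean))
        for _ in range(n_branches):
            # comb branch: a parallel strand at a lateral offset, attached by
            # a short rung so the reticulum stays one connected instance
            bx = float(np.clip(spine_x + rng_muscle.choice([-1, 1])
                               * rng_muscle.uniform(300, 1200), x_lo_nm, x_hi_nm))
            z_attach = float(rng_muscle.uniform(sp0[2] + 500, sp1[2] - 500))
            blen = float(rng_muscle.uniform(1500, 6000))
            b0 = np.array([bx, y_mid, max(z_cap_lo + strand_r, z_attach - blen / 2)])
            b1 = np.array([bx, y_mid, min(z_cap_hi - strand_r, z_attach + blen / 2)])
            rung0 = np.array([spine_x, y_mid, z_attach])
            rung1 = np.array([bx, y_mid, z_attach])
            rasterize_capsule(mito_labels, spec.resolution, rung0, rung1,
                              strand_r, mito_id)
            rasterize_capsule(mito_labels, spec.resolution, b0, b1, strand_r, mito_id)
            total_len += float(b1[2] - b0[2]) + abs(bx - spine_x)
        # confine to the slab (strand radius fits inside slab thickness)
        mitos.append(TrueMito(
            mito_id=mito_id, cell_id=cid, length_nm=total_len,
            centroid=(spine_x, y_mid, float((sp0[2] + sp1[2]) / 2)),
            nearest_zone_nm=float("nan"), coupled=False))

    # --- cell records ------------------------------------------------------
    vox_counts = np.bincount(cell_labels.ravel(), minlength=int(cell_labels.max()) + 1)
    classes = ("sensory", "inter", "motor")
    nts = ("ACh", "Glu", "GABA")
    nt_p = (0.5, 0.3, 0.2)
    cells = []
    for i in range(spec.n_neurites):
        cells.append(CellRecord(
            cell_id=i + 1, name=f"N{i + 1:03d}", cell_class=classes[i % 3],
            neurotransmitter=nts[int(rng_meta.choice(3, p=nt_p))],
            cell_volume=float(vox_counts[i + 1]) * voxvol))
    for m, cid in enumerate(muscle_ids):
        cells.append(CellRecord(
            cell_id=cid, name=f"BWM{m + 1:02d}", cell_class="muscle",
            neurotransmitter="unknown",
            cell_volume=float(vox_counts[cid]) * voxvol))

    # --- truth distances ---------------------------------------------------
    site_positions_by_cell = {
        c: np.array([p for p, _ in ps]) if ps else np.empty((0, 3))
        for c, ps in sites_by_cell.items()}
    for tm in mitos:
        pos = site_positions_by_cell.get(tm.cell_id)
        if pos is not None and len(pos):
            tm.nearest_zone_nm = float(
                np.linalg.norm(pos - np.asarray(tm.centroid), axis=1).min())

    grid_kwargs = dict(resolution=spec.resolution)
    return SyntheticTruth(
        cell_labels=VoxelGrid(cell_labels, **grid_kwargs),
        mito_labels=VoxelGrid(mito_labels, **grid_kwargs),
        active_zones=zones, cells=cells, mitochondria=mitos, spec=spec)


# ---------------------------------------------------------------------------
# 2D training pairs
# ---------------------------------------------------------------------------

def generate_training_pairs(spec: SyntheticSpec, n_pairs: int,
                            section_size: int = 128) -> list[tuple[np.ndarray, np.ndarray]]:
    """Paired grayscale sections and exact binary mitochondria masks.

    Images: smooth bright background, darker elliptical mitochondria with
    internal stripe texture, additive Gaussian noise of scale
    ``spec.pair_noise_scale``. Masks are the exact generating ellipses.
    Deterministic given ``spec.seed``; each pair's foreground fraction lies
    inside ``spec.pair_density_band``.
    """
    if section_size < 64:
        raise ValidationError("section_size must be >= 64")
    ss = np.random.SeedSequence((spec.seed, 0x2D))
    rng = np.random.default_rng(ss)
    lo_band, hi_band = spec.pair_density_band
    pairs = []
    yy, xx = np.mgrid[0:section_size, 0:section_size]
    for _ in range(n_pairs):
        for _attempt in range(50):
            mask = np.zeros((section_size, section_size), dtype=bool)
            n_ellipses = rng.integers(3, 9)
            for _e in range(n_ellipses):
                cy, cx = rng.uniform(8, section_size - 8, size=2)
                a = rng.uniform(5, section_size / 6)
                b = rng.uniform(3, a)
                theta = rng.uniform(0, math.pi)
                ct, st = math.cos(theta), math.sin(theta)
                u = (xx - cx) * ct + (yy - cy) * st
                v = -(xx - cx) * st + (yy - cy) * ct
                mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
            frac = mask.mean()
            if lo_band <= frac <= hi_band:
                break
        background = 0.72 + 0.10 * gaussian_filter(
            rng.standard_normal((section_size, section_size)), sigma=8.0)
        background = np.clip(background, 0.60, 0.85)
        theta = rng.uniform(0, math.pi)
        phase = rng.uniform(0, 2 * math.pi)
        stripes = 0.06 * np.sin(
            2 * math.pi * (xx * math.cos(theta) + yy * math.sin(theta)) / 6.0 + phase)
        interior = 0.32 + stripes
        image = np.where(mask, interior, background)
        if spec.pair_noise_scale > 0:
            image = image + spec.pair_noise_scale * rng.standard_normal(image.shape)
        image = np.clip(image, 0.0, 1.0).astype(np.float32)
        pairs.append((image, mask))
    return pairs


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_world(truth: SyntheticTruth, out_dir) -> None:
    """Write a world's grids (HDF5) and tables (CSV) under ``out_dir``."""
    import os

    import pandas as pd

    from . import io_formats

    os.makedirs(out_dir, exist_ok=True)
    io_formats.write_label_volume(truth.cell_labels, os.path.join(out_dir, "cells.h5"))
    io_formats.write_label_volume(truth.mito_labels, os.path.join(out_dir, "mitochondria.h5"))
    io_formats.write_synapse_table(truth.active_zones,
                                   os.path.join(out_dir, "active_zones.csv"))
    io_formats.write_cell_table(truth.cells, os.path.join(out_dir, "cells.csv"))
    pd.DataFrame([{
        "mito_id": m.mito_id, "cell_id": m.cell_id, "length_nm": m.length_nm,
        "centroid_x_nm": m.centroid[0], "centroid_y_nm": m.centroid[1],
        "centroid_z_nm": m.centroid[2], "nearest_zone_nm": m.nearest_zone_nm,
        "coupled": m.coupled,
    } for m in truth.mitochondria]).to_csv(
        os.path.join(out_dir, "true_mitochondria.csv"), index=False)
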