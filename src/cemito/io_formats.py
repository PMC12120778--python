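"""Readers and writers for every on-disk artifact.

Formats
-------
* Label volumes: HDF5 (dataset ``/labels`` uint32, attrs ``resolution_nm``
  and ``offset_nm`` in (x, y, z) nm) or multi-page TIFF (uint32, one page
  per section; resolution must be supplied because TIFF tags cannot carry
  3-axis nm spacing reliably).
* Tables: UTF-8 comma-separated CSV with a mandatory header; intra-cell
  lists (postsynaptic partners) are ";"-separated inside one column.
* Skeletons: SWC, positions in nm, one tree per root.

All readers reject malformed input instead of repairing it.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import (
    ActiveZone,
    CellRecord,
    Skeleton,
    ValidationError,
    VoxelGrid,
)

LIST_SEP = ";"


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

def write_label_volume(grid: VoxelGrid, path: str | os.PathLike, dataset_name: str = "labels") -> None:
    """Write a label volume as HDF5 (default) or multi-page TIFF by suffix."""
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, grid.labels.astype(np.uint32), metadata={
            "resolution_nm": list(grid.resolution),
            "offset_nm": list(grid.offset),
        })
        return
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(dataset_name, data=grid.labels.astype(np.uint32),
                              compression="gzip", compression_opts=1)
        ds.attrs["resolution_nm"] = np.asarray(grid.resolution, dtype=float)
        ds.attrs["offset_nm"] = np.asarray(grid.offset, dtype=float)


def read_label_volume(
    path: str | os.PathLike,
    dataset_name: str = "labels",
    resolution: Sequence[float] | None = None,
    offset: Sequence[float] | None = None,
) -> VoxelGrid:
    """Read a label volume from HDF5 or TIFF.

    Resolution metadata must either be stored in the file or supplied
    explicitly; a missing resolution is an error, never a silent default.
    """
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            labels = tf.asarray()
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            res = resolution if resolution is not None else meta.get("resolution_nm")
            off = offset if offset is not None else meta.get("offset_nm", (0.0, 0.0, 0.0))
        if res is None:
            raise ValidationError(
                f"{path}: no resolution metadata in TIFF and none supplied"
            )
        return VoxelGrid(labels.astype(np.uint32), tuple(res), tuple(off))
    with h5py.File(path, "r") as f:
        if dataset_name not in f:
            raise ValidationError(f"{path}: missing dataset {dataset_name!r}")
        ds = f[dataset_name]
        labels = ds[()]
        res = resolution if resolution is not None else ds.attrs.get("resolution_nm")
        off = offset if offset is not None else ds.attrs.get("offset_nm", (0.0, 0.0, 0.0))
    if res is None:
        raise ValidationError(f"{path}: dataset lacks resolution_nm and none supplied")
    return VoxelGrid(labels.astype(np.uint32), tuple(np.asarray(res, dtype=float)),
                     tuple(np.asarray(off, dtype=float)))


def convert_volume(src: str, dst: str, dataset_name: str = "labels",
                   resolution: Sequence[float] | None = None) -> None:
    """Convert a label volume between HDF5 and TIFF containers."""
    grid = read_label_volume(src, dataset_name=dataset_name, resolution=resolution)
    write_label_volume(grid, dst, dataset_name=dataset_name)


# ---------------------------------------------------------------------------
# synapse / cell tables
# ---------------------------------------------------------------------------

ZONE_COLUMNS = ["zone_id", "presyn_cell_id", "voxel_count", "size_nm3",
                "centroid_x_nm", "centroid_y_nm", "centroid_z_nm", "partners"]


def write_synapse_table(zones: Iterable[ActiveZone], path: str | os.PathLike) -> None:
    rows = []
    for z in zones:
        rows.append({
            "zone_id": z.zone_id,
            "presyn_cell_id": z.presyn_cell_id,
            "voxel_count": z.voxel_count,
            "size_nm3": z.size,
            "centroid_x_nm": z.centroid[0],
            "centroid_y_nm": z.centroid[1],
            "centroid_z_nm": z.centroid[2],
            "partners": LIST_SEP.join(str(p) for p in z.partners),
        })
    pd.DataFrame(rows, columns=ZONE_COLUMNS).to_csv(path, index=False)


def read_synapse_table(path: str | os.PathLike) -> list[ActiveZone]:
    """Read active zones from CSV; zone and partner order are preserved."""
    df = pd.read_csv(path, dtype={"partners": str})
    missing = [c for c in ZONE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["zone_id"].duplicated().any():
        dup = df.loc[df["zone_id"].duplicated(), "zone_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate zone_id {dup}")
    zones = []
    for row in df.itertuples(index=False):
        partners_raw = "" if pd.isna(row.partners) else str(row.partners)
        parts = [p for p in partners_raw.split(LIST_SEP) if p != ""]
        if not parts:
            raise ValidationError(
                f"{path}: zone {row.zone_id} has an empty partner list"
            )
        zones.append(ActiveZone(
            zone_id=int(row.zone_id),
            presyn_cell_id=int(row.presyn_cell_id),
            voxel_count=int(row.voxel_count),
            size=float(row.size_nm3),
            centroid=(float(row.centroid_x_nm), float(row.centroid_y_nm),
                      float(row.centroid_z_nm)),
            partners=tuple(int(p) for p in parts),
        ))
    return zones


CELL_COLUMNS = ["cell_id", "name", "cell_class", "neurotransmitter", "cell_volume_nm3"]


def write_cell_table(cells: Iterable[CellRecord], path: str | os.PathLike) -> None:
    rows = [{
        "cell_id": c.cell_id,
        "name": c.name,
        "cell_class": c.cell_class,
        "neurotransmitter": c.neurotransmitter,
        "cell_volume_nm3": c.cell_volume,
    } for c in cells]
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, index=False)


def read_cell_table(path: str | os.PathLike) -> list[CellRecord]:
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["cell_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate cell_id")
    return [CellRecord(int(r.cell_id), str(r.name), str(r.cell_class),
                       str(r.neurotransmitter), float(r.cell_volume_nm3))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# SWC skeletons
# ---------------------------------------------------------------------------

def write_skeleton(skeleton: Skeleton, path: str | os.PathLike) -> None:
    """Write a skeleton forest as SWC (positions nm, one tree per root).

    SWC ids are 1-based; each root has parent -1. The node order is a
    preorder walk of each tree, so parents always precede children.
    """
    n = skeleton.n_nodes
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in skeleton.edges:
        if a == b:
            raise ValidationError("skeleton has a self-loop")
        adj[a].append(b)
        adj[b].append(a)
    lines = []
    visited = np.zeros(n, dtype=bool)
    swc_id = np.full(n, -1, dtype=int)
    next_id = 1
    for root in skeleton.roots:
        if visited[root]:
            continue
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            if visited[node]:
                raise ValidationError("cyclic edge list: skeleton must be a forest")
            visited[node] = True
            swc_id[node] = next_id
            next_id += 1
            x, y, z = skeleton.positions[node]
            r = skeleton.radii[node]
            pid = -1 if parent < 0 else swc_id[parent]
            lines.append(f"{swc_id[node]} 3 {x:.3f} {y:.3f} {z:.3f} {r:.3f} {pid}")
            for nb in sorted(adj[node], reverse=True):
                if not visited[nb]:
                    stack.append((nb, node))
    if not visited.all():
        raise ValidationError("skeleton edges include nodes unreachable from roots")
    with open(path, "w") as f:
        f.write("# SWC skeleton, positions in nm\n")
        f.write("\n".join(lines) + ("\n" if lines else ""))


def read_skeleton(path: str | os.PathLike) -> Skeleton:
    ids, positions, radii, parents = [], [], [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ValidationError(f"{path}: malformed SWC line {line!r}")
            ids.append(int(fields[0]))
            positions.append([float(fields[2]), float(fields[3]), float(fields[4])])
            r = float(fields[5])
            if r < 0:
                raise ValidationError(f"{path}: negative radius on node {fields[0]}")
            radii.append(r)
            parents.append(int(fields[6]))
    index = {node_id: i for i, node_id in enumerate(ids)}
    if len(index) != len(ids):
        raise ValidationError(f"{path}: duplicate SWC node ids")
    edges, roots = [], []
    for i, pid in enumerate(parents):
        if pid == -1:
            roots.append(i)
        else:
            if pid not in index:
                raise ValidationError(f"{path}: parent {pid} not defined")
            edges.append((index[pid], i))
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    edges_arr = np.asarray(edges, dtype=int).reshape(-1, 2)
    length = 0.0
    if len(edges_arr):
        diffs = positions[edges_arr[:, 0]] - positions[edges_arr[:, 1]]
        length = float(np.linalg.norm(diffs, axis=1).sum())
    return Skeleton(positions=positions, radii=np.asarray(radii, dtype=float),
                    edges=edges_arr, roots=tuple(roots), length=length)
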