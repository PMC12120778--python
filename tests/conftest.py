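import numpy as np
import pytest

from cemito.synthetic_data import CountLaw, SyntheticSpec, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact world shared by read-only tests: 9 neurites, 2 muscles."""
    spec = SyntheticSpec(n_neurites=9, n_muscles=2, tube_length_voxels=300,
                         mito_count_law=CountLaw(kind="poisson", mean=4), seed=7)
    return generate_world(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def bfs_flood_fill_26(mask: np.ndarray) -> np.ndarray:
    """Breadth-first 26-connected labeling in zyx scan order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    current = 0
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or labels[z, y, x]:
                    continue
                current += 1
                queue = [(z, y, x)]
                labels[z, y, x] = current
                while queue:
                    cz, cy, cx = queue.pop(0)
                    for dz, dy, dx in offsets:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if (0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                                and mask[pz, py, px] and not labels[pz, py, px]):
                            labels[pz, py, px] = current
                            queue.append((pz, py, px))
    return labels


def brute_force_surface_area(mask: np.ndarray, resolution) -> float:
    """Loop over every voxel and its 6 faces, summing exposed face areas."""
    mask = np.asarray(mask, dtype=bool)
    dx, dy, dz = resolution
    areas = {(1, 0, 0): dx * dy, (-1, 0, 0): dx * dy,   # z faces
             (0, 1, 0): dx * dz, (0, -1, 0): dx * dz,   # y faces
             (0, 0, 1): dy * dz, (0, 0, -1): dy * dz}   # x faces
    nzs, nys, nxs = mask.shape
    total = 0.0
    for z in range(nzs):
        for y in range(nys):
            for x in range(nxs):
                if not mask[z, y, x]:
                    continue
                for (oz, oy, ox), area in areas.items():
                    pz, py, px = z + oz, y + oy, x + ox
                    if not (0 <= pz < nzs and 0 <= py < nys and 0 <= px < nxs) \
                            or not mask[pz, py, px]:
                        total += area
    return total


def wilcoxon_exact_p_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration of rank splits."""
    from itertools import combinations

    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"
    rank_of = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(rank_of[v] for v in x)
    nx = len(x)
    splits = list(combinations(range(1, len(combined) + 1), nx))
    le = sum(1 for s in splits if sum(s) <= w_obs)
    ge = sum(1 for s in splits if sum(s) >= w_obs)
    return min(1.0, 2.0 * min(le, ge) / len(splits))
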