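"""Grid-based cavity detection by dual-probe solvent accessibility.

Space around the receptor is discretised on a regular lattice (0.5 Å by
default).  A grid point is accessible to a spherical probe when the probe
centred there overlaps no receptor atom, i.e. its distance to every atom
centre is at least vdW(atom) + probe radius (the Lee–Richards
solvent-accessible convention).  Cavities are the points accessible to a
small solvent probe (1.4 Å, interior regions included) but outside the bulk
solvent volume — the space swept by large (10 Å) probe spheres whose centres
sit in the boundary-connected valid-centre region.  Cavity points are
clustered by
26-connectivity; clusters smaller than 96 points (12 Å³ at 0.5 Å spacing,
about one water molecule) are discarded and survivors are labelled 1..n in
decreasing volume order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .structures import ProteinStructure

__all__ = [
    "Cavity",
    "CavityGrid",
    "accessibility_mask",
    "detect_cavities",
    "neuron_in_cavity",
    "neuron_density",
    "write_cavity_dx",
    "write_cavity_pdb",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Cavity:
    id: int
    voxel_count: int
    spacing: float
    voxels: np.ndarray = field(repr=False)     # (n, 3) integer grid indices

    @property
    def volume(self) -> float:
        """Cavity volume in Å³ — exactly voxel_count × spacing³."""
        return self.voxel_count * self.spacing ** 3


@dataclass
class CavityGrid:
    origin: np.ndarray            # (3,) Å, snapped to multiples of spacing
    spacing: float
    dims: tuple[int, int, int]
    label: np.ndarray             # per-grid-point int, 0 = non-cavity
    cavities: list[Cavity]

    def cavity(self, cavity_id: int) -> Cavity:
        for c in self.cavities:
            if c.id == cavity_id:
                return c
        raise KeyError(cavity_id)

    def to_table(self) -> list[dict]:
        return [
            {"id": c.id, "voxel_count": c.voxel_count, "volume": c.volume}
            for c in self.cavities
        ]


def _grid_geometry(structure: ProteinStructure, spacing: float,
                   margin: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Bounding box padded by margin, origin snapped to multiples of spacing."""
    lo = structure.coords.min(axis=0) - margin
    hi = structure.coords.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    dims = tuple(int(np.ceil((hi[d] - origin[d]) / spacing)) + 1 for d in range(3))
    return origin, dims


def _blocked_mask(structure: ProteinStructure, probe_radius: float,
                  origin: np.ndarray, dims: tuple[int, int, int],
                  spacing: float) -> np.ndarray:
    """Grid points within vdW + probe of any atom, marked atom by atom on a
    local index window (cheap: each atom touches O((r/spacing)^3) points)."""
    blocked = np.zeros(dims, dtype=bool)
    coords = structure.coords
    radii = structure.radii + probe_radius
    for (ax, ay, az), r in zip(coords, radii):
        lo = np.maximum(np.floor((np.array([ax, ay, az]) - r - origin) / spacing), 0).astype(int)
        hi = np.minimum(np.ceil((np.array([ax, ay, az]) + r - origin) / spacing).astype(int) + 1,
                        dims)
        if np.any(lo >= hi):
            continue
        gx = origin[0] + spacing * np.arange(lo[0], hi[0])
        gy = origin[1] + spacing * np.arange(lo[1], hi[1])
        gz = origin[2] + spacing * np.arange(lo[2], hi[2])
        d2 = ((gx - ax) ** 2)[:, None, None] + ((gy - ay) ** 2)[None, :, None] \
            + ((gz - az) ** 2)[None, None, :]
        blocked[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 < r * r
    return blocked


def _boundary_connected(mask: np.ndarray) -> np.ndarray:
    """26-connected flood fill of ``mask`` from the grid faces."""
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return np.zeros_like(mask)
    face_labels = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ]))
    face_labels = face_labels[face_labels > 0]
    return np.isin(labels, face_labels)


def accessibility_mask(
    structure: ProteinStructure,
    probe_radius: float,
    spacing: float = 0.5,
    margin: float | None = None,
    *,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(geometric, boundary_connected, origin)`` accessibility masks.

    ``geometric`` marks every point where a probe of the given radius fits
    (interior cavities included); ``boundary_connected`` additionally requires
    a 26-connected path of accessible points to the grid boundary (the mask
    used for bulk solvent).
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    if margin is None:
        margin = probe_radius + float(structure.radii.max())
    if origin is None or dims is None:
        origin, dims = _grid_geometry(structure, spacing, margin)
    geometric = ~_blocked_mask(structure, probe_radius, origin, dims, spacing)
    return geometric, _boundary_connected(geometric), origin


def detect_cavities(
    structure: ProteinStructure,
    probe: float = 1.4,
    bulk_probe: float = 10.0,
    spacing: float = 0.5,
    min_voxels: int = 96,
    max_grid_points: int = 200_000_000,
) -> CavityGrid:
    """Detect cavities: solvent-accessible points that bulk solvent cannot reach."""
    if bulk_probe <= probe:
        raise ValueError("bulk_probe must exceed the solvent probe")
    margin = bulk_probe + float(structure.radii.max())
    origin, dims = _grid_geometry(structure, spacing, margin)
    if int(np.prod(dims)) > max_grid_points:
        raise MemoryError(
            f"grid of {np.prod(dims):,} points exceeds the cap; increase spacing"
        )
    solvent, _, _ = accessibility_mask(structure, probe, spacing,
                                       origin=origin, dims=dims)
    bulk_geometric = ~_blocked_mask(structure, bulk_probe, origin, dims, spacing)
    bulk_centers = _boundary_connected(bulk_geometric)
    # bulk solvent VOLUME: everything covered by a bulk probe sphere whose
    # centre sits in the boundary-connected valid-centre region
    dist_to_bulk = ndimage.distance_transform_edt(~bulk_centers, sampling=spacing)
    bulk_volume = dist_to_bulk <= bulk_probe
    cavity_mask = solvent & ~bulk_volume

    labels, n = ndimage.label(cavity_mask, structure=_CONN26)
    out_label = np.zeros(dims, dtype=np.int32)
    cavities: list[Cavity] = []
    if n:
        counts = np.bincount(labels.ravel())[1:]          # cluster sizes, label 1..n
        keep = [(int(c), k + 1) for k, c in enumerate(counts) if c >= min_voxels]
        keep.sort(key=lambda t: (-t[0], t[1]))            # decreasing volume
        for new_id, (count, old) in enumerate(keep, start=1):
            vox = np.argwhere(labels == old)
            out_label[labels == old] = new_id
            cavities.append(Cavity(new_id, count, spacing, vox))
    return CavityGrid(np.asarray(origin, dtype=float), spacing, tuple(dims),
                      out_label, cavities)


def neuron_in_cavity(position, grid: CavityGrid) -> int | None:
    """Cavity id at a 3D position, or None.

    The position belongs to a cavity if any of the 8 corners of the grid cell
    enclosing it carries that cavity's label; ties across labels go to the
    smallest id.
    """
    f = (np.asarray(position, dtype=float) - grid.origin) / grid.spacing
    i0 = np.floor(f).astype(int)
    if np.any(i0 < 0) or np.any(i0 + 1 >= np.array(grid.dims)):
        return None
    corners = grid.label[i0[0]:i0[0] + 2, i0[1]:i0[1] + 2, i0[2]:i0[2] + 2]
    positive = corners[corners > 0]
    return int(positive.min()) if positive.size else None


def neuron_density(som, cavity: Cavity, grid: CavityGrid) -> float:
    """Neurons inside the cavity divided by its volume (neurons/Å³)."""
    if not som.trained:
        raise ValueError("SOM must be trained")
    flat = som.neurons.reshape(-1, 3)
    inside = sum(1 for pos in flat if neuron_in_cavity(pos, grid) == cavity.id)
    return inside / cavity.volume


# ---------------------------------------------------------------------------
# export

def write_cavity_dx(grid: CavityGrid, path: str | Path) -> None:
    """Export the cavity label field as an OpenDX scalar grid."""
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    head = (
        f"object 1 class gridpositions counts {nx} {ny} {nz}\n"
        f"origin {ox:.3f} {oy:.3f} {oz:.3f}\n"
        f"delta {s:.3f} 0 0\ndelta 0 {s:.3f} 0\ndelta 0 0 {s:.3f}\n"
        f"object 2 class gridconnections counts {nx} {ny} {nz}\n"
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
    )
    vals = grid.label.astype(float).ravel()
    body = "\n".join(
        " ".join(f"{v:g}" for v in vals[i:i + 3]) for i in range(0, len(vals), 3)
    )
    Path(path).write_text(head + body +
                          '\nattribute "dep" string "positions"\n'
                          'object "cavities" class field\n')


def write_cavity_pdb(grid: CavityGrid, path: str | Path) -> None:
    """Write cavity grid points as pseudo-atoms, cavity id in the B-factor."""
    lines = []
    serial = 0
    for cav in grid.cavities:
        for idx in cav.voxels:
            serial += 1
            x, y, z = grid.origin + grid.spacing * idx
            lines.append(
                f"HETATM{serial % 100000:5d} {'CAV':<4}{'CAV':>4} A{cav.id % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{float(cav.id):6.2f}          {'C':>2}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cavity_json(grid: CavityGrid, path: str | Path) -> None:
    Path(path).write_text(json.dumps(grid.to_table(), indent=2) + "\n")
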