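"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline's inputs without any external data:

* :func:`make_hollow_receptor` — pseudo-atom spherical shells whose interior
  void is an analytically known cavity (optionally opened into a surface
  pocket by a mouth cone), for the cavity detector;
* :func:`sample_poses` — docking-pose clouds concentrated in one or more
  Gaussian "pockets" plus a diffuse uniform background, with per-pose scores
  lower (better) in the favoured pocket, for the SOM/consensus stages;
* :func:`make_toy_library` — random valence-correct small-molecule graphs
  (4–12 heavy atoms) emitted as SMILES, for the feature/enrichment stages.

Pose "ligands" are rigid random atom clusters, not conformer ensembles:
enough to exercise density and consensus logic, with no claim of physical
docking energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import Pose, PoseSet, ProteinStructure, ReferenceLigand

__all__ = [
    "PocketSpec",
    "SyntheticTruth",
    "make_hollow_receptor",
    "sample_poses",
    "make_toy_library",
    "write_fixture",
]


@dataclass
class PocketSpec:
    center: tuple[float, float, float]
    spread: float                     # Å, isotropic Gaussian sd of pose centres
    weight: float                     # fraction of poses landing here
    label: str = "pocket"

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated fixture."""

    assignments: list[tuple[str, int, str]] = field(default_factory=list)
    void_volume: float | None = None          # analytic interior volume, Å³
    inner_radius: float | None = None
    reference_ligand: ReferenceLigand | None = None
    pocket_centers: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_hollow_receptor(
    inner_radius: float = 8.0,
    shell_thickness: float = 3.0,
    atom_spacing: float = 1.0,
    mouth_radius: float | None = None,
    seed: int = 0,
    *,
    atom_radius: float = 1.7,
    probe: float = 1.4,
    check_sealed: bool = True,
) -> tuple[ProteinStructure, SyntheticTruth]:
    """Spherical shell of carbon-like pseudo-atoms enclosing a void.

    A ``mouth_radius`` removes a cone of atoms around +z, turning the
    interior cavity into a surface pocket.  For sealed shells a flood-fill
    self-check verifies the solvent probe cannot leak through the tiling.
    """
    if inner_radius <= 2 * probe:
        raise ValueError("inner_radius must exceed twice the probe radius")
    if atom_spacing > 1.5:
        raise ValueError("atom_spacing above 1.5 Å cannot guarantee a sealed shell")
    layers = np.arange(inner_radius + atom_radius,
                       inner_radius + atom_radius + shell_thickness + 1e-9,
                       atom_spacing)
    if len(layers) == 0:
        raise ValueError("shell has no atoms")
    coords = []
    for r in layers:
        n = max(8, int(np.ceil(4 * np.pi * r ** 2 / atom_spacing ** 2)))
        coords.append(r * _fibonacci_sphere(n))
    coords = np.concatenate(coords)
    if mouth_radius is not None:
        # drop atoms inside the mouth cone around +z
        half_angle = np.arctan2(mouth_radius, inner_radius)
        z = coords[:, 2] / np.linalg.norm(coords, axis=1)
        coords = coords[np.arccos(np.clip(z, -1, 1)) > half_angle]
    if len(coords) == 0:
        raise ValueError("no shell atoms remain")
    structure = ProteinStructure(["C"] * len(coords), coords,
                                 np.full(len(coords), atom_radius),
                                 id="hollow-shell")
    if check_sealed and mouth_radius is None:
        from .cavities import accessibility_mask

        geometric, bulk, origin = accessibility_mask(structure, probe, spacing=1.0)
        centre_idx = tuple(np.round((-origin) / 1.0).astype(int))
        if bulk[centre_idx]:
            raise ValueError("shell is leaky: probe reaches the interior from outside")
    truth = SyntheticTruth(void_volume=4.0 / 3.0 * np.pi * inner_radius ** 3,
                           inner_radius=inner_radius)
    return structure, truth


def _rigid_cluster(rng: np.random.Generator, n_atoms: int,
                   bond_length: float = 1.5) -> np.ndarray:
    """Random chain-like rigid cluster of atoms, centred at the origin."""
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        v = rng.normal(size=3)
        pos[i] = pos[i - 1] + bond_length * v / np.linalg.norm(v)
    return pos - pos.mean(axis=0)


def sample_poses(
    pockets: list[PocketSpec],
    n_ligands: int = 50,
    atoms_per_ligand: tuple[int, int] = (3, 8),
    background_box: tuple[float, float] = (-30.0, 30.0),
    score_model: dict[str, float] | None = None,
    seed: int = 0,
    *,
    poses_per_ligand: int = 20,
    score_sd: float = 0.5,
) -> tuple[list[PoseSet], SyntheticTruth]:
    """Pose clouds in Gaussian pockets plus uniform background.

    Pocket weights must sum to at most 1; the remainder is the diffuse
    background fraction.  Scores are normal around per-pocket means
    (``score_model``, label → mean; the favoured pocket should be lowest).
    """
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    lo, hi = background_box
    if not hi > lo:
        raise ValueError("degenerate background box")
    wsum = sum(p.weight for p in pockets)
    if wsum > 1.0 + 1e-9 or any(p.weight < 0 for p in pockets):
        raise ValueError("pocket weights must be non-negative and sum to <= 1")
    labels = [p.label for p in pockets] + ["background"]
    probs = [p.weight for p in pockets] + [max(0.0, 1.0 - wsum)]
    score_model = score_model or {lab: -6.0 - 2.0 * (probs[i] == max(probs[:-1] or [0]))
                                  for i, lab in enumerate(labels[:-1])}
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(pocket_centers={p.label: tuple(p.center) for p in pockets})
    pose_sets = []
    for li in range(n_ligands):
        lig_id = f"lig{li:04d}"
        n_atoms = int(rng.integers(atoms_per_ligand[0], atoms_per_ligand[1] + 1))
        template = _rigid_cluster(rng, n_atoms)
        poses = []
        for pi in range(poses_per_ligand):
            which = rng.choice(len(labels), p=np.array(probs) / sum(probs))
            lab = labels[which]
            if lab == "background":
                centre = rng.uniform(lo, hi, size=3)
                mean_score = score_model.get("background", 0.0)
            else:
                pk = pockets[which]
                centre = np.asarray(pk.center) + rng.normal(scale=pk.spread, size=3)
                mean_score = score_model.get(lab, -6.0)
            # random rigid rotation of the template
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            coords = template @ R.T + centre
            score = float(rng.normal(mean_score, score_sd))
            poses.append(Pose(pi, coords, score, ["C"] * n_atoms))
            truth.assignments.append((lig_id, pi, lab))
        pose_sets.append(PoseSet(lig_id, poses))
    # a probe ligand sitting in the heaviest pocket, for evaluation
    if pockets:
        major = max(pockets, key=lambda p: p.weight)
        pts = np.asarray(major.center) + rng.normal(scale=major.spread,
                                                    size=(8, 3))
        truth.reference_ligand = ReferenceLigand(pts, np.ones(8, bool), id="probe")
    return pose_sets, truth


_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def make_toy_library(n_molecules: int, seed: int = 0,
                     size_range: tuple[int, int] = (4, 12)) -> list[str]:
    """Random connected heavy-atom graphs with valid valences, as SMILES."""
    from rdkit import Chem

    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_molecules):
        n = int(rng.integers(size_range[0], size_range[1] + 1))
        symbols = [str(rng.choice(["C", "C", "C", "N", "O"])) for _ in range(n)]
        mol = Chem.RWMol()
        free = []
        for s in symbols:
            a = Chem.Atom(s)
            mol.AddAtom(a)
            free.append(_MAX_VALENCE[s])
        for i in range(1, n):
            candidates = [j for j in range(i) if free[j] > 0]
            j = int(rng.choice(candidates))
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            free[i] -= 1
            free[j] -= 1
        # an occasional ring closure where valences allow
        if rng.random() < 0.4:
            open_atoms = [i for i in range(n) if free[i] > 0]
            if len(open_atoms) >= 2:
                i, j = rng.choice(open_atoms, size=2, replace=False)
                if mol.GetBondBetweenAtoms(int(i), int(j)) is None:
                    mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        out.append(Chem.MolToSmiles(m))
    return out


def write_fixture(directory: str | Path, pose_sets: list[PoseSet],
                  structure: ProteinStructure | None = None,
                  smiles: list[str] | None = None) -> dict[str, Path]:
    """Emit a fixture in the formats the real pipeline consumes."""
    from .structures import write_poses_sdf

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if structure is not None:
        lines = []
        for n, ((x, y, z), e) in enumerate(zip(structure.coords,
                                               structure.elements), start=1):
            lines.append(
                f"ATOM  {n % 100000:5d} {e[:2]:<4}{'SYN':>4} A{n % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {e[:2]:>2}"
            )
        lines.append("END")
        paths["receptor"] = d / "receptor.pdb"
        paths["receptor"].write_text("\n".join(lines) + "\n")
    if pose_sets:
        paths["poses"] = d / "poses.sdf"
        paths["scores"] = d / "scores.tsv"
        write_poses_sdf(pose_sets, paths["poses"], score_table=paths["scores"])
    if smiles is not None:
        paths["library"] = d / "library.smi"
        paths["library"].write_text("\n".join(smiles) + "\n")
    return paths
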