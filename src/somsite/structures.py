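"""Molecular structure I/O: receptors, docked pose sets and reference ligands.

Receptors are read from PDB with Biopython; multi-pose ligand files are read
from SDF (RDKit), PDBQT (AutoDock Vina output; small text parser, no Python
reader exists for the dialect) or mol2.  Docking scores come from PDBQT
``REMARK VINA RESULT`` lines, SDF data tags, or a plain-text sidecar table
``ligand_id<TAB>pose_index<TAB>score``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BONDI_RADII",
    "ProteinStructure",
    "Pose",
    "PoseSet",
    "ReferenceLigand",
    "read_receptor",
    "read_poses",
    "read_reference_ligand",
    "read_score_table",
    "write_neuron_pdb",
]

#: Bondi van der Waals radii (Å) for common heavy elements.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92, "SI": 2.10, "AS": 1.85,
    # common metal ions in receptor files; Bondi where defined
    "ZN": 1.39, "MG": 1.73, "CA": 2.31, "MN": 2.05, "FE": 2.05,
    "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63, "CD": 1.58,
}


@dataclass
class ProteinStructure:
    """A receptor as a flat list of atoms with element, coordinate and vdW radius."""

    elements: list[str]
    coords: np.ndarray            # (n, 3) Å
    radii: np.ndarray             # (n,) Å
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.coords) == 0:
            raise ValueError("structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("all vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Pose:
    index: int
    coords: np.ndarray            # (n_atoms, 3) Å, heavy atoms at minimum
    score: float
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) == 0:
            raise ValueError("pose must contain at least one atom")
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")


@dataclass
class PoseSet:
    """All retained docked poses of one ligand, sorted by ascending score."""

    ligand_id: str
    poses: list[Pose] = field(default_factory=list)

    def truncate(self, max_poses: int) -> "PoseSet":
        """Keep the ``max_poses`` lowest-score poses (stable for ties)."""
        order = sorted(range(len(self.poses)), key=lambda i: (self.poses[i].score, i))
        kept = [self.poses[i] for i in order[:max_poses]]
        return PoseSet(self.ligand_id, kept)


@dataclass
class ReferenceLigand:
    """Co-crystal ligand used to evaluate predicted binding sites."""

    coords: np.ndarray            # (n, 3) Å
    heavy: np.ndarray             # (n,) bool
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.heavy = np.asarray(self.heavy, dtype=bool)
        if len(self.coords) == 0:
            raise ValueError("reference ligand must contain at least one atom")


# ---------------------------------------------------------------------------
# receptor reading

def read_receptor(
    path: str | Path,
    radius_table: Mapping[str, float] | None = None,
    *,
    include_hetatm: bool = False,
    include_hydrogens: bool = False,
    default_radius: float | None = None,
) -> ProteinStructure:
    """Read a PDB receptor into a :class:`ProteinStructure`.

    One atom per ATOM record (HETATM optional); hydrogens are excluded by
    default.  Every element must resolve in ``radius_table`` (Bondi radii by
    default) unless ``default_radius`` is given.
    """
    from Bio.PDB import PDBParser

    table = {k.upper(): v for k, v in (radius_table or BONDI_RADII).items()}
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))

    elements, coords, radii = [], [], []
    for atom in structure.get_atoms():
        hetflag = atom.get_parent().get_id()[0].strip()
        if hetflag and not include_hetatm:
            continue
        elem = (atom.element or "").strip().upper()
        if not elem:
            elem = atom.get_name().strip()[:1].upper()
        if elem == "H" and not include_hydrogens:
            continue
        if elem in table:
            r = table[elem]
        elif default_radius is not None:
            r = default_radius
        else:
            raise ValueError(
                f"unknown element {elem!r} in {path.name} and no default radius configured"
            )
        elements.append(elem)
        coords.append(atom.get_coord())
        radii.append(r)

    if not coords:
        raise ValueError(f"no heavy atoms found in {path}")
    return ProteinStructure(elements, np.array(coords, dtype=float),
                            np.array(radii, dtype=float), id=path.stem)


# ---------------------------------------------------------------------------
# pose reading

def read_score_table(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a sidecar score table: whitespace-separated ligand_id, pose_index, score."""
    scores: dict[tuple[str, int], float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lig, idx, s = line.split()[:3]
        scores[(lig, int(idx))] = float(s)
    return scores


def _heavy_filter(elements: Sequence[str], coords: np.ndarray,
                  heavy_only: bool) -> tuple[list[str], np.ndarray]:
    if not heavy_only:
        return list(elements), coords
    keep = [i for i, e in enumerate(elements) if e.upper() != "H"]
    return [elements[i] for i in keep], coords[keep]


def _poses_from_sdf(path: Path, score_tag: str | None,
                    sidecar: dict | None, heavy_only: bool) -> dict[str, list[Pose]]:
    from rdkit import Chem

    by_ligand: dict[str, list[Pose]] = {}
    suppl = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in suppl:
        if mol is None:
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        name = name or path.stem
        poses = by_ligand.setdefault(name, [])
        idx = len(poses)
        conf = mol.GetConformer()
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        elements, coords = _heavy_filter(elements, coords, heavy_only)
        if score_tag is not None and mol.HasProp(score_tag):
            score = float(mol.GetProp(score_tag))
        elif sidecar is not None and (name, idx) in sidecar:
            score = sidecar[(name, idx)]
        else:
            raise ValueError(f"pose {idx} of ligand {name!r} in {path.name} has no score")
        poses.append(Pose(idx, coords, score, elements))
    if not by_ligand:
        raise ValueError(f"no molecules parsed from {path}")
    return by_ligand


def _poses_from_pdbqt(path: Path, sidecar: dict | None,
                      heavy_only: bool) -> dict[str, list[Pose]]:
    """Parse AutoDock Vina multi-model PDBQT output."""
    name = path.stem
    models: list[tuple[float | None, list[str], list[list[float]]]] = []
    score: float | None = None
    elems: list[str] = []
    xyz: list[list[float]] = []
    in_model = False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, score, elems, xyz = True, None, [], []
        elif rec == "ENDMDL":
            models.append((score, elems, xyz))
            in_model = False
        elif line.startswith("REMARK VINA RESULT:"):
            score = float(line.split()[3])
        elif rec in ("ATOM", "HETATM"):
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            # PDBQT column 78- holds the AutoDock atom type; map to element
            ad_type = line[77:].strip().upper() or line[12:16].strip()[:1].upper()
            elem = {"A": "C", "NA": "N", "OA": "O", "SA": "S",
                    "HD": "H", "HS": "H"}.get(ad_type, ad_type)
            elems.append(elem)
            xyz.append([x, y, z])
    if in_model:
        raise ValueError(f"unterminated MODEL block in {path}")
    if not models and xyz:          # single-model file without MODEL records
        models.append((score, elems, xyz))
    if not models:
        raise ValueError(f"no poses parsed from {path}")

    poses = []
    for idx, (s, elements, coords) in enumerate(models):
        if s is None:
            if sidecar is not None and (name, idx) in sidecar:
                s = sidecar[(name, idx)]
            else:
                raise ValueError(f"pose {idx} in {path.name} has no score")
        elements, arr = _heavy_filter(elements, np.array(coords, dtype=float), heavy_only)
        poses.append(Pose(idx, arr, s, elements))
    return {name: poses}


def _poses_from_mol2(path: Path, sidecar: dict | None,
                     heavy_only: bool) -> dict[str, list[Pose]]:
    """Parse a (possibly multi-molecule) TRIPOS mol2 file.

    Only molecule names, atom elements and coordinates are consumed; charge
    columns may be absent.
    """
    text = Path(path).read_text()
    blocks = [b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    if not blocks:
        raise ValueError(f"no molecules parsed from {path}")
    by_ligand: dict[str, list[Pose]] = {}
    for block in blocks:
        lines = block.splitlines()
        name = lines[1].strip() if len(lines) > 1 and lines[1].strip() else path.stem
        elems, xyz = [], []
        in_atoms = False
        for line in lines:
            if line.startswith("@<TRIPOS>"):
                in_atoms = line.startswith("@<TRIPOS>ATOM")
                continue
            if in_atoms and line.strip():
                parts = line.split()
                x, y, z = map(float, parts[2:5])
                sybyl = parts[5] if len(parts) > 5 else parts[1]
                elems.append(sybyl.split(".")[0].upper())
                xyz.append([x, y, z])
        if not xyz:
            raise ValueError(f"molecule {name!r} in {path.name} has no atoms")
        poses = by_ligand.setdefault(name, [])
        idx = len(poses)
        if sidecar is None or (name, idx) not in sidecar:
            raise ValueError(f"pose {idx} of ligand {name!r} in {path.name} has no score")
        elements, arr = _heavy_filter(elems, np.array(xyz, dtype=float), heavy_only)
        poses.append(Pose(idx, arr, sidecar[(name, idx)], elements))
    return by_ligand


def read_poses(
    paths: Iterable[str | Path],
    format: str = "sdf",
    max_poses: int = 20,
    *,
    score_tag: str | None = "score",
    score_table: str | Path | None = None,
    heavy_only: bool = True,
) -> list[PoseSet]:
    """Read docked poses, sort each ligand's poses by ascending score and keep
    at most ``max_poses`` (the 20 lowest-energy poses by default)."""
    if max_poses < 1:
        raise ValueError("max_poses must be positive")
    sidecar = read_score_table(score_table) if score_table is not None else None
    merged: dict[str, list[Pose]] = {}
    for p in paths:
        p = Path(p)
        if format == "sdf":
            parsed = _poses_from_sdf(p, score_tag, sidecar, heavy_only)
        elif format == "pdbqt":
            parsed = _poses_from_pdbqt(p, sidecar, heavy_only)
        elif format == "mol2":
            parsed = _poses_from_mol2(p, sidecar, heavy_only)
        else:
            raise ValueError(f"unknown pose format {format!r}")
        for name, poses in parsed.items():
            merged.setdefault(name, []).extend(poses)
    return [PoseSet(name, poses).truncate(max_poses) for name, poses in merged.items()]


def read_reference_ligand(path: str | Path, format: str | None = None) -> ReferenceLigand:
    """Read a co-crystal ligand from PDB or SDF; all atoms kept, heavy flagged."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        elems, xyz = [], []
        for line in path.read_text().splitlines():
            if line[:6].strip() in ("ATOM", "HETATM"):
                elem = line[76:78].strip().upper() or line[12:16].strip()[:1].upper()
                elems.append(elem)
                xyz.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        if not xyz:
            raise ValueError(f"no atoms in {path}")
        heavy = np.array([e != "H" for e in elems])
        return ReferenceLigand(np.array(xyz), heavy, id=path.stem)
    if fmt in ("sdf", "mol"):
        from rdkit import Chem

        mol = next(iter(Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)))
        if mol is None:
            raise ValueError(f"could not parse {path}")
        coords = np.array(mol.GetConformer().GetPositions())
        heavy = np.array([a.GetAtomicNum() > 1 for a in mol.GetAtoms()])
        return ReferenceLigand(coords, heavy, id=path.stem)
    raise ValueError(f"unsupported reference-ligand format {fmt!r}")


# ---------------------------------------------------------------------------
# writing

def write_poses_sdf(pose_sets: Sequence[PoseSet], path: str | Path,
                    score_tag: str = "score",
                    score_table: str | Path | None = None) -> None:
    """Write pose sets to a multi-molecule SDF (one record per pose, score in
    a data tag) and optionally a sidecar score table."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401  (registers conformer ops)

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    table_lines = []
    for ps in pose_sets:
        for pose in ps.poses:
            mol = Chem.RWMol()
            for e in (pose.elements or ["C"] * len(pose.coords)):
                a = Chem.Atom(e.capitalize())
                a.SetNoImplicit(True)
                mol.AddAtom(a)
            conf = Chem.Conformer(len(pose.coords))
            for i, (x, y, z) in enumerate(pose.coords):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            m = mol.GetMol()
            m.AddConformer(conf)
            m.SetProp("_Name", ps.ligand_id)
            m.SetProp(score_tag, repr(pose.score))
            writer.write(m)
            table_lines.append(f"{ps.ligand_id}\t{pose.index}\t{pose.score!r}")
    writer.close()
    if score_table is not None:
        Path(score_table).write_text("\n".join(table_lines) + "\n")


def write_neuron_pdb(som, per_neuron_value, path: str | Path) -> None:
    """Write one HETATM pseudo-atom per trained SOM neuron, with the given
    per-neuron scalar (U-value, mean score, ...) in the B-factor column."""
    if not som.trained:
        raise ValueError("SOM must be trained before export")
    values = np.asarray(per_neuron_value, dtype=float).ravel()
    flat = som.neurons.reshape(-1, 3)
    if len(values) != len(flat):
        raise ValueError(f"expected {len(flat)} values, got {len(values)}")
    lines = []
    for n, ((x, y, z), v) in enumerate(zip(flat, values), start=1):
        serial = n % 100000
        lines.append(
            f"HETATM{serial:5d} {'NEU':<4}{'NEU':>4} A{(n % 10000):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{v:6.2f}          {'C':>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
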