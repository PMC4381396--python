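"""Circular (Morgan) substructure decomposition of ligands.

Each compound is decomposed into the circular atom environments of every
heavy atom for radii 0–3 bonds; an environment's canonical Morgan hash is
its feature identifier, stable across runs and atom orderings.  Occurrences
whose atom sets contain fewer than 3 or more than 7 heavy atoms are
discarded, leaving "chemical features" — small moieties whose geometric
centres in each docked pose can feed the SOM in place of raw atoms and whose
identities support enrichment statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureRecord",
    "FeatureCenter",
    "decompose",
    "feature_centers",
    "assign_to_ccs",
]


@dataclass(frozen=True)
class FeatureRecord:
    feature_id: int
    heavy_atom_count: int
    atom_indices: tuple[int, ...]      # heavy-atom indices, sorted
    ligand_id: str = ""


@dataclass(frozen=True)
class FeatureCenter:
    feature_id: int
    ligand_id: str
    pose_index: int
    center: tuple[float, float, float]


def _env_atoms(mol, atom_idx: int, radius: int) -> set[int]:
    from rdkit import Chem

    if radius == 0:
        return {atom_idx}
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
    atoms = {atom_idx}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return atoms


def decompose(molecule, ligand_id: str = "", *, max_radius: int = 3,
              min_atoms: int = 3, max_atoms: int = 7) -> list[FeatureRecord]:
    """Enumerate circular environments of every heavy atom (radius 0..3),
    keep those spanning ``min_atoms``–``max_atoms`` heavy atoms, and
    deduplicate identical (feature id, atom set) occurrences.

    ``molecule`` is an RDKit Mol or a SMILES string.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparsable molecule for ligand {ligand_id!r}")
    else:
        mol = molecule
    try:
        mol = Chem.RemoveHs(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:          # noqa: BLE001 - RDKit raises many types
        raise ValueError(f"unsanitizable molecule for ligand {ligand_id!r}: {exc}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"molecule for ligand {ligand_id!r} has no heavy atoms")

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max_radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    seen: set[tuple[int, tuple[int, ...]]] = set()
    records: list[FeatureRecord] = []
    for fid, hits in sorted(ao.GetBitInfoMap().items()):
        for atom_idx, radius in hits:
            atoms = tuple(sorted(_env_atoms(mol, atom_idx, radius)))
            if not (min_atoms <= len(atoms) <= max_atoms):
                continue
            key = (int(fid), atoms)
            if key in seen:
                continue
            seen.add(key)
            records.append(FeatureRecord(int(fid), len(atoms), atoms, ligand_id))
    return records


def feature_centers(features: list[FeatureRecord], pose_coords: np.ndarray,
                    pose_index: int = 0,
                    index_map: dict[int, int] | None = None) -> list[FeatureCenter]:
    """Geometric centre of each feature occurrence in one pose.

    ``pose_coords`` must hold one row per molecule heavy atom in molecule
    order, or ``index_map`` must translate molecule atom indices to pose rows.
    """
    coords = np.asarray(pose_coords, dtype=float)
    centers = []
    for f in features:
        if index_map is not None:
            try:
                rows = [index_map[a] for a in f.atom_indices]
            except KeyError as exc:
                raise ValueError(f"index map is missing molecule atom {exc}")
        else:
            if f.atom_indices and max(f.atom_indices) >= len(coords):
                raise ValueError(
                    "pose atom count does not cover the molecule; pass index_map"
                )
            rows = list(f.atom_indices)
        c = coords[rows].mean(axis=0)
        centers.append(FeatureCenter(f.feature_id, f.ligand_id, pose_index,
                                     tuple(float(v) for v in c)))
    return centers


def assign_to_ccs(centers: list[FeatureCenter], ccs, som, as_rank: int = 1,
                  ) -> tuple[set[int], set[int], dict[int, bool]]:
    """Partition feature ids by whether any occurrence centre ever falls
    within r_CC of the active-site CC (the CC at ``as_rank``).

    Returns ``(F_AS, F_AS_bar, per_feature_flag)``; the two sets partition
    the ids present in ``centers``.
    """
    from .consensus import compute_rcc

    as_cc = next((c for c in ccs if c.rank == as_rank), None)
    if as_cc is None:
        raise ValueError(f"no CC with rank {as_rank}")
    r = as_cc.r_cc if as_cc.r_cc is not None else compute_rcc(as_cc, som)
    neurons = as_cc.neuron_coords(som)

    in_as: dict[int, bool] = {}
    if centers:
        pts = np.array([c.center for c in centers])
        d2 = ((pts[:, None, :] - neurons[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        hit = d2 <= r * r
        for c, h in zip(centers, hit):
            in_as[c.feature_id] = in_as.get(c.feature_id, False) or bool(h)
    f_as = {fid for fid, h in in_as.items() if h}
    f_as_bar = {fid for fid, h in in_as.items() if not h}
    return f_as, f_as_bar, in_as
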