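"""Model/Results facade over the binding-site pipeline.

:class:`BindingSiteModel` holds the data (docked pose sets, optionally a
receptor and a co-crystal reference ligand) and the run configuration;
:meth:`BindingSiteModel.fit` trains the SOM on the pose-atom cloud, extracts
consensual clusters and returns a :class:`BindingSiteResults` carrying the
estimates (clusters, radii, densities), diagnostics (quantization errors,
GMM summaries) and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cavities as _cav
from . import consensus as _cons
from . import som as _som
from .config import RunConfig
from .structures import PoseSet, ProteinStructure, ReferenceLigand

__all__ = ["BindingSiteModel", "BindingSiteResults"]


class BindingSiteModel:
    """Binding-site identification model over docked ligand poses.

    Parameters
    ----------
    pose_sets
        Docked poses per ligand (scores ascending, already truncated).
    receptor
        Optional receptor structure; enables cavity detection and
        neuron-density characterisation.
    reference_ligand
        Optional co-crystal ligand; enables Top1/Top3 evaluation.
    config
        Run parameters; defaults are the published operating point.
    """

    def __init__(self, pose_sets: list[PoseSet],
                 receptor: ProteinStructure | None = None,
                 reference_ligand: ReferenceLigand | None = None,
                 config: RunConfig | None = None):
        if not pose_sets:
            raise ValueError("need at least one pose set")
        self.pose_sets = pose_sets
        self.receptor = receptor
        self.reference_ligand = reference_ligand
        self.config = config or RunConfig()
        self.config.validate()

    @classmethod
    def from_files(cls, pose_paths, format: str = "sdf",
                   receptor_path=None, reference_ligand_path=None,
                   config: RunConfig | None = None, **read_kwargs) -> "BindingSiteModel":
        from . import structures as io

        config = config or RunConfig()
        poses = io.read_poses(pose_paths, format=format,
                              max_poses=config.max_poses,
                              heavy_only=config.heavy_only, **read_kwargs)
        receptor = (io.read_receptor(receptor_path)
                    if receptor_path is not None else None)
        ligand = (io.read_reference_ligand(reference_ligand_path)
                  if reference_ligand_path is not None else None)
        return cls(poses, receptor, ligand, config)

    # ------------------------------------------------------------------
    @property
    def points(self) -> np.ndarray:
        """All pose-atom coordinates stacked, (n, 3)."""
        return np.concatenate([p.coords for ps in self.pose_sets
                               for p in ps.poses])

    @property
    def point_scores(self) -> np.ndarray:
        """Per atom, the docking score of the pose it belongs to."""
        return np.concatenate([np.full(len(p.coords), p.score)
                               for ps in self.pose_sets for p in ps.poses])

    def fit(self, seed: int | None = None) -> "BindingSiteResults":
        """Train the SOM, threshold the U-matrix and extract ranked clusters."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        points = self.points

        frame = _som.pca_frame(points)
        dims = _som.map_dims(frame.lengths, cfg.som_target_size)
        som = _som.init_som(frame, dims)
        _som.train(som, points, cfg.schedule, seed=seed, kernel=cfg.kernel)

        umatrix = _cons.compute_umatrix(som)
        umatrix.t_u, umatrix.gmm_summary = _cons.fit_gmm_threshold(
            umatrix.values.ravel(), cfg.gmm_max_components, seed=seed)
        ccs = _cons.extract_ccs(umatrix, som)
        for cc in ccs:
            try:
                _cons.compute_rcc(cc, som, seed=seed)
            except ValueError:
                cc.r_cc = None        # single-neuron CC: unusable for precision

        grid = None
        if self.receptor is not None:
            grid = _cav.detect_cavities(self.receptor, cfg.probe, cfg.bulk_probe,
                                        cfg.spacing, cfg.min_voxels)
        evaluation = None
        if self.reference_ligand is not None:
            usable = [c for c in ccs if c.r_cc is not None]
            evaluation = _cons.evaluate_target(
                usable, som, self.reference_ligand,
                precision_threshold=cfg.precision_threshold,
                radius_mode=cfg.radius_mode, atom_mode=cfg.atom_mode, seed=seed)

        qe = _som.quantization_errors(som, points)
        return BindingSiteResults(self, som, umatrix, ccs, qe,
                                  cavity_grid=grid, evaluation=evaluation,
                                  seed=seed)


@dataclass
class BindingSiteResults:
    """Fitted binding-site model: SOM, U-matrix, ranked consensual clusters."""

    model: BindingSiteModel
    som: _som.SOMap
    umatrix: _cons.UMatrix
    ccs: list[_cons.ConsensualCluster]
    quantization: np.ndarray = field(repr=False)
    cavity_grid: _cav.CavityGrid | None = None
    evaluation: _cons.TargetEvaluation | None = None
    seed: int = 0

    # ------------------------------------------------------------------
    def cc_cavity_id(self, cc: _cons.ConsensualCluster) -> int | None:
        """Cavity holding the cluster: most common cavity label among member
        neurons (ties to the smaller id), None without receptor or match."""
        if self.cavity_grid is None:
            return None
        hits = [_cav.neuron_in_cavity(p, self.cavity_grid)
                for p in cc.neuron_coords(self.som)]
        hits = [h for h in hits if h is not None]
        if not hits:
            return None
        ids, counts = np.unique(hits, return_counts=True)
        return int(ids[np.lexsort((ids, -counts))[0]])

    def neuron_mean_scores(self) -> np.ndarray:
        """Per neuron, mean docking score of the pose atoms mapping it
        (NaN for neurons that attract no atom)."""
        best = _som.bmu_indices(self.som, self.model.points)
        scores = self.model.point_scores
        out = np.full(self.som.n_neurons, np.nan)
        sums = np.bincount(best, weights=scores, minlength=self.som.n_neurons)
        counts = np.bincount(best, minlength=self.som.n_neurons)
        nz = counts > 0
        out[nz] = sums[nz] / counts[nz]
        return out

    def neuron_densities(self) -> dict[int, float]:
        """Neurons-per-Å³ for every detected cavity."""
        if self.cavity_grid is None:
            return {}
        return {c.id: _cav.neuron_density(self.som, c, self.cavity_grid)
                for c in self.cavity_grid.cavities}

    # ------------------------------------------------------------------
    def cc_table(self) -> list[dict]:
        rows = []
        for cc in self.ccs:
            rows.append({
                "rank": cc.rank,
                "n_neurons": cc.count,
                "r_cc": None if cc.r_cc is None else round(float(cc.r_cc), 6),
                "centroid": [round(float(v), 6) for v in cc.centroid],
                "mean_u": round(float(cc.mean_u), 6),
                "cavity_id": self.cc_cavity_id(cc),
            })
        return rows

    def to_report(self) -> dict:
        """Machine-readable report; deterministic for a given seed and data."""
        rep = {
            "config": self.model.config.to_dict(),
            "seed": self.seed,
            "n_points": int(len(self.quantization)),
            "map_dims": list(self.som.dims),
            "quantization_mean": round(float(self.quantization.mean()), 6),
            "quantization_sd": round(float(self.quantization.std()), 6),
            "t_u": round(float(self.umatrix.t_u), 6),
            "gmm": self.umatrix.gmm_summary,
            "n_ccs": len(self.ccs),
            "ccs": self.cc_table(),
        }
        if self.cavity_grid is not None:
            rep["cavities"] = self.cavity_grid.to_table()
            rep["neuron_densities"] = {
                str(k): round(v, 6) for k, v in self.neuron_densities().items()}
        if self.evaluation is not None:
            rep["evaluation"] = self.evaluation.to_dict()
        return rep

    def write_report(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2,
                                         sort_keys=True) + "\n")

    def write_neuron_pdb(self, path, values: str = "umatrix") -> None:
        """Neuron pseudo-atom PDB coloured by U-value or mean docking score."""
        from .structures import write_neuron_pdb

        if values == "umatrix":
            v = self.umatrix.values.ravel()
        elif values == "score":
            v = np.nan_to_num(self.neuron_mean_scores(), nan=0.0)
        else:
            raise ValueError("values must be 'umatrix' or 'score'")
        write_neuron_pdb(self.som, v, path)

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        q = self.quantization
        lines = [
            "Binding-site consensus analysis",
            "=" * 47,
            f"input atoms:          {len(q)}",
            f"map dimensions:       {self.som.dims}  "
            f"({self.som.n_neurons} neurons)",
            f"quantization error:   {q.mean():.3f} ± {q.std():.3f} Å",
            f"U-value threshold:    {self.umatrix.t_u:.4f} Å  "
            f"(GMM, {self.umatrix.gmm_summary['n_components']} components)",
            f"consensual clusters:  {len(self.ccs)}",
            "",
            f"{'rank':>4} {'neurons':>8} {'r_CC (Å)':>9} {'cavity':>7}  centroid (Å)",
        ]
        for row in self.cc_table():
            r = "-" if row["r_cc"] is None else f"{row['r_cc']:.3f}"
            cav = "-" if row["cavity_id"] is None else str(row["cavity_id"])
            c = ", ".join(f"{v:7.2f}" for v in row["centroid"])
            lines.append(f"{row['rank']:>4} {row['n_neurons']:>8} {r:>9} "
                         f"{cav:>7}  [{c}]")
        if self.evaluation is not None:
            e = self.evaluation
            hit = "-" if e.hit_rank is None else str(e.hit_rank)
            lines += [
                "",
                f"evaluation (threshold {e.precision_threshold}, "
                f"radius {e.radius_mode}, atoms {e.atom_mode}):",
                f"  hit CC rank: {hit}   Top1: {e.top1}   Top3: {e.top3}",
            ]
        return "\n".join(lines)
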