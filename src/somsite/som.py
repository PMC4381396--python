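"""3D non-periodic Kohonen self-organizing map over atomic coordinates.

The map is a rectangular (I, J, K) lattice of neurons, each carrying a 3D
coordinate in Å.  Its dimensions are set approximately proportional to the
principal-component lengths of the input cloud with a product close to a
target size (15³ by default), and the lattice is initialised regularly
spaced along the principal axes over the projection range of the data.

Training runs in two phases of exponentially decaying neighbourhood radius
r and learning rate α; within a phase at step t,

    r_t = (r0 − rf) · exp(−t / λ) + rf,      λ = (cycles · n) / 10,

and likewise for α.  Each cycle presents every input vector once in a
seeded random order; after each presentation the best-matching unit (BMU)
is found by Euclidean distance and every neuron w is pulled toward the
input x by α_t · h · (x − w), where the neighbourhood factor h is a
Gaussian exp(−d²/(2 r_t²)) of the lattice-index distance d to the BMU
(optionally a hard cutoff d ≤ r_t).  Phase defaults: one cycle at
((7.5, 3.75), (1, 0.5)) then ten cycles at ((3.75, 1), (0.5, 0.1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PCAFrame",
    "Phase",
    "TrainingSchedule",
    "SOMap",
    "pca_frame",
    "map_dims",
    "init_som",
    "train",
    "bmu",
    "bmu_indices",
    "quantization_errors",
]


@dataclass
class PCAFrame:
    """Principal axes of a point cloud: mean, orthonormal components (rows),
    lengths (sqrt eigenvalues) and per-component projection extrema."""

    mean: np.ndarray          # (3,)
    components: np.ndarray    # (3, 3), rows V1, V2, V3
    lengths: np.ndarray       # (3,), S1 >= S2 >= S3 >= 0
    vmin: np.ndarray          # (3,) min projection of centred points on V_i
    vmax: np.ndarray          # (3,)


@dataclass
class Phase:
    cycles: int
    r0: float
    rf: float
    alpha0: float
    alphaf: float

    def __post_init__(self) -> None:
        if not (self.r0 >= self.rf > 0):
            raise ValueError("need r0 >= rf > 0")
        if not (self.alpha0 >= self.alphaf > 0):
            raise ValueError("need alpha0 >= alphaf > 0")


@dataclass
class TrainingSchedule:
    phases: list[Phase] = field(default_factory=lambda: [
        Phase(1, 7.5, 3.75, 1.0, 0.5),
        Phase(10, 3.75, 1.0, 0.5, 0.1),
    ])


@dataclass
class SOMap:
    dims: tuple[int, int, int]
    neurons: np.ndarray       # (I, J, K, 3) Å
    trained: bool = False
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return int(np.prod(self.dims))

    def flat(self) -> np.ndarray:
        """Neurons as an (N, 3) array in C order (k fastest)."""
        return self.neurons.reshape(-1, 3)

    def index_coords(self) -> np.ndarray:
        """Lattice indices of every neuron, (N, 3), matching :meth:`flat` order."""
        I, J, K = self.dims
        return np.stack(np.meshgrid(np.arange(I), np.arange(J), np.arange(K),
                                    indexing="ij"), axis=-1).reshape(-1, 3)

    def to_dict(self) -> dict:
        return {"dims": list(self.dims), "seed": self.seed, "trained": self.trained,
                "neurons": self.flat().tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SOMap":
        dims = tuple(d["dims"])
        neurons = np.asarray(d["neurons"], dtype=float).reshape(*dims, 3)
        return cls(dims, neurons, trained=d.get("trained", False), seed=d.get("seed"))


def pca_frame(points: np.ndarray) -> PCAFrame:
    """Principal component analysis of a 3D point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points to orient a map")
    mean = pts.mean(axis=0)
    centred = pts - mean
    cov = centred.T @ centred / max(len(pts) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    comps = evecs.T
    # fix the sign convention so the frame is deterministic
    for i in range(3):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    proj = centred @ comps.T
    return PCAFrame(mean, comps, np.sqrt(evals), proj.min(axis=0), proj.max(axis=0))


def map_dims(S, target_size: int = 3375) -> tuple[int, int, int]:
    """Lattice dimensions proportional to the PCA lengths with product close
    to ``target_size`` (15³ by default); zero lengths are floored at S1/100
    and every dimension at 2."""
    S = np.asarray(S, dtype=float).copy()
    if np.all(S <= 0):
        raise ValueError("all PCA lengths are zero")
    S = np.maximum(S, S.max() / 100.0)
    c = (target_size / np.prod(S)) ** (1.0 / 3.0)
    return tuple(max(2, int(np.round(c * s))) for s in S)


def init_som(frame: PCAFrame, dims: tuple[int, int, int]) -> SOMap:
    """Regular lattice spanning the projection range along each principal axis."""
    I, J, K = dims
    neurons = np.empty((I, J, K, 3), dtype=float)
    offsets = []
    for d, n in zip(range(3), dims):
        idx = np.arange(n)
        offsets.append(frame.vmin[d] + idx * (frame.vmax[d] - frame.vmin[d]) / n)
    for i in range(I):
        for j in range(J):
            for k in range(K):
                neurons[i, j, k] = (frame.mean
                                    + offsets[0][i] * frame.components[0]
                                    + offsets[1][j] * frame.components[1]
                                    + offsets[2][k] * frame.components[2])
    return SOMap(dims, neurons)


def train(
    som: SOMap,
    points: np.ndarray,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    *,
    kernel: str = "gaussian",
) -> SOMap:
    """Train the map in place and return it.

    ``kernel="gaussian"`` (default) updates all neurons with a Gaussian
    neighbourhood factor; ``kernel="cutoff"`` updates only neurons within the
    current radius (hard step).  Same seed and inputs give bit-identical maps.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite input point")
    if kernel not in ("gaussian", "cutoff"):
        raise ValueError(f"unknown kernel {kernel!r}")
    schedule = schedule or TrainingSchedule()
    rng = np.random.default_rng(seed)

    flat = som.neurons.reshape(-1, 3)
    idx = som.index_coords().astype(float)
    n = len(pts)
    for phase in schedule.phases:
        lam = (phase.cycles * n) / 10.0
        t = 0
        for _cycle in range(phase.cycles):
            for p in rng.permutation(n):
                decay = np.exp(-t / lam)
                r = (phase.r0 - phase.rf) * decay + phase.rf
                alpha = (phase.alpha0 - phase.alphaf) * decay + phase.alphaf
                x = pts[p]
                diff = x - flat
                best = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                d2 = np.einsum("ij,ij->i", idx - idx[best], idx - idx[best])
                if kernel == "gaussian":
                    h = np.exp(-d2 / (2.0 * r * r))
                else:
                    h = (d2 <= r * r).astype(float)
                flat += (alpha * h)[:, None] * diff
                t += 1
    som.trained = True
    som.seed = seed
    return som


def bmu(som: SOMap, point) -> tuple[int, int, int]:
    """Index (i, j, k) of the neuron nearest the point; ties break to the
    smallest flat index (k fastest)."""
    diff = np.asarray(point, dtype=float) - som.flat()
    best = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
    return tuple(int(v) for v in np.unravel_index(best, som.dims))


def bmu_indices(som: SOMap, points: np.ndarray) -> np.ndarray:
    """Flat BMU index for every point (vectorised, chunked)."""
    pts = np.asarray(points, dtype=float)
    flat = som.flat()
    out = np.empty(len(pts), dtype=np.int64)
    step = max(1, 2_000_000 // max(len(flat), 1))
    for s in range(0, len(pts), step):
        chunk = pts[s:s + step]
        d2 = ((chunk[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
        out[s:s + step] = np.argmin(d2, axis=1)
    return out


def quantization_errors(som: SOMap, points: np.ndarray) -> np.ndarray:
    """Euclidean distance of each input to its BMU (the map's acuity)."""
    if not som.trained:
        raise ValueError("SOM must be trained")
    pts = np.asarray(points, dtype=float)
    flat = som.flat()
    best = bmu_indices(som, pts)
    return np.linalg.norm(pts - flat[best], axis=1)
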