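"""Run configuration shared by the model facade and the CLI.

Defaults are the method's published operating point: 0.5 Å grid, 1.4 Å
solvent probe, 10 Å bulk probe, 96-voxel cavity floor, 15³ target map size,
two-phase training schedule, 0.25 precision threshold, adaptive r_CC radius.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .som import TrainingSchedule


@dataclass
class RunConfig:
    spacing: float = 0.5              # grid spacing, Å
    probe: float = 1.4                # solvent probe radius, Å
    bulk_probe: float = 10.0          # bulk solvent probe radius, Å
    min_voxels: int = 96              # cavity size floor (12 Å³ at 0.5 Å)
    som_target_size: int = 3375       # target neuron count, 15³
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    kernel: str = "gaussian"          # neighbourhood kernel: gaussian | cutoff
    gmm_max_components: int = 10
    precision_threshold: float = 0.25
    radius_mode: str = "rcc"          # rcc | 1.6 | 2.0
    atom_mode: str = "all"            # all | heavy
    n_randomizations: int = 1_000_000
    max_poses: int = 20
    heavy_only: bool = True           # heavy atoms only as SOM input
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = [vars(p) for p in self.schedule.phases]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .som import Phase

        d = dict(d)
        if "schedule" in d and not isinstance(d["schedule"], TrainingSchedule):
            d["schedule"] = TrainingSchedule([Phase(**p) for p in d["schedule"]])
        return cls(**d)

    def validate(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.bulk_probe <= self.probe:
            raise ValueError("bulk_probe must exceed probe")
        if self.radius_mode not in ("rcc",) and float(self.radius_mode) <= 0:
            raise ValueError("radius_mode must be 'rcc' or a positive radius")
        if self.atom_mode not in ("all", "heavy"):
            raise ValueError("atom_mode must be 'all' or 'heavy'")
        if not 0 <= self.precision_threshold <= 1:
            raise ValueError("precision_threshold must lie in [0, 1]")
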