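"""Pipeline configuration: one structured file drives every stage.

Every stochastic stage gets an explicit named seed; when not given, stage
seeds are derived deterministically from the scenario seed so a config is
always fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from hybridswarm.simswarm import ScenarioConfig

ALL_STAGES = ["simulate", "gl", "admixture", "carriers", "popstats",
              "tracts", "cpnet", "geostats"]

_SEED_OFFSETS = {"reads": 101, "thin": 211, "admixture": 307,
                 "window": 401, "geo": 503}


@dataclass
class PipelineConfig:
    outdir: Path
    scenario: dict = field(default_factory=dict)
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    k_global: int = 4
    k_window: int = 4
    n_reps: int = 5
    thin_bp: int = 5000
    alpha_lrt: float = 1e-6
    stats_window: int = 10_000
    tract_window: int = 50_000
    locus_window: int = 10_000
    min_sites_window: int = 10
    min_region_n: int = 10
    carrier_cutoff: float = 0.95
    admixed_cutoff: float = 0.20
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        for t in (self.carrier_cutoff, self.admixed_cutoff):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must be within [0, 1]")
        base = int(self.scenario.get("seed", 1))
        for name, off in _SEED_OFFSETS.items():
            self.seeds.setdefault(name, base + off)

    def scenario_config(self) -> ScenarioConfig:
        return ScenarioConfig(**self.scenario)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "scenario": self.scenario_config().to_dict(),
            "stages": list(self.stages),
            "k_global": self.k_global, "k_window": self.k_window,
            "n_reps": self.n_reps, "thin_bp": self.thin_bp,
            "alpha_lrt": self.alpha_lrt, "stats_window": self.stats_window,
            "tract_window": self.tract_window,
            "locus_window": self.locus_window,
            "min_sites_window": self.min_sites_window,
            "min_region_n": self.min_region_n,
            "carrier_cutoff": self.carrier_cutoff,
            "admixed_cutoff": self.admixed_cutoff,
            "seeds": dict(self.seeds),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
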