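"""Run configuration: a single YAML file drives the whole pipeline.

All randomness flows from the one ``seed`` here; every stochastic stage
derives its generator from it.  The after-ripening timepoint map defaults to
the assay schedule {TP1: 6, ..., TP7: 160} days post physiological maturity.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from phsmalt.simulate import TIMEPOINT_DAYS, SimConfig

ALL_STAGES = (
    "simulate",
    "germination",
    "partition",
    "blues",
    "correlations",
    "selection",
    "scoring",
)


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "results"
    timepoint_days: dict = field(default_factory=lambda: dict(TIMEPOINT_DAYS))
    stages: tuple = ALL_STAGES
    # analysis scope
    scan_traits: list = field(default_factory=lambda: ["FAN", "AA", "SP", "BG"])
    scan_timepoints: list = field(default_factory=lambda: ["TP1", "TP4", "TP6"])
    scan_groups: list = field(default_factory=lambda: ["ALL", "D", "N", "Nstar"])
    germ_trait: str = "GI"
    partition_traits: list | None = None  # None = every trait in the data
    selection_traits: list | None = None  # None = scan_traits
    scoring_config: str | None = None  # None = packaged illustrative config
    min_lines: int = 30
    n_starts: int = 3
    max_het: float = 0.10
    min_maf: float = 0.05
    # generator overrides (keys of SimConfig)
    sim: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        from phsmalt.simulate import AlleleCurve, TraitDef

        cfg = SimConfig()
        for k, v in self.sim.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown SimConfig field {k!r}")
            if k == "traits":
                v = {t: (TraitDef(**d) if isinstance(d, dict) else d) for t, d in v.items()}
            elif k == "allele_curves":
                v = {a: (AlleleCurve(**d) if isinstance(d, dict) else d) for a, d in v.items()}
            elif k in ("years", "germ_timepoints", "parent_alleles"):
                v = tuple(v)
            elif k == "malt_timepoints":
                v = {int(y): tuple(tps) for y, tps in v.items()}
            elif k == "cycle_sizes":
                v = {c: int(n) for c, n in v.items()}
            setattr(cfg, k, v)
        return cfg

    def digest(self) -> str:
        payload = yaml.safe_dump(_as_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run config; missing keys fall back to defaults."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.stages = tuple(cfg.stages)
    return cfg
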