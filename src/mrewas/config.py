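"""Run configuration: YAML parsing and fail-fast validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_subjects: int = 50
    n_probes: int = 1000
    maf677: float = 0.33
    maf1298: float = 0.23
    alpha0: float = 6.50
    alpha1: float = 0.12
    alpha2: float = 0.05
    alpha_c: float = 0.2
    sigma_x: float = 0.26
    p_planned: float = 0.5
    frac_sex: float = 0.105
    frac_cross_reactive: float = 0.036
    frac_missing: float = 0.015
    frac_distractor: float = 0.23
    n_signal_probes: int = 7
    signal_beta1: float = 0.4
    beta2: float = 0.02
    beta_c: float = 0.2
    sigma_y: float = 0.06
    with_intensities: bool = False


@dataclass
class InputConfig:
    cohort: str | None = None
    betas: str | None = None
    annotations: str | None = None
    gene2term: str | None = None


@dataclass
class PreprocessConfig:
    alpha: float = 0.05


@dataclass
class ScanConfig:
    alpha: float = 0.05
    bootstrap_reps: int = 1000
    multiplicity: bool = False


@dataclass
class ConfoundSimConfig:
    enabled: bool = True
    levels: tuple[float, ...] = (0.1, 0.2)
    n_reps: int = 10_000
    y_from_simulated_x: bool = False
    max_loci: int = 7


@dataclass
class EnrichConfig:
    enabled: bool = True
    n_terms: int = 40


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "mrewas_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    inputs: InputConfig = field(default_factory=InputConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    confound_sim: ConfoundSimConfig = field(default_factory=ConfoundSimConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for name, a in (("preprocess.alpha", self.preprocess.alpha),
                        ("scan.alpha", self.scan.alpha)):
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.scan.bootstrap_reps < 0:
            raise ValueError("scan.bootstrap_reps must be >= 0")
        if self.confound_sim.n_reps < 1:
            raise ValueError("confound_sim.n_reps must be >= 1")
        for lv in self.confound_sim.levels:
            if lv < 0:
                raise ValueError("confounding levels must be non-negative")
        if not self.simulate.enabled:
            for f in ("cohort", "betas", "annotations"):
                if getattr(self.inputs, f) is None:
                    raise ValueError(
                        f"simulate disabled but inputs.{f} not provided")


_SECTION_TYPES = {
    "simulate": SimulateConfig,
    "inputs": InputConfig,
    "preprocess": PreprocessConfig,
    "scan": ScanConfig,
    "confound_sim": ConfoundSimConfig,
    "enrich": EnrichConfig,
}


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from a YAML file or dict.

    Unknown keys are rejected so typos fail fast.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)

    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = set(cls.__dataclass_fields__)
            unknown = set(value) - valid
            if unknown:
                raise ValueError(
                    f"unknown key(s) in section {key!r}: {sorted(unknown)}")
            if key == "confound_sim" and "levels" in value:
                value = {**value, "levels": tuple(value["levels"])}
            kwargs[key] = cls(**value)
        elif key in ("seed", "out_dir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown top-level config key {key!r}")

    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg
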