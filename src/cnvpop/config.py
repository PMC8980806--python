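"""Run configuration: every tunable of the pipeline in one structured object
that round-trips losslessly through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .depth import DepthCallerParams
from .simulate import CallerProfile, CnvDesign, DEFAULT_PROFILES

__all__ = ["RunConfig", "GenomeParams", "DepthSimParams", "PopgenParams",
           "DegParams", "validate_config"]


@dataclass
class GenomeParams:
    n_chroms: int = 1
    chrom_len: int = 10_000_000
    masked_fraction: float = 0.10
    n_genes: int = 100


@dataclass
class DepthSimParams:
    mean_depth: float = 10.0
    window: int = 1000
    gc_bias_strength: float = 0.3
    dispersion: float = 0.05


@dataclass
class PopgenParams:
    top_fraction: float = 0.01
    vst_threshold: float = 0.4
    n_components: int = 4


@dataclass
class DegParams:
    padj_max: float = 0.01
    fc_min: float = 1.5
    dosage_r: float = -0.9


@dataclass
class ConsensusParams:
    min_del_length: int = 50
    min_support: int = 2
    min_reciprocal: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "cnvpop_out"
    genome: GenomeParams = field(default_factory=GenomeParams)
    design: CnvDesign = field(default_factory=CnvDesign)
    depth_sim: DepthSimParams = field(default_factory=DepthSimParams)
    caller: DepthCallerParams = field(default_factory=DepthCallerParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    popgen: PopgenParams = field(default_factory=PopgenParams)
    deg: DegParams = field(default_factory=DegParams)
    profiles: dict[str, CallerProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "genome" in kwargs:
            kwargs["genome"] = GenomeParams(**kwargs["genome"])
        if "design" in kwargs:
            d = dict(kwargs["design"])
            for key in ("length_range", "neutral_freq_range",
                        "domestication_length_range", "breed_specific_length_range"):
                if key in d and d[key] is not None:
                    d[key] = tuple(d[key])
            kwargs["design"] = CnvDesign(**d)
        if "depth_sim" in kwargs:
            kwargs["depth_sim"] = DepthSimParams(**kwargs["depth_sim"])
        if "caller" in kwargs:
            kwargs["caller"] = DepthCallerParams(**kwargs["caller"])
        if "consensus" in kwargs:
            kwargs["consensus"] = ConsensusParams(**kwargs["consensus"])
        if "popgen" in kwargs:
            kwargs["popgen"] = PopgenParams(**kwargs["popgen"])
        if "deg" in kwargs:
            kwargs["deg"] = DegParams(**kwargs["deg"])
        if "profiles" in kwargs:
            kwargs["profiles"] = {
                name: CallerProfile(**p) for name, p in kwargs["profiles"].items()
            }
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Return every violated invariant as a human-readable message
    (empty list means the configuration is valid)."""
    errors: list[str] = []
    if config.seed < 0:
        errors.append("seed must be non-negative")
    g = config.genome
    if g.n_chroms < 1:
        errors.append("genome.n_chroms must be >= 1")
    if not 0.0 <= g.masked_fraction < 0.5:
        errors.append("genome.masked_fraction must be in [0, 0.5)")
    if config.depth_sim.mean_depth <= 0:
        errors.append("depth_sim.mean_depth must be positive")
    if config.depth_sim.dispersion < 0:
        errors.append("depth_sim.dispersion must be non-negative")
    c = config.caller
    if c.min_hits > c.heptad:
        errors.append("caller.min_hits cannot exceed caller.heptad")
    if c.core_sd <= 0 or c.refine_sd <= 0:
        errors.append("caller thresholds must be positive")
    n_callers = len(config.profiles) + 1  # simulated callers + the rd caller
    if config.consensus.min_support > n_callers:
        errors.append(
            f"consensus.min_support={config.consensus.min_support} exceeds the "
            f"{n_callers} available callers"
        )
    if config.consensus.min_del_length < 1:
        errors.append("consensus.min_del_length must be >= 1")
    if not 0.0 < config.popgen.top_fraction <= 1.0:
        errors.append("popgen.top_fraction must be in (0, 1]")
    if not 0.0 <= config.popgen.vst_threshold <= 1.0:
        errors.append("popgen.vst_threshold must be in [0, 1]")
    if not 0.0 < config.deg.padj_max <= 1.0:
        errors.append("deg.padj_max must be in (0, 1]")
    if config.deg.fc_min <= 1.0:
        errors.append("deg.fc_min must exceed 1")
    if not -1.0 <= config.deg.dosage_r <= 1.0:
        errors.append("deg.dosage_r must be in [-1, 1]")
    d = config.design
    if min(d.length_range) < config.consensus.min_del_length:
        errors.append("design.length_range minimum is below the deletion length filter")
    return errors
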