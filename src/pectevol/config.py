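"""Pipeline configuration: YAML-backed, defaulted, unknown keys rejected."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import SimulationConfig
from .synteny import ChainParams

STAGES = (
    "simulate",
    "classify",
    "synteny",
    "retention",
    "kaks",
    "branchmodel",
    "ortho",
    "expression",
)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every numeric parameter of every stage, with defaults.

    ``stages`` lists the stages to run (dependency order is enforced by the
    runner); the simulation block carries the synthetic-genome conditions.
    """

    outdir: str = "pectevol_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # family classification
    domain_evalue_cutoff: float = 1e-4
    # collinearity chaining
    chain: ChainParams = field(default_factory=ChainParams)
    # molecular evolution
    substitution_rate: float = 1.5e-8
    ks_bin_width: float = 0.1
    branch_omega_background: float = 0.17
    branch_omega_foreground: float = 0.28
    branch_n_codons: int = 500
    branch_n_taxa: int = 6
    # ortholog clustering
    ortho_evalue_cutoff: float = 1e-5
    mcl_inflation: float = 1.5
    min_cluster_size: int = 4
    # expression
    fpkm_threshold: float = 10.0
    mean_normalized_threshold: float = 1.0
    # synthetic genome
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        # keep the simulation seed slaved to the pipeline seed
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in data and isinstance(data["simulation"], dict):
            sim_known = {f.name for f in fields(SimulationConfig)}
            sim_unknown = set(data["simulation"]) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
            data["simulation"] = SimulationConfig(**data["simulation"])
        if "chain" in data and isinstance(data["chain"], dict):
            chain_known = {f.name for f in fields(ChainParams)}
            chain_unknown = set(data["chain"]) - chain_known
            if chain_unknown:
                raise ConfigError(f"unknown chain keys: {sorted(chain_unknown)}")
            data["chain"] = ChainParams(**data["chain"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def header(self) -> str:
        """One-line parameter record stamped into every stage output."""
        sim = self.simulation
        return (
            f"# seed={self.seed} domain_cutoff={self.domain_evalue_cutoff:g} "
            f"match_score={self.chain.match_score} min_anchors={self.chain.min_anchors} "
            f"gap_score={self.chain.gap_score} block_evalue={self.chain.block_evalue_cutoff:g} "
            f"rate={self.substitution_rate:g} inflation={self.mcl_inflation:g} "
            f"n_genes={sim.n_genes} p_loss={','.join(f'{p:g}' for p in sim.p_loss)}"
        )
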