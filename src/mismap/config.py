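"""YAML-backed run configuration for the command-line pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionParams
from .errors import MismapError
from .qc import QCThresholds
from .segments import SignatureParams
from .simulate import SimConfig

__all__ = ["PopulationInput", "RunConfig", "load_run_config", "load_sim_config"]


@dataclass(frozen=True)
class PopulationInput:
    """One genotype panel: either a PLINK prefix or a VCF path."""

    label: str
    plink_prefix: str | None = None
    vcf: str | None = None

    def __post_init__(self) -> None:
        if bool(self.plink_prefix) == bool(self.vcf):
            raise MismapError(
                f"population {self.label!r}: give exactly one of plink_prefix / vcf"
            )


@dataclass
class RunConfig:
    populations: list[PopulationInput]
    agp_path: str
    out_dir: str
    qc: QCThresholds = field(default_factory=QCThresholds)
    detection: DetectionParams = field(default_factory=DetectionParams)
    signature: SignatureParams = field(default_factory=SignatureParams)
    relocation_seed: int = 0
    chromosomes: list[str] | None = None  # optional allow-list (e.g. autosomes)

    def validate_paths(self) -> None:
        missing = []
        for pop in self.populations:
            if pop.vcf and not Path(pop.vcf).exists():
                missing.append(pop.vcf)
            if pop.plink_prefix:
                for ext in (".bed", ".bim", ".fam"):
                    p = Path(pop.plink_prefix + ext)
                    if not p.exists():
                        missing.append(str(p))
        if not Path(self.agp_path).exists():
            missing.append(self.agp_path)
        if missing:
            raise MismapError("missing input file(s): " + ", ".join(missing))


def _sub(mapping: dict, cls):
    return cls(**mapping) if mapping else cls()


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        pops = [PopulationInput(**p) for p in raw["populations"]]
        cfg = RunConfig(
            populations=pops,
            agp_path=raw["agp_path"],
            out_dir=raw["out_dir"],
            qc=_sub(raw.get("qc", {}), QCThresholds),
            detection=_sub(raw.get("detection", {}), DetectionParams),
            signature=_sub(raw.get("signature", {}), SignatureParams),
            relocation_seed=int(raw.get("relocation_seed", 0)),
            chromosomes=raw.get("chromosomes"),
        )
    except (KeyError, TypeError) as exc:
        raise MismapError(f"bad run config {path}: {exc}") from exc
    return cfg


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return SimConfig(**raw)
    except TypeError as exc:
        raise MismapError(f"bad simulation config {path}: {exc}") from exc
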