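"""Pipeline configuration: every numeric rule of the method in one place.

Defaults reproduce the analysis conventions of the pipeline: 4.2 Å
framework-CDR window, 5.5 Å interfacial-contact cutoff, 2.7-3.3 Å
hydrogen-bond and 3.3-4.0 Å carbon-carbon windows, 10 Å no-interaction
bound, 5% relative-SASA NIS threshold, the residue polarity classes, the
linear dG coefficient set, the per-chain upper-hydrophobic-core position
sets and the conservative-substitution classes.  A YAML file can override
any subset; CLI flags override the file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import affinity, kabat, structure
from .errors import InputError


@dataclass
class PipelineConfig:
    analysis_cutoff: float = structure.ANALYSIS_CUTOFF
    ic_cutoff: float = affinity.IC_CUTOFF
    hbond_range: tuple[float, float] = structure.HBOND_RANGE
    hydrophobic_range: tuple[float, float] = structure.HYDROPHOBIC_RANGE
    no_interaction_beyond: float = structure.NO_INTERACTION_BEYOND
    nis_threshold: float = affinity.NIS_RELATIVE_SASA_THRESHOLD
    temperature: float = affinity.DEFAULT_TEMPERATURE
    contact_weight_threshold: int = structure.DEFAULT_CONTACT_WEIGHT_THRESHOLD
    residue_classes: dict = field(
        default_factory=lambda: dict(affinity.DEFAULT_RESIDUE_CLASSES)
    )
    dg_coefficients: dict = field(
        default_factory=lambda: dict(affinity.DEFAULT_DG_COEFFICIENTS)
    )
    upper_core: dict = field(
        default_factory=lambda: {
            ct: sorted(kabat.DEFAULT_UPPER_CORE[ct]) for ct in kabat.CHAIN_TYPES
        }
    )
    swap_classes: list = field(
        default_factory=lambda: ["KRH", "DE", "ST", "NQ", "LIVM", "FYW", "AG", "C", "P"]
    )
    germline_priors: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("analysis_cutoff", "ic_cutoff", "no_interaction_beyond", "temperature"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        lo, hi = self.hbond_range
        lo2, hi2 = self.hydrophobic_range
        if not (0 < lo <= hi and 0 < lo2 <= hi2):
            raise InputError("interaction windows must be positive and ordered")
        if hi > hi2:
            raise InputError("hydrogen-bond window must not extend past the hydrophobic window")
        missing = set(affinity.DEFAULT_DG_COEFFICIENTS) - set(self.dg_coefficients)
        if missing:
            raise InputError(f"dg_coefficients incomplete, missing {sorted(missing)}")
        covered = set("".join(aa for aa in self.residue_classes))
        if covered != set(kabat.AMINO_ACIDS):
            raise InputError("residue_classes must cover exactly the 20 canonical residues")
        return self

    def swap_class_sets(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(s) for s in self.swap_classes)

    def upper_core_set(self, chain_type: str) -> kabat.UpperCoreSet:
        return kabat.UpperCoreSet(chain_type, frozenset(self.upper_core[chain_type]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hbond_range"] = list(self.hbond_range)
        d["hydrophobic_range"] = list(self.hydrophobic_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise InputError(f"cannot read config {path}: {exc}") from None
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.hbond_range = tuple(cfg.hbond_range)  # type: ignore[assignment]
        cfg.hydrophobic_range = tuple(cfg.hydrophobic_range)  # type: ignore[assignment]
        return cfg.validate()

    def with_overrides(self, **overrides) -> "PipelineConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return self.from_dict(data)
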