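"""Pipeline configuration: one validated YAML file drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from lysoquant.diffexpr import DEPParams
from lysoquant.droplets import LDParams
from lysoquant.scoring import ScoringScheme

_TOP_KEYS = {
    "seed",
    "output_dir",
    "case_group",
    "control_group",
    "normalize",
    "dep_params",
    "scheme",
    "ld_params",
    "catalogs",
    "external_sets",
    "simulate",
}
_SIM_KEYS = {
    "n_proteins",
    "groups",
    "replicates_per_group",
    "frac_dep",
    "effect_log2",
    "noise_sigma_log2",
    "p_lyso",
    "sensitivity",
    "fpr",
}


@dataclass
class PipelineConfig:
    """Validated, serializable run configuration.

    ``catalogs`` maps criterion source name → catalog file path;
    ``external_sets`` maps external study name → gene-list file path
    (the CLN3/CLN6/CLN7/CLN11-style NCL datasets are user-provided or
    synthetic, never bundled).
    """

    seed: int = 0
    output_dir: str = "lysoquant_out"
    case_group: str = "case"
    control_group: str = "control"
    normalize: str = "median-scale"
    dep_params: DEPParams = field(default_factory=DEPParams)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    ld_params: LDParams = field(default_factory=LDParams)
    catalogs: dict[str, str] = field(default_factory=dict)
    external_sets: dict[str, str] = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "dep_params" in kwargs:
            kwargs["dep_params"] = DEPParams(**kwargs["dep_params"])
        if "scheme" in kwargs:
            kwargs["scheme"] = ScoringScheme.from_dict(kwargs["scheme"])
        if "ld_params" in kwargs:
            kwargs["ld_params"] = LDParams(**kwargs["ld_params"])
        if "simulate" in kwargs:
            bad = set(kwargs["simulate"]) - _SIM_KEYS
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = self.scheme.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
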