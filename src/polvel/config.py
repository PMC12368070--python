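"""Pipeline configuration: YAML schema, validation, defaults, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .sim import ConditionSpec, SamplingSpec, SpikeInSpec, default_spikeins


class ConfigError(ValueError):
    """Invalid configuration; message names the offending key path."""


_SCHEMA = {
    "seed": int,
    "outdir": str,
    "genome": {
        "n_genes": int,
        "length_min": int,
        "length_max": int,
        "intergenic_gap": int,
        "n_chroms": int,
        "genes_bed": str,          # alternative to synthetic genome
        "nontranscribed_bed": str,
    },
    "kinetics": {
        "initiation_rate": float,
        "velocity_kb_min": float,
    },
    "conditions": [{
        "name": str,
        "velocity_factor": float,
        "onset_time": float,
    }],
    "sampling": {
        "label_start": float,
        "label_duration": float,
        "replicates": int,
        "ttseq_depth_per_kb": float,
        "mnet_tags_per_pol": float,
        "chip_reads_per_pol_kb": float,
        "chip_background_per_kb": float,
        "fragment_min": int,
        "fragment_max": int,
        "library_scales": list,
        "warmup": float,
    },
    "spikeins": [{
        "spike_id": str,
        "length": int,
        "copies": float,
        "labeled": bool,
    }],
    "analysis": {
        "velocity_bin": int,
        "chip_bin": int,
        "rpk_threshold": float,
        "bootstrap_iters": int,
        "pseudo_count": float,
        "exclude_first": int,
        "n_body_bins": int,
        "flank_bp": int,
        "flank_bins": int,
        "heatmap_window_bp": int,
        "control": str,
    },
}


def _check_keys(node, schema, path: str) -> None:
    if isinstance(schema, dict):
        if not isinstance(node, dict):
            raise ConfigError(f"config key {path or '<root>'}: expected a mapping")
        for key, value in node.items():
            child = f"{path}.{key}" if path else key
            if key not in schema:
                raise ConfigError(f"unknown config key: {child}")
            _check_keys(value, schema[key], child)
    elif isinstance(schema, list):
        if not isinstance(node, list):
            raise ConfigError(f"config key {path}: expected a list")
        for i, item in enumerate(node):
            _check_keys(item, schema[0], f"{path}[{i}]")
    # leaves: numeric coercion is handled where values are consumed


_DEFAULTS = {
    "seed": 0,
    "outdir": "polvel_out",
    "genome": {"n_genes": 20, "length_min": 10_000, "length_max": 100_000,
               "intergenic_gap": 20_000, "n_chroms": 2},
    "kinetics": {"initiation_rate": 2.0, "velocity_kb_min": 2.0},
    "conditions": [
        {"name": "control", "velocity_factor": 1.0, "onset_time": 0.0},
        {"name": "depleted", "velocity_factor": 0.5, "onset_time": 0.0},
    ],
    "sampling": {},
    "spikeins": None,
    "analysis": {"velocity_bin": 50, "chip_bin": 500, "rpk_threshold": 10.0,
                 "bootstrap_iters": 10_000, "pseudo_count": 1.0,
                 "exclude_first": 1000, "n_body_bins": 100, "flank_bp": 2500,
                 "flank_bins": 50, "heatmap_window_bp": 100_000,
                 "control": "control"},
}


@dataclass
class PipelineConfig:
    """Validated configuration with the study defaults filled in.

    Defaults mirror the analysis constants: 50-bp velocity bins, 500-bp
    ChIP bins, RPK threshold 10, 10,000 bootstrap iterations, pseudo-count
    1, first-kilobase exclusion, 5-minute labeling pulse starting at 60
    minutes (one hour of depletion)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        _check_keys(self.raw, _SCHEMA, "")
        merged = json.loads(json.dumps(_DEFAULTS))
        for key, value in self.raw.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        self.data = merged
        for key, sub in (("analysis", "velocity_bin"), ("analysis", "chip_bin"),
                         ("analysis", "bootstrap_iters"), ("analysis", "rpk_threshold"),
                         ("analysis", "pseudo_count")):
            if self.data[key][sub] <= 0:
                raise ConfigError(f"config key {key}.{sub}: must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw=raw)

    # -- typed accessors ----------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def outdir(self) -> str:
        return str(self.data["outdir"])

    def conditions(self) -> list[ConditionSpec]:
        return [ConditionSpec(name=c["name"],
                              velocity_factor=float(c.get("velocity_factor", 1.0)),
                              onset_time=float(c.get("onset_time", 0.0)))
                for c in self.data["conditions"]]

    def sampling(self) -> SamplingSpec:
        return SamplingSpec(**{k: v for k, v in self.data["sampling"].items()})

    def spikeins(self) -> list[SpikeInSpec]:
        raw = self.data.get("spikeins")
        if not raw:
            return default_spikeins()
        return [SpikeInSpec(**s) for s in raw]

    @property
    def analysis(self) -> dict:
        return self.data["analysis"]

    @property
    def genome_spec(self) -> dict:
        return self.data["genome"]

    @property
    def kinetics_spec(self) -> dict:
        return self.data["kinetics"]

    def config_hash(self) -> str:
        # outdir and seed are excluded: the hash identifies the scientific
        # settings, the seed is printed separately in the provenance line
        hashed = {k: v for k, v in self.data.items() if k not in ("outdir", "seed")}
        blob = json.dumps(hashed, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def provenance(self, seed: int | None = None) -> str:
        s = self.seed if seed is None else seed
        return (f" polvel v{__version__}\n"
                f" config_hash={self.config_hash()} seed={s}")


def dump_default_yaml() -> str:
    return yaml.safe_dump(_DEFAULTS, sort_keys=False)
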