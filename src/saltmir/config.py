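"""Configuration objects shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

LIBRARIES = ("3dSL", "3dCKL", "3dSR", "3dCKR")
TREATED = {"3dSL": True, "3dCKL": False, "3dSR": True, "3dCKR": False}

#: default insert length mixture over 18-30 nt; 21 nt is the mode, 24 nt second
DEFAULT_LENGTH_MIXTURE = {
    18: 0.02, 19: 0.04, 20: 0.12, 21: 0.32, 22: 0.08, 23: 0.06, 24: 0.20,
    25: 0.05, 26: 0.04, 27: 0.03, 28: 0.02, 29: 0.01, 30: 0.01,
}

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCG"


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters for the synthetic genome + four-library read simulator."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_conserved_loci: int = 20
    n_novel_loci: int = 10
    n_ncrna_loci: int = 8
    n_exon_loci: int = 8
    n_repeat_loci: int = 4
    reads_per_library: int = 100_000
    length_mixture: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MIXTURE)
    )
    contamination_rates: dict[str, float] = field(
        default_factory=lambda: {
            "adapter_null": 0.02,
            "insert_null": 0.01,
            "polyA": 0.02,
            "low_quality": 0.02,
        }
    )
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.05
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    background_fraction: float = 0.35
    star_fraction: float = 0.15
    frac_5p_arm: float = 0.6
    min_len: int = 18
    max_len: int = 30

    def validate(self) -> "SimulationConfig":
        if abs(sum(self.length_mixture.values()) - 1.0) > 1e-9:
            raise ConfigError("length_mixture probabilities must sum to 1")
        if any(not (self.min_len <= l <= self.max_len) for l in self.length_mixture):
            raise ConfigError("length_mixture keys must lie in [min_len, max_len]")
        for name, r in self.contamination_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"contamination rate {name} outside [0,1]")
        if sum(self.contamination_rates.values()) >= 1.0:
            raise ConfigError("contamination rates must sum to < 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ConfigError("background_fraction outside [0,1)")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "length_mixture" in d:
            d["length_mixture"] = {int(k): float(v) for k, v in d["length_mixture"].items()}
        return cls(**d).validate()


@dataclass
class CleanParams:
    """Thresholds for read cleaning; defaults follow common sRNA practice."""

    min_len: int = 18
    max_len: int = 30
    adapter_k: int = 8
    min_mean_quality: float = 20.0
    max_n_bases: int = 2
    polya_fraction: float = 0.8
    polya_run: int = 10
    trim_adapter: bool = True


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
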