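"""Simulation configuration.

The default profile reproduces the divergence structure of a
hyper-heterozygous parthenogenetic diploid: two haplotype scaffold sets
separated by class-specific substitution densities (CDS 3.7%, intron 7.1%,
intergenic 5.6%, overall ~5.7%), short insertion/deletion events at 0.66%
per aligned base, and a small number of inversions and translocations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Fraction of allelic gene pairs with a deviant expression ratio
#: (2-10 fold); default matches 121 deviant pairs out of 7306.
DEFAULT_DEVIANT_FRACTION = 121 / 7306


@dataclass
class SimulationConfig:
    seed: int = 0
    ancestral_length: int = 500_000
    n_scaffolds: int = 2
    snv_rate_cds: float = 0.037
    snv_rate_intron: float = 0.071
    snv_rate_intergenic: float = 0.056
    indel_event_rate: float = 0.0066
    indel_length_geom_p: float = 0.35
    indel_max_length: int = 50
    n_inversions: int = 1
    n_translocations: int = 1
    inversion_size_range: tuple[int, int] = (2_000, 5_000)
    translocation_size_range: tuple[int, int] = (2_000, 5_000)
    n_genes: int = 100
    exons_per_gene_range: tuple[int, int] = (2, 6)
    cds_fraction: float = 0.25
    expression_log_mean: float = 5.0
    expression_log_sd: float = 1.0
    deviant_pair_fraction: float = DEFAULT_DEVIANT_FRACTION
    deviant_fold_range: tuple[float, float] = (2.0, 10.0)
    expression_poisson: bool = True
    read_length: int = 100
    coverage_per_haplotype: float = 30.0
    read_error_rate: float = 0.01
    est_tag_length: int = 300
    est_error_rate: float = 0.02
    est_families: int = 20
    est_family_size_range: tuple[int, int] = (2, 6)

    def validate(self) -> None:
        rates = {
            "snv_rate_cds": self.snv_rate_cds,
            "snv_rate_intron": self.snv_rate_intron,
            "snv_rate_intergenic": self.snv_rate_intergenic,
            "indel_event_rate": self.indel_event_rate,
            "read_error_rate": self.read_error_rate,
            "est_error_rate": self.est_error_rate,
            "deviant_pair_fraction": self.deviant_pair_fraction,
            "cds_fraction": self.cds_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ancestral_length <= 0:
            raise ValueError("ancestral_length must be positive")
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        max_event = 0
        if self.n_inversions > 0:
            max_event = max(max_event, self.inversion_size_range[1])
        if self.n_translocations > 0:
            max_event = max(max_event, self.translocation_size_range[1])
        if max_event and self.ancestral_length < 10 * max_event:
            raise ValueError(
                "ancestral_length must be at least 10x the largest "
                f"structural event size ({max_event} bp)"
            )
        if self.n_translocations > 0 and self.n_scaffolds < 2:
            raise ValueError("translocations need at least 2 scaffolds")
        if not 0.0 < self.indel_length_geom_p <= 1.0:
            raise ValueError("indel_length_geom_p must be in (0, 1]")
        for name in ("exons_per_gene_range", "est_family_size_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(data[f.name], list):
                data[f.name] = tuple(data[f.name])
        cfg = cls(**data)
        cfg.validate()
        return cfg


_STAGE_IDS = {
    "genome": 1,
    "expression": 2,
    "reads": 3,
    "est": 4,
    "fragmentation": 5,
}


def stage_rng(seed: int, stage: str):
    """One named, reproducible random substream per pipeline stage."""
    import numpy as np

    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])
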