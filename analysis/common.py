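"""Shared configuration for the numbered analysis scripts.

One deterministic simulated diploid serves as the study system for every
step; each script regenerates it from the same seed (generation is cheap)
so the scripts can be run independently and in any order after 01.
"""

from pathlib import Path

from hyperhet.config import SimulationConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"


def study_config() -> SimulationConfig:
    """The default divergence profile at a 300 kb desk scale."""
    return SimulationConfig(seed=2025, ancestral_length=300_000,
                            n_scaffolds=2, n_genes=60,
                            n_inversions=1, n_translocations=1)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
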