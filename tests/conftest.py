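"""Shared fixtures: small cached simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from hyperhet.config import SimulationConfig
from hyperhet.simulate import generate_truth


@pytest.fixture(scope="session")
def default_truth():
    """Default-profile diploid at reduced scale, with structural events."""
    cfg = SimulationConfig(seed=11, ancestral_length=150_000, n_scaffolds=2,
                           n_genes=30, n_inversions=1, n_translocations=1)
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def clean_truth():
    """Default divergence profile without structural events."""
    cfg = SimulationConfig(seed=12, ancestral_length=60_000, n_scaffolds=2,
                           n_genes=12, n_inversions=0, n_translocations=0)
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def snv_only_truth():
    """Uniform substitutions only: no indels, no structural events."""
    cfg = SimulationConfig(seed=13, ancestral_length=60_000, n_scaffolds=1,
                           snv_rate_cds=0.057, snv_rate_intron=0.057,
                           snv_rate_intergenic=0.057, indel_event_rate=0.0,
                           n_inversions=0, n_translocations=0, n_genes=0)
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def default_segments(default_truth):
    from hyperhet.pairing import pair_assembly

    scaffolds = {**default_truth.haplotype_a, **default_truth.haplotype_b}
    return pair_assembly(scaffolds)


@pytest.fixture(scope="session")
def clean_segments(clean_truth):
    from hyperhet.pairing import pair_assembly

    scaffolds = {**clean_truth.haplotype_a, **clean_truth.haplotype_b}
    return pair_assembly(scaffolds)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate(rng, seq: str, sub_rate: float = 0.0, indel_rate: float = 0.0,
           protect_ends: int = 0) -> str:
    """Independent substitutions and short indels, optionally leaving the
    ends untouched so that global and anchored alignments agree."""
    out = []
    bases = "ACGT"
    n = len(seq)
    i = 0
    while i < n:
        in_core = protect_ends <= i < n - protect_ends
        c = seq[i]
        if in_core and rng.random() < sub_rate:
            c = bases[(bases.index(c) + 1 + rng.integers(0, 3)) % 4]
        if in_core and rng.random() < indel_rate:
            length = int(rng.integers(1, 5))
            if rng.random() < 0.5:
                out.append(random_seq(rng, length))
                out.append(c)
            else:
                out.append(c)
                i += length  # delete the next bases
                i += 1
                continue
        out.append(c)
        i += 1
    return "".join(out)
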