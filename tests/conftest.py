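import numpy as np
import pytest

from ltrcensus import FamilySpec, gen_background, plant_families
from ltrcensus.synthgenome import _random_seq


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def random_seq():
    def make(length: int, seed: int = 0, gc: float = 0.5) -> str:
        return _random_seq(np.random.default_rng(seed), length, gc)

    return make


@pytest.fixture
def planted_genome():
    """Genome with one divergence-free planted full-length element
    (707 bp LTRs, 11,257 bp internal region) plus the truth ledger."""
    background = gen_background(50_000, 0.4, seed=42)
    spec = FamilySpec(
        "fam1", ltr_len=707, internal_len=11_257, n_full=1, n_solo=0, divergence=0.0
    )
    genome, truth = plant_families(background, [spec], seed=7)
    return genome, truth, spec
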