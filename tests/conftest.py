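import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from longamp.gene_model import GeneModel, Interval
from longamp.scenarios import tiny_gene
from longamp.synthetic import ldlr_like_gene

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random open reading frame: ATG, non-stop body, one stop."""
    sense = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS
    ]
    body = [sense[int(rng.integers(len(sense)))] for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    """Single-exon gene: 60 nt reference, exon 1..60, CDS 1..57."""
    rng = np.random.default_rng(42)
    cds = random_cds(rng, 19)  # 57 nt
    seq = cds + random_seq(rng, 3)
    return GeneModel(
        name="toy", reference=seq,
        exons=[Interval(0, 60)], cds_intervals=[Interval(0, 57)],
    )


@pytest.fixture(scope="session")
def two_exon_model() -> GeneModel:
    """Two exons; CDS intervals 1..30 and 41..70 (1-based), 10 nt intron."""
    rng = np.random.default_rng(43)
    cds = random_cds(rng, 20)  # 60 nt
    seq = cds[:30] + random_seq(rng, 10) + cds[30:] + random_seq(rng, 10)
    return GeneModel(
        name="toy2", reference=seq,
        exons=[Interval(0, 30), Interval(40, 75)],
        cds_intervals=[Interval(0, 30), Interval(40, 70)],
    )


@pytest.fixture(scope="session")
def ldlr():
    """Synthetic LDLR-like gene model and its 5-amplicon panel."""
    return ldlr_like_gene()


@pytest.fixture(scope="session")
def tiny():
    """Tiny single-amplicon gene for depth-driven experiments."""
    return tiny_gene()
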