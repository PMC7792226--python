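import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xfert import simdata
from xfert.annotate import TranscriptModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def tiny_config(**overrides) -> simdata.SimConfig:
    """A desk-toy population: two short chromosomes, elevated causal
    frequency so homozygotes exist at small census sizes."""
    base = dict(
        n_founder_boars=20,
        n_founder_sows=120,
        n_generations=3,
        n_markers_per_chrom=60,
        chrom_lengths={"1": 20_000_000, "X": 20_000_000},
        causal_chrom="X",
        causal_pos=5_000_000,
        causal_alt_freq=0.20,
        ld_block_len=2_000_000,
        case_label_error=1.0 / 3.0,
        case_detection=1.0,
        n_cases=6,
        n_controls=100,
        litter_size=6,
        seed=7,
    )
    base.update(overrides)
    return simdata.SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> simdata.SimConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_pop(tiny_cfg):
    return simdata.simulate_population(tiny_cfg)


def make_toy_transcript(strand: str = "+") -> TranscriptModel:
    """A 402-codon transcript whose codon 212 is CGA (Arg), split over two
    exons, so the C>T substitution at the codon's first base creates a
    premature TGA stop: p.R212X."""
    cds = "GCT" * 211 + "CGA" + "GCT" * 190 + "TAA"   # 402 codons + stop
    assert len(cds) == 1209
    exon1, exon2 = cds[:600], cds[600:]
    if strand == "+":
        return TranscriptModel("toy_tx", "X", "+",
                               [(101, 700), (801, 1409)], [exon1, exon2])
    # mirror construction on the minus strand of a 2000 bp contig
    rc = lambda s: s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    iv1 = (2000 - 1409 + 1, 2000 - 801 + 1)
    iv2 = (2000 - 700 + 1, 2000 - 101 + 1)
    return TranscriptModel("toy_tx_minus", "X", "-",
                           [iv1, iv2], [rc(exon2), rc(exon1)])


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    return make_toy_transcript("+")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_549)
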