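import numpy as np
import pytest

from pseudex.model import GeneContext, PseudoexonRecord
from pseudex.classify import ModelSet
from pseudex.sequences import SequenceSource
from pseudex.simulate import SimParams, generate_locus


@pytest.fixture
def plus_gene() -> GeneContext:
    """Toy + strand gene: exon1 [1000,1100) = c.1..100, exon2 [1200,1300)."""
    return GeneContext(
        gene_symbol="TOY",
        transcript_id="TOY_T1",
        chrom="chrT",
        strand="+",
        exons=[(1000, 1100), (1200, 1300)],
        cds_start_offset=0,
    )


@pytest.fixture
def minus_gene() -> GeneContext:
    """Mirror of plus_gene on the - strand (same cDNA lengths)."""
    return GeneContext(
        gene_symbol="YOT",
        transcript_id="YOT_T1",
        chrom="chrT",
        strand="-",
        exons=[(1200, 1300), (1000, 1100)],
        cds_start_offset=0,
    )


@pytest.fixture
def plus_pe(plus_gene) -> PseudoexonRecord:
    return PseudoexonRecord("TOY-1-1", plus_gene, 1, 5000, 5100)


@pytest.fixture
def models() -> ModelSet:
    return ModelSet.packaged()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def locus(rng):
    """One deterministic synthetic + strand locus with sequence access."""
    loc = generate_locus(SimParams(seed=11, strands=("+",)), rng, 0)
    return loc, SequenceSource({loc.chrom: loc.seq})


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
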