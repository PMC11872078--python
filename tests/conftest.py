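import pytest

from ampedit.locus_model import build_allele_set, build_transcript_model
from ampedit.synthetic_reads import demo_locus, demo_nickase_locus, demo_transcript_locus


@pytest.fixture(scope="session")
def het_locus():
    """Nuclease-mode heterozygous demo locus: (locus, mut, template)."""
    return demo_locus()


@pytest.fixture(scope="session")
def het_alleles(het_locus):
    locus, mut, template = het_locus
    return build_allele_set(locus, mut, template)


@pytest.fixture(scope="session")
def nickase_locus():
    return demo_nickase_locus()


@pytest.fixture(scope="session")
def nickase_alleles(nickase_locus):
    locus, mut, template = nickase_locus
    return build_allele_set(locus, mut, template)


@pytest.fixture(scope="session")
def transcript_setup():
    """(locus, mut, template, truncation, model) for the 3-exon demo gene."""
    locus, mut, template, truncation = demo_transcript_locus()
    model = build_transcript_model(locus, mut, template, truncation)
    return locus, mut, template, truncation, model
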