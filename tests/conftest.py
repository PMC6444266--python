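import pytest

from plastovar.io import find_quadripartite
from plastovar.simulate import default_config, simulate_quartet
from plastovar.variation import AlignmentSet


@pytest.fixture(scope="session")
def quartet():
    """One deterministic desk-scale quartet shared across the suite."""
    return simulate_quartet(default_config(seed=1))


@pytest.fixture(scope="session")
def quartet_alignment(quartet):
    return AlignmentSet(
        taxa=list(quartet.config.taxa),
        rows=[quartet.alignment[t] for t in quartet.config.taxa],
        reference_taxon=quartet.config.reference,
    )


@pytest.fixture(scope="session")
def quartet_structure(quartet):
    return find_quadripartite(quartet.reference, min_ir=1000)


GENBANK_TWO_EXON = """\
LOCUS       TESTREC                  100 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  synthetic two-exon fixture.
ACCESSION   TESTREC
FEATURES             Location/Qualifiers
     source          1..100
     CDS             join(10..20,40..60)
                     /gene="demo"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture()
def two_exon_genbank(tmp_path):
    path = tmp_path / "two_exon.gb"
    path.write_text(GENBANK_TWO_EXON)
    return path
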