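import numpy as np
import pytest

from mitocodon.genetic_code import load_genetic_code
from mitocodon.sequence_io import CodingSequence


@pytest.fixture(scope="session")
def code1():
    return load_genetic_code(1)


@pytest.fixture(scope="session")
def code5():
    return load_genetic_code(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_cds(seq, *, code, species="spX", compartment="mito", gene="COX1"):
    return CodingSequence(species, compartment, gene, seq, code)


@pytest.fixture(scope="session")
def random_small_genes(code1):
    """100 random small genes (stop-free codon strings) for oracle tests."""
    rng = np.random.default_rng(2024)
    sense = list(code1.sense_codons)
    genes = []
    for i in range(100):
        n = int(rng.integers(30, 120))
        seq = "".join(sense[j] for j in rng.integers(0, len(sense), n))
        genes.append(make_cds(seq, code=code1, gene=f"g{i}"))
    return genes


GENBANK_PLUS = """\
LOCUS       TESTREC                   18 bp    DNA     circular INV 01-JAN-2024
DEFINITION  synthetic test mitogenome fragment.
ACCESSION   TESTREC
VERSION     TESTREC.1
KEYWORDS    .
SOURCE      mitochondrion Testus wormus
  ORGANISM  Testus wormus
            Eukaryota.
FEATURES             Location/Qualifiers
     source          1..18
                     /organism="Testus wormus"
     CDS             1..9
                     /gene="ND1"
                     /transl_table=5
     CDS             complement(10..18)
                     /gene="cytb"
ORIGIN
        1 atgaaataat tatttcat
//
"""
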