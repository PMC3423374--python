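import warnings

import pytest

from twinmito.io import spliced_sequence
from twinmito.simulate import simulate_genome

warnings.filterwarnings("ignore", message=".*duplicated gene names.*")


@pytest.fixture(scope="session")
def sim_genome():
    genome, truth = simulate_genome(seed=3)
    return genome, truth


@pytest.fixture(scope="session")
def long_cds(sim_genome):
    """Spliced CDS of the longest simulated protein gene (>1 kb)."""
    genome, _ = sim_genome
    feat = max((f for f in genome.features if f.cls == "protein"),
               key=lambda f: f.length(len(genome)))
    return spliced_sequence(genome, feat)


MINIMAL_GENBANK = """\
LOCUS       TESTREC                  120 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  minimal test record.
ACCESSION   TESTREC
FEATURES             Location/Qualifiers
     CDS             1..90
                     /gene="cox1"
                     /transl_table=1
ORIGIN
        1 atggctgctg ctgctgctgc tgctgctgct gctgctgctg ctgctgctgc tgctgctgct
       61 gctgctgctg ctgctgctta aacgtacgta cgtacgtacg tacgtacgta cgtacgtacg
//
"""

WRAPPED_GENBANK = """\
LOCUS       WRAPREC                  150 bp    DNA     circular UNA 01-JAN-2000
DEFINITION  wrapping test record.
ACCESSION   WRAPREC
FEATURES             Location/Qualifiers
     CDS             join(100..150,1..30)
                     /gene="cob"
ORIGIN
        1 atggctgctg ctgctgctgc tgctgctgct acgtacgtac gtacgtacgt acgtacgtac
       61 gtacgtacgt acgtacgtac gtacgtacgt acgtacgtat gggctgctgc tgctgctgct
      121 gctgctgctg ctgctgctgc tgctgctgct
//
"""


@pytest.fixture
def minimal_gb(tmp_path):
    path = tmp_path / "minimal.gb"
    path.write_text(MINIMAL_GENBANK)
    return path


@pytest.fixture
def wrapped_gb(tmp_path):
    path = tmp_path / "wrapped.gb"
    path.write_text(WRAPPED_GENBANK)
    return path
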