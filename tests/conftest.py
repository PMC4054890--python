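import numpy as np
import pytest

from splicevar.esr_features import HexamerSet
from splicevar.fixtures import FixtureConfig, build_world, generate_reference
from splicevar.genomic_context import GeneModels, GenomeSequence, TranscriptModel

SMALL_CONFIG = FixtureConfig(
    seed=11,
    n_genes=30,
    n_sav=60,
    n_snv=80,
    n_unlabeled=30,
    n_mislabeled=2,
)


@pytest.fixture(scope="session")
def small_world():
    return build_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_reference(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("ref")
    return generate_reference(SMALL_CONFIG, outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _toy_contig():
    # one gene, three exons, canonical GT..AG introns, on the plus strand
    rng = np.random.default_rng(42)
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    exon1 = "G" + rand(28) + "CAG"
    exon2 = "G" + rand(38) + "CAG"
    exon3 = "G" + rand(30)
    intron1 = "GTAAGT" + rand(50) + "CTCTTTTCTTCCAG"
    intron2 = "GTAAGT" + rand(60) + "TTCTCTCTTTCCAG"
    lead, tail = rand(30), rand(25)
    seq = lead + exon1 + intron1 + exon2 + intron2 + exon3 + tail
    s1 = len(lead)
    e1 = s1 + len(exon1)
    s2 = e1 + len(intron1)
    e2 = s2 + len(exon2)
    s3 = e2 + len(intron2)
    e3 = s3 + len(exon3)
    return seq, ((s1, e1), (s2, e2), (s3, e3))


@pytest.fixture(scope="session")
def toy_locus():
    """(GenomeSequence, GeneModels) with one 3-exon plus-strand gene and a
    2-exon isoform missing the middle exon."""
    seq, exons = _toy_contig()
    genome = GenomeSequence({"chrT": seq})
    models = GeneModels()
    models.add(
        TranscriptModel(
            "txA", "geneT", "chrT", "+", exons, cds_start=exons[0][0], cds_end=exons[2][1]
        )
    )
    models.add(
        TranscriptModel(
            "txB", "geneT", "chrT", "+", (exons[0], exons[2]),
            cds_start=exons[0][0], cds_end=exons[2][1],
        )
    )
    return genome, models


@pytest.fixture(scope="session")
def simple_hexamers():
    return HexamerSet(frozenset({"AAAAAA"}), frozenset({"CCCCCC"}))
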