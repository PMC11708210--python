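import numpy as np
import pytest

from urscan.complexity import NullModel
from urscan.genomeannot import GeneModel
from urscan.simgen import make_fixture


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Full-size synthetic genome fixture (6+6 blocks of 25 kb, 48 genes)."""
    return make_fixture(tmp_path_factory.mktemp("fixture"), seed=3)


@pytest.fixture(scope="session")
def small_fixture_paths(tmp_path_factory):
    """Small fixture for pipeline smoke tests (4+4 blocks of 12.5 kb)."""
    return make_fixture(
        tmp_path_factory.mktemp("small_fixture"),
        seed=5,
        unique_blocks=4,
        repeat_blocks=4,
        block_length=12_500,
        genes_per_block=2,
    )


@pytest.fixture
def toy_null():
    """Hand-built null model with a known quantile structure."""
    return NullModel(
        me=3.0,
        null_cm=np.array([0.8, 0.9, 1.0, 1.05, 1.1]),
        window_length=10,
        step=1,
        total_length=1000,
        composition=np.full(4, 0.25),
        replicates=1,
    )


def make_gene(gene_id, chrom, strand, transcripts, protein_ids=()):
    return GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        transcripts=list(transcripts),
        protein_ids=list(protein_ids),
    )
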