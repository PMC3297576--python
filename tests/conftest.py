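import numpy as np
import pytest

from isletseq.annotation import GeneModel, Transcript, build_segments


@pytest.fixture
def two_isoform_gene():
    """The worked example: T1 = [0,100)+[200,300), T2 = [0,100)+[250,300)."""
    t1 = Transcript("T1", "G1", ((0, 100), (200, 300)))
    t2 = Transcript("T2", "G1", ((0, 100), (250, 300)))
    return GeneModel("G1", "chr1", "+", (t1, t2))


@pytest.fixture
def two_isoform_segments(two_isoform_gene):
    return build_segments(two_isoform_gene)


def random_gene(rng: np.random.Generator, gene_id: str = "G", max_tx: int = 3) -> GeneModel:
    """Small random gene model for property tests (exons on a 0..500 grid)."""
    n_tx = int(rng.integers(1, max_tx + 1))
    transcripts = []
    for k in range(n_tx):
        n_exons = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(np.arange(0, 500, 10), size=2 * n_exons, replace=False))
        exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons))
        transcripts.append(Transcript(f"{gene_id}.{k + 1}", gene_id, exons))
    return GeneModel(gene_id, "chr1", "+", tuple(transcripts))
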