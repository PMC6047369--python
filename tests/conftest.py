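import numpy as np
import pytest

from pscluster import ConflictGraph, SimilarityMatrix
from pscluster.graph import edge
from pscluster.instances import example_three_documents, synthetic_corpus


@pytest.fixture
def example_graph() -> ConflictGraph:
    """Triangle with blue a-b, b-c and black a-c: two clusters, one bridge."""
    return example_three_documents()


@pytest.fixture
def triangle() -> ConflictGraph:
    return ConflictGraph(
        nodes={"a", "b", "c"},
        black_edges={edge("a", "b"), edge("b", "c"), edge("a", "c")},
    )


@pytest.fixture
def two_block_matrix() -> SimilarityMatrix:
    """Planted structure: within-block similarity 0.9, cross-block 0.1."""
    ids = [f"d{i}" for i in range(8)]
    m = np.full((8, 8), 0.1)
    m[:4, :4] = 0.9
    m[4:, 4:] = 0.9
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(ids, m, normalized=True)


@pytest.fixture(scope="session")
def topic_corpus():
    return synthetic_corpus(
        k_topics=3, docs_per_topic=10, vocab_per_topic=10,
        keyword_overlap=0.0, seed=7,
    )
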