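import numpy as np
import pytest

from snsvd.io import ExpressionMatrix, GeneNetwork
from snsvd.graph import normalized_laplacian


@pytest.fixture
def tiny_expression_file(tmp_path):
    """3-gene x 2-sample TSV with one missing cell."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tsA\tsB\n"
        "g1\t1.5\t-2.0\n"
        "g2\t0.25\tNA\n"
        "g3\t3.0\t4.5\n"
    )
    return path


@pytest.fixture
def path_graph_4():
    """g1 - g2 - g3 - g4 (degrees 1, 2, 2, 1)."""
    return GeneNetwork(["g1", "g2", "g3", "g4"], {(0, 1), (1, 2), (2, 3)})


def random_network(p: int, edge_prob: float, rng: np.random.Generator) -> GeneNetwork:
    iu, ju = np.triu_indices(p, k=1)
    drawn = rng.random(iu.size) < edge_prob
    edges = {(int(a), int(b)) for a, b in zip(iu[drawn], ju[drawn])}
    return GeneNetwork([f"g{i + 1}" for i in range(p)], edges)


@pytest.fixture
def random_instance():
    """Factory: random X plus a random network and its Laplacian."""

    def make(p=30, n=20, edge_prob=0.2, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((p, n))
        net = random_network(p, edge_prob, rng)
        return X, net, normalized_laplacian(net), rng

    return make


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(42)
    values = rng.standard_normal((12, 8))
    return ExpressionMatrix(
        values,
        [f"g{i + 1}" for i in range(12)],
        [f"s{j + 1}" for j in range(8)],
    )
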