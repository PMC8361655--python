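import numpy as np
import pytest

from mirppin import ExpressionMatrix, MiRPPIN


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def two_group_matrix(rng):
    """200 features x 12 samples, 20 planted shifts (delta=2, sigma=0.5)."""
    n_feat, n_per = 200, 6
    values = rng.normal(8.0, 0.5, size=(n_feat, 2 * n_per))
    planted = list(range(20))
    for i in planted:
        values[i, :n_per] += 2.0
    sample_ids = [f"s{i}" for i in range(2 * n_per)]
    groups = {s: ("case" if i < n_per else "ctrl") for i, s in enumerate(sample_ids)}
    mat = ExpressionMatrix(
        feature_ids=[f"f{i}" for i in range(n_feat)],
        sample_ids=sample_ids,
        values=values,
        group_of=groups,
    )
    return mat, planted


def make_ppi_net(edges) -> MiRPPIN:
    """PPI-layer-only network from an undirected edge list."""
    norm = {(str(a), str(b)) if str(a) <= str(b) else (str(b), str(a)) for a, b in edges}
    return MiRPPIN(gene_nodes={g for e in norm for g in e}, ppi_edges=norm)


@pytest.fixture
def path_net():
    return make_ppi_net([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net():
    return make_ppi_net([("S", f"L{i}") for i in range(4)])
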