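import numpy as np
import pytest

from netcurv import WeightedNetwork, fixture


@pytest.fixture
def k3():
    return fixture("K3")


@pytest.fixture
def star13():
    return fixture("star13")


@pytest.fixture
def chorded_c4():
    return fixture("chorded_C4")


@pytest.fixture
def double_star():
    return fixture("double_star")


@pytest.fixture
def tiny_matrix(tmp_path):
    """3-node symmetric matrix file with 3 edges, plus labels file."""
    m = tmp_path / "m.txt"
    m.write_text("0 0.5 0.3\n0.5 0 0.45\n0.3 0.45 0\n")
    lab = tmp_path / "labels.txt"
    lab.write_text("A\nB\nC\n")
    return m, lab


def make_net(labels, edges):
    """Network from explicit weighted edge list."""
    labels = tuple(labels)
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    w = np.zeros((n, n))
    for u, v, wt in edges:
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = wt
    return WeightedNetwork(labels, w)
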