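import networkx as nx
import numpy as np
import pytest

from ecograph import EcoEvoParams
from ecograph.graphs import PopulationGraph, complete_graph, star_graph


@pytest.fixture(scope="session")
def small_graphs():
    """Five small connected graphs spanning regular and irregular shapes."""
    return {
        "complete6": complete_graph(6),
        "star6": star_graph(6),
        "path5": PopulationGraph(nx.path_graph(5)),
        "cycle6": PopulationGraph(nx.cycle_graph(6)),
        "lollipop7": PopulationGraph(nx.lollipop_graph(4, 3)),
    }


@pytest.fixture
def weak_params():
    return EcoEvoParams(N=100, s=-0.001, alpha=0.53)


@pytest.fixture
def strong_params():
    return EcoEvoParams(N=500, s=-0.01, alpha=0.8)


def dense_chain_fixation(params, start=1):
    """Independent oracle: dense absorbing solve of the 1-D count chain.

    Builds the well-mixed Bd transition matrix state by state and solves the
    absorption system directly, with no product formula.
    """
    from ecograph.ecology import fitness_table

    N = params.N
    f = fitness_table(params)
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = P[N, N] = 1.0
    for n in range(1, N):
        W = n * f[n] + (N - n)
        up = (n * f[n] / W) * (N - n) / (N - 1)
        dn = ((N - n) / W) * n / (N - 1)
        P[n, n + 1] = up
        P[n, n - 1] = dn
        P[n, n] = 1.0 - up - dn
    Q = P[1:N, 1:N]
    b = P[1:N, N]
    u = np.linalg.solve(np.eye(N - 1) - Q, b)
    return u[start - 1]
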