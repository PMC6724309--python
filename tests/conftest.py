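"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.optimize import minimize

from npa.network import TwoLayerNetwork, _from_edges


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive: explicit sums, generic optimizer)
# ---------------------------------------------------------------------------

def objective_sum(net: TwoLayerNetwork, f: dict, beta: dict) -> float:
    """The smoothing objective as an explicit sum over every edge of both layers."""
    vals = dict(f)
    vals.update(beta)
    total = 0.0
    for s, t, sg in net.backbone_edges:
        total += (vals[s] - sg * vals[t]) ** 2
    for s, g, sg in net.transcript_edges:
        total += (vals[s] - sg * vals[g]) ** 2
    return total


def npa_edge_sum(net: TwoLayerNetwork, f: dict) -> float:
    """The amplitude as the explicit edge average over backbone edges."""
    total = sum((f[s] + sg * f[t]) ** 2 for s, t, sg in net.backbone_edges)
    return total / len(net.backbone_edges)


def minimize_objective(net: TwoLayerNetwork, beta: dict) -> dict:
    """Generic numerical minimizer of the objective over the backbone values."""
    order = sorted(net.backbone_nodes)

    def fun(x):
        return objective_sum(net, dict(zip(order, x)), beta)

    res = minimize(fun, np.zeros(len(order)), method="BFGS", tol=1e-12)
    return dict(zip(order, res.x))


# ---------------------------------------------------------------------------
# Random instance factory
# ---------------------------------------------------------------------------

def random_instance(rng, n_backbone=None, n_genes=None):
    """Small random connected two-layer network plus a random contrast vector.

    3-8 backbone nodes, 5-30 genes, random +-1 signs everywhere; every
    backbone node is connected (random spanning tree plus extra edges) and
    at least 3 nodes carry transcript edges.
    """
    n = int(n_backbone or rng.integers(3, 9))
    m = int(n_genes or rng.integers(5, 31))
    nodes = [f"n{i}" for i in range(n)]
    genes = [f"g{j}" for j in range(m)]
    backbone = []
    for i in range(1, n):  # random spanning tree keeps things connected
        j = int(rng.integers(0, i))
        backbone.append((nodes[j], nodes[i], int(rng.choice([-1, 1]))))
    for _ in range(int(rng.integers(0, n))):
        i, j = rng.choice(n, size=2, replace=False)
        backbone.append((nodes[int(i)], nodes[int(j)], int(rng.choice([-1, 1]))))
    transcript = []
    owners = rng.choice(n, size=m)
    for j, i in enumerate(owners):
        transcript.append((nodes[int(i)], genes[j], int(rng.choice([-1, 1]))))
    net = _from_edges(backbone, transcript, name="rand", extra_backbone_nodes=nodes)
    beta = {g: float(b) for g, b in zip(genes, rng.normal(0, 1, size=m))}
    return net, beta


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_node_net():
    """Backbone a->b (+1), one +1 transcript edge per node."""
    return _from_edges(
        [("a", "b", 1)],
        [("a", "Ga", 1), ("b", "Gb", 1)],
        name="two-node",
    )
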