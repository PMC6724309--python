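"""Leading-node analysis: ranking, cross-contrast matrices, dense modules.

Two different backbone perturbation patterns can yield the same amplitude,
and functional layers can hold hundreds of nodes; the *leading nodes* — the
minimal prefix of the contribution ranking that accounts for a cutoff
fraction (default 80%) of the score — give the short list worth inspecting,
together with the direction (sign of the differential value) of each.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import TwoLayerNetwork

__all__ = [
    "LeadingNodeSet",
    "leading_nodes",
    "leading_node_matrix",
    "extract_module",
    "write_module",
]


@dataclass(frozen=True)
class LeadingNodeSet:
    """Ranked contribution decomposition of one scored network.

    ``nodes`` holds *all* backbone nodes sorted by decreasing contribution
    (ties broken lexicographically); ``leading`` is the shortest prefix whose
    cumulative contribution reaches ``cutoff * score`` (boundary inclusive).
    Negative contributions sort last and the prefix rule still terminates
    because the full cumulative sum equals the score.
    """

    nodes: tuple
    contributions: tuple
    cumulative_fraction: tuple
    cutoff: float
    n_leading: int
    directionality: dict

    @property
    def leading(self) -> tuple:
        return self.nodes[: self.n_leading]

    def ranks(self) -> dict:
        """1-based rank per node over the full ordering."""
        return {x: i + 1 for i, x in enumerate(self.nodes)}


def leading_nodes(result, cutoff: float = 0.8) -> LeadingNodeSet:
    """Minimal prefix of the contribution ranking covering ``cutoff`` of the score."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if result.score <= 0:
        raise ValueError(
            f"{result.network} / {result.contrast}: no perturbation to decompose"
        )
    order = sorted(result.contributions, key=lambda x: (-result.contributions[x], x))
    contribs = np.array([result.contributions[x] for x in order])
    cumfrac = np.cumsum(contribs) / result.score
    target = cutoff
    hit = np.nonzero(cumfrac >= target - 1e-12)[0]
    n_leading = int(hit[0]) + 1 if hit.size else len(order)
    return LeadingNodeSet(
        nodes=tuple(order),
        contributions=tuple(contribs),
        cumulative_fraction=tuple(cumfrac),
        cutoff=cutoff,
        n_leading=n_leading,
        directionality={x: float(np.sign(result.f[x])) for x in order},
    )


def leading_node_matrix(results, cutoff: float = 0.8) -> pd.DataFrame:
    """Signed-rank matrix (backbone nodes x contrasts) of leading nodes.

    Entries are ``rank * sign(f)`` where the node is leading for that
    contrast, 0 elsewhere.  All results must come from the same network.
    """
    results = list(results)
    if not results:
        raise ValueError("no results given")
    networks = {r.network for r in results}
    if len(networks) > 1:
        raise ValueError(f"results mix networks: {sorted(networks)}")
    nodes = sorted(results[0].f)
    mat = pd.DataFrame(
        0.0, index=nodes, columns=[r.contrast for r in results]
    )
    for r in results:
        ls = leading_nodes(r, cutoff=cutoff)
        ranks = ls.ranks()
        for x in ls.leading:
            mat.loc[x, r.contrast] = ranks[x] * ls.directionality[x]
    mat.index.name = "node"
    return mat


def extract_module(
    net: TwoLayerNetwork, results, size_penalty: float = 0.05
) -> nx.Graph:
    """Greedy seed-and-grow extraction of a leading-node-dense subgraph.

    Each backbone node is scored by its mean contribution *fraction* across
    contrasts minus ``size_penalty``.  Growth starts from the top-scoring
    node and repeatedly absorbs the best-scoring neighbour while doing so
    does not decrease the module total (nodes at exactly zero adjusted score
    are absorbed); with ``size_penalty = 0`` and nonnegative contributions
    this returns the seed's whole connected component.  The result is always
    connected in the backbone.
    """
    results = list(results)
    if not results:
        raise ValueError("no results given")
    scores = {x: 0.0 for x in net.backbone_nodes}
    for r in results:
        if r.score <= 0:
            continue
        for x, c in r.contributions.items():
            if x in scores:
                scores[x] += (c / r.score) / len(results)
    adj = {x: s - size_penalty for x, s in scores.items()}
    g = net.backbone_graph()
    seed = min(adj, key=lambda x: (-adj[x], x))
    module = {seed}
    while True:
        frontier = set()
        for x in module:
            frontier.update(g.neighbors(x))
        frontier -= module
        if not frontier:
            break
        best = min(frontier, key=lambda x: (-adj[x], x))
        if adj[best] < 0:
            break
        module.add(best)
    return g.subgraph(module).copy()


def write_module(net: TwoLayerNetwork, module: nx.Graph, path, graphml: bool = True):
    """Write a module's backbone edges as network-dialect TSV (+ GraphML).

    Only signed backbone edges with both endpoints inside the module are
    exported; the GraphML twin (``<path>.graphml``) is for graph viewers.
    """
    from pathlib import Path

    path = Path(path)
    keep = set(module.nodes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tsign\ttarget\tlayer\n")
        for s, t, sg in net.backbone_edges:
            if s in keep and t in keep:
                fh.write(f"{s}\t{sg}\t{t}\tfunctional\n")
    if graphml:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(keep))
        for s, t, sg in net.backbone_edges:
            if s in keep and t in keep:
                g.add_edge(s, t, sign=int(sg))
        nx.write_graphml(g, path.with_suffix(".graphml"))
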