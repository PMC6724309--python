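"""Two-layer causal networks: data model, I/O, filters, and Laplacian encoding.

A two-layer network couples a signed, directed *backbone* (the functional
layer: protein activities, transcription-factor activities, abundances) to a
*transcript layer* of genes via signed footprint edges.  The measured log2
fold-changes on the transcript layer act as boundary values from which the
backbone differential values are inferred by constrained least-squares
smoothing; the smoothing and the perturbation score are both quadratic forms
in sub-blocks of the signed Laplacian of the full two-layer graph, which
:func:`build_laplacian_blocks` assembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TwoLayerNetwork",
    "LaplacianBlocks",
    "NetworkFormatError",
    "read_network",
    "write_network",
    "prune_underrepresented",
    "restrict_to_scorable",
    "build_laplacian_blocks",
]

#: accepted sign tokens in the TSV dialect
_SIGN_TOKENS = {"1": 1, "+1": 1, "-1": -1, "increases": 1, "decreases": -1}
_LAYER_TOKENS = {"functional", "transcript"}


class NetworkFormatError(ValueError):
    """Raised when a network file or edge list violates the format contract."""


@dataclass(frozen=True)
class TwoLayerNetwork:
    """A signed, directed backbone plus its signed backbone->gene footprint.

    Parameters
    ----------
    backbone_nodes : frozenset of str
        Functional-layer entities.
    gene_nodes : frozenset of str
        Transcript-layer gene symbols; disjoint from the backbone.
    backbone_edges : tuple of (source, target, sign)
        Directed signed edges within the functional layer.  Parallel edges
        are allowed and summed term-by-term in the quadratic forms;
        self-loops are rejected.
    transcript_edges : tuple of (backbone node, gene, sign)
        Signed footprint edges from backbone nodes to genes.
    name : str
        Network label.
    family : str or None
        Optional family label used when aggregating several networks.
    """

    backbone_nodes: frozenset
    gene_nodes: frozenset
    backbone_edges: tuple
    transcript_edges: tuple
    name: str = "network"
    family: str | None = None

    def __post_init__(self):
        overlap = self.backbone_nodes & self.gene_nodes
        if overlap:
            raise NetworkFormatError(
                f"backbone and gene node sets overlap: {sorted(overlap)[:5]}"
            )
        for s, t, sg in self.backbone_edges:
            if sg not in (1, -1):
                raise NetworkFormatError(f"backbone edge {s}->{t} has sign {sg!r}")
            if s == t:
                raise NetworkFormatError(f"self-loop on backbone node {s!r}")
            if s not in self.backbone_nodes or t not in self.backbone_nodes:
                raise NetworkFormatError(
                    f"backbone edge {s}->{t} references undeclared node"
                )
        for s, g, sg in self.transcript_edges:
            if sg not in (1, -1):
                raise NetworkFormatError(f"transcript edge {s}->{g} has sign {sg!r}")
            if s not in self.backbone_nodes:
                raise NetworkFormatError(
                    f"transcript edge source {s!r} is not a backbone node"
                )
            if g not in self.gene_nodes:
                raise NetworkFormatError(
                    f"transcript edge target {g!r} is not a declared gene"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_backbone(self) -> int:
        return len(self.backbone_nodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_nodes)

    def footprint_counts(self) -> dict:
        """Number of transcript edges attached to each backbone node."""
        counts = {x: 0 for x in self.backbone_nodes}
        for s, _, _ in self.transcript_edges:
            counts[s] += 1
        return counts

    def backbone_digraph(self) -> nx.DiGraph:
        """Directed backbone graph (parallel edges collapsed; reachability only)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.backbone_nodes)
        g.add_edges_from((s, t) for s, t, _ in self.backbone_edges)
        return g

    def backbone_graph(self) -> nx.Graph:
        """Undirected backbone graph used for connectivity and module growth."""
        g = nx.Graph()
        g.add_nodes_from(self.backbone_nodes)
        g.add_edges_from((s, t) for s, t, _ in self.backbone_edges)
        return g


def _from_edges(
    backbone_edges: Iterable,
    transcript_edges: Iterable,
    name: str = "network",
    family: str | None = None,
    extra_backbone_nodes: Iterable = (),
) -> TwoLayerNetwork:
    backbone_edges = tuple(backbone_edges)
    transcript_edges = tuple(transcript_edges)
    bnodes = set(extra_backbone_nodes)
    for s, t, _ in backbone_edges:
        bnodes.add(s)
        bnodes.add(t)
    gnodes = set()
    for s, g, _ in transcript_edges:
        bnodes.add(s)
        gnodes.add(g)
    return TwoLayerNetwork(
        backbone_nodes=frozenset(bnodes),
        gene_nodes=frozenset(gnodes),
        backbone_edges=backbone_edges,
        transcript_edges=transcript_edges,
        name=name,
        family=family,
    )


# ---------------------------------------------------------------------------
# TSV dialect I/O
# ---------------------------------------------------------------------------

def read_network(path, format: str = "tsv") -> TwoLayerNetwork:
    """Read a two-layer network from the tab-separated edge-list dialect.

    The file is UTF-8, tab-separated, with a required header
    ``source  sign  target  layer``.  ``layer`` is ``functional`` or
    ``transcript``; signs are ``1``/``-1`` or the causal tokens
    ``increases``/``decreases``.  Lines starting with ``#`` are comments.
    An optional sidecar ``<path>.meta`` with ``key=value`` lines supplies
    ``name`` and ``family``; otherwise the file stem is used as the name.

    Duplicate identical edges are collapsed with a warning; exact parallel
    edges that differ in sign are kept (they are legitimate multi-edges).
    """
    if format != "tsv":
        raise ValueError(f"unsupported network format {format!r}")
    path = Path(path)
    backbone, transcript = [], []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if header != ["source", "sign", "target", "layer"]:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected header "
                        f"'source\\tsign\\ttarget\\tlayer', got {line!r}"
                    )
                continue
            if len(fields) != 4:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            source, sign_tok, target, layer = (f.strip() for f in fields)
            if sign_tok.lower() not in _SIGN_TOKENS:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown sign token {sign_tok!r}"
                )
            if layer.lower() not in _LAYER_TOKENS:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown layer tag {layer!r}"
                )
            sign = _SIGN_TOKENS[sign_tok.lower()]
            key = (source, target, sign, layer.lower())
            if key in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate edge {source}->{target} "
                    f"({layer}) deduplicated",
                    stacklevel=2,
                )
                continue
            seen.add(key)
            if layer.lower() == "functional":
                backbone.append((source, target, sign))
            else:
                transcript.append((source, target, sign))
    if not transcript:
        raise NetworkFormatError(f"{path}: network has no transcript layer")
    name, family = path.stem, None
    sidecar = path.with_name(path.name + ".meta")
    if sidecar.exists():
        for raw in sidecar.read_text(encoding="utf-8").splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#") or "=" not in raw:
                continue
            k, v = raw.split("=", 1)
            if k.strip() == "name":
                name = v.strip()
            elif k.strip() == "family":
                family = v.strip()
    return _from_edges(backbone, transcript, name=name, family=family)


def write_network(net: TwoLayerNetwork, path, write_meta: bool = True) -> None:
    """Write a network in the TSV edge-list dialect (plus ``.meta`` sidecar)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tsign\ttarget\tlayer\n")
        for s, t, sg in net.backbone_edges:
            fh.write(f"{s}\t{sg}\t{t}\tfunctional\n")
        for s, g, sg in net.transcript_edges:
            fh.write(f"{s}\t{sg}\t{g}\ttranscript\n")
    if write_meta:
        meta = [f"name={net.name}"]
        if net.family is not None:
            meta.append(f"family={net.family}")
        path.with_name(path.name + ".meta").write_text(
            "\n".join(meta) + "\n", encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def prune_underrepresented(
    net: TwoLayerNetwork, min_downstream: int = 5
) -> TwoLayerNetwork:
    """Strip the footprints of under-represented backbone nodes.

    A backbone node supported by fewer than ``min_downstream`` transcript
    edges (but at least one) has its entire footprint removed: a handful of
    downstream genes is too thin a readout to constrain the node.  Backbone
    edges and footprint-free nodes are untouched.
    """
    if min_downstream < 1:
        raise ValueError("min_downstream must be >= 1")
    counts = net.footprint_counts()
    drop = {x for x, c in counts.items() if 1 <= c < min_downstream}
    if not drop:
        return net
    kept = tuple(e for e in net.transcript_edges if e[0] not in drop)
    genes = frozenset(g for _, g, _ in kept)
    return replace(net, transcript_edges=kept, gene_nodes=genes)


def restrict_to_scorable(net: TwoLayerNetwork) -> TwoLayerNetwork:
    """Keep only backbone nodes constrained by some measured relative.

    A node is scorable when an ancestor or a descendant (itself included) in
    the directed backbone carries at least one transcript edge; a node with
    no directed path to or from any measured node has a differential value
    untethered to data and is removed together with its incident edges.
    Idempotent.
    """
    counts = net.footprint_counts()
    with_fp = {x for x, c in counts.items() if c > 0}
    dig = net.backbone_digraph()
    keep = set()
    for x in net.backbone_nodes:
        if x in with_fp:
            keep.add(x)
        elif (nx.ancestors(dig, x) | nx.descendants(dig, x)) & with_fp:
            keep.add(x)
    if not keep:
        raise NetworkFormatError(f"{net.name}: no scorable nodes")
    if keep == set(net.backbone_nodes):
        return net
    bedges = tuple(e for e in net.backbone_edges if e[0] in keep and e[1] in keep)
    tedges = tuple(e for e in net.transcript_edges if e[0] in keep)
    genes = frozenset(g for _, g, _ in tedges)
    return replace(
        net,
        backbone_nodes=frozenset(keep),
        gene_nodes=genes,
        backbone_edges=bedges,
        transcript_edges=tedges,
    )


# ---------------------------------------------------------------------------
# Laplacian blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LaplacianBlocks:
    """Signed-Laplacian sub-blocks of a two-layer network, in fixed order.

    With every edge treated as undirected, the full signed Laplacian ``L`` of
    the two-layer graph satisfies ``[f; beta]^T L [f; beta] =
    sum_{x->y} (f(x) - sigma(x->y) f(y))^2`` over all edges of both layers.
    ``L3`` is its backbone x backbone block and ``L2`` the backbone x gene
    coupling block, so the constrained minimiser is ``f = -L3^{-1} L2 beta``.
    ``Q`` is the *coherence* form over backbone edges only:
    ``f^T Q f = sum_{e in E} (f(e0) + sigma(e) f(e1))^2``, and the
    perturbation amplitude is ``f^T Q f / |E|``.

    Attributes
    ----------
    node_order, gene_order : tuple of str
        Lexicographic orders fixing row/column meaning.
    L3 : ndarray, (n, n)
        Symmetric; diagonal = total (backbone + transcript) degree.
    L2 : ndarray, (n, m)
        ``L2[x, g] = -sum of signs`` of transcript edges x->g.
    Q : ndarray, (n, n)
        Symmetric PSD; diagonal = backbone degree, off-diagonal = +sum of
        backbone edge signs.
    E_size : int
        Number of backbone edges (with multiplicity).
    transcript_degree : ndarray, (n,)
        Transcript-edge multiplicity per backbone node (``L3 = B + diag(td)``
        with ``B`` the backbone-only signed Laplacian; kept so permutation
        nulls can re-assemble ``L3`` cheaply).
    """

    node_order: tuple
    gene_order: tuple
    L3: np.ndarray
    L2: np.ndarray
    Q: np.ndarray
    E_size: int
    transcript_degree: np.ndarray = field(repr=False, default=None)

    @property
    def n_backbone(self) -> int:
        return len(self.node_order)

    def node_index(self) -> dict:
        return {x: i for i, x in enumerate(self.node_order)}

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_order)}


#: reciprocal condition number below which L3 is declared singular
RCOND_SINGULAR = 1e-12


def build_laplacian_blocks(net: TwoLayerNetwork) -> LaplacianBlocks:
    """Assemble ``L3``, ``L2`` and ``Q`` from a filtered network.

    Parallel edges are summed term-by-term: opposite-sign parallel edges
    cancel in off-diagonals while each still contributes to degrees and to
    ``E_size``.  Raises if the network has no backbone or transcript edges,
    or if ``L3`` is numerically singular (a backbone component with no path
    to the transcript layer), naming the offending components.
    """
    if not net.backbone_edges:
        raise NetworkFormatError(f"{net.name}: network has no backbone edges")
    if not net.transcript_edges:
        raise NetworkFormatError(f"{net.name}: network has no transcript edges")
    node_order = tuple(sorted(net.backbone_nodes))
    gene_order = tuple(sorted(net.gene_nodes))
    nidx = {x: i for i, x in enumerate(node_order)}
    gidx = {g: i for i, g in enumerate(gene_order)}
    n, m = len(node_order), len(gene_order)

    L3 = np.zeros((n, n))
    Q = np.zeros((n, n))
    for s, t, sg in net.backbone_edges:
        i, j = nidx[s], nidx[t]
        L3[i, i] += 1.0
        L3[j, j] += 1.0
        L3[i, j] -= sg
        L3[j, i] -= sg
        Q[i, i] += 1.0
        Q[j, j] += 1.0
        Q[i, j] += sg
        Q[j, i] += sg

    L2 = np.zeros((n, m))
    tdeg = np.zeros(n)
    for s, g, sg in net.transcript_edges:
        i = nidx[s]
        L2[i, gidx[g]] -= sg
        L3[i, i] += 1.0
        tdeg[i] += 1.0

    rcond = 1.0 / np.linalg.cond(L3, 1) if n > 0 else 0.0
    if not np.isfinite(rcond) or rcond < RCOND_SINGULAR:
        comps = [
            sorted(c)
            for c in nx.connected_components(net.backbone_graph())
            if not any(tdeg[nidx[x]] > 0 for x in c)
        ]
        raise NetworkFormatError(
            f"{net.name}: singular backbone Laplacian; components without "
            f"transcript support: {comps}"
        )
    return LaplacianBlocks(
        node_order=node_order,
        gene_order=gene_order,
        L3=L3,
        L2=L2,
        Q=Q,
        E_size=len(net.backbone_edges),
        transcript_degree=tdeg,
    )


def prepare_network(
    net: TwoLayerNetwork, min_downstream: int = 5
) -> TwoLayerNetwork:
    """Standard filter pipeline: footprint pruning, then scorability."""
    return restrict_to_scorable(prune_underrepresented(net, min_downstream))
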