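"""Synthetic two-layer networks and contrasts with planted perturbations.

The generator emulates the structure the scoring method expects: a
connected, signed, directed backbone whose nodes carry signed gene
footprints, plus expression contrasts in which a coherent backbone state of
amplitude ``a`` is propagated to the footprint genes (through the edge
signs) and corrupted with Gaussian noise.  ``amplitude = 0`` gives pure-null
contrasts for calibration; small noise at positive amplitude gives
recoverable planted signals with known ground truth ``f(x) = a * s(x)`` and
score ``4 a^2`` on sign-consistent backbones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Contrast
from .network import TwoLayerNetwork, _from_edges

__all__ = ["SynthConfig", "generate_network", "generate_contrast", "coherent_gauge"]


@dataclass
class SynthConfig:
    """Knobs of the generator.

    Defaults describe a small but realistic scoring problem: a 10-node
    connected backbone of moderate density with ~1/3 repressive edges, 80%
    of nodes carrying footprints of 5-20 genes (all surviving the
    five-downstream filter), 50 decoy genes outside the network, and 10%
    relative noise on the planted amplitude.
    """

    n_backbone: int = 10
    edge_density: float = 0.3
    neg_sign_prob: float = 0.3
    footprint_min: int = 5
    footprint_max: int = 20
    footprint_fraction: float = 0.8
    amplitude: float = 1.0
    noise_sd: float = 0.1
    n_genes_background: int = 50
    pseudo_n: int = 10
    seed: int = 0

    def validate(self):
        if self.n_backbone < 2:
            raise ValueError("n_backbone must be >= 2")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        for p, nm in (
            (self.neg_sign_prob, "neg_sign_prob"),
            (self.footprint_fraction, "footprint_fraction"),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")
        if not 1 <= self.footprint_min <= self.footprint_max:
            raise ValueError("need 1 <= footprint_min <= footprint_max")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        if self.n_genes_background < 0 or self.pseudo_n < 1:
            raise ValueError("n_genes_background >= 0 and pseudo_n >= 1 required")


def generate_network(cfg: SynthConfig) -> TwoLayerNetwork:
    """Connected random signed backbone plus per-node gene footprints.

    Backbone adjacency is Erdos-Renyi, rejected and resampled until
    connected (up to 100 tries); each accepted edge gets a uniform random
    orientation and a sign that is negative with probability
    ``neg_sign_prob``.  Footprint genes are distinct per node and across
    nodes.  Deterministic for a given seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_backbone
    nodes = [f"N{i:03d}" for i in range(n)]
    edges_idx = None
    for _ in range(100):
        upper = rng.random((n, n)) < cfg.edge_density
        cand = [(i, j) for i in range(n) for j in range(i + 1, n) if upper[i, j]]
        # connectivity check via union-find
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in cand:
            parent[find(i)] = find(j)
        if n > 0 and len({find(i) for i in range(n)}) == 1:
            edges_idx = cand
            break
    if edges_idx is None:
        raise ValueError(
            f"could not draw a connected backbone at density {cfg.edge_density} "
            f"after 100 tries"
        )
    backbone = []
    for i, j in edges_idx:
        if rng.random() < 0.5:
            i, j = j, i
        sign = -1 if rng.random() < cfg.neg_sign_prob else 1
        backbone.append((nodes[i], nodes[j], sign))

    n_fp = max(1, int(round(cfg.footprint_fraction * n)))
    fp_nodes = sorted(rng.choice(n, size=n_fp, replace=False))
    transcript = []
    gene_counter = 0
    for i in fp_nodes:
        k = int(rng.integers(cfg.footprint_min, cfg.footprint_max + 1))
        for _ in range(k):
            sign = -1 if rng.random() < cfg.neg_sign_prob else 1
            transcript.append((nodes[i], f"G{gene_counter:05d}", sign))
            gene_counter += 1
    return _from_edges(
        backbone,
        transcript,
        name=f"synth-{cfg.seed}",
        extra_backbone_nodes=nodes,
    )


def coherent_gauge(net: TwoLayerNetwork) -> tuple[dict, int]:
    """Best-effort coherent backbone state ``s: node -> {+1, -1}``.

    Propagates ``s(y) = sigma(x, y) * s(x)`` along a BFS spanning forest of
    the undirected backbone.  Returns the gauge and the number of
    *frustrated* edges (edges whose sign the gauge cannot satisfy); 0 means
    the backbone admits an exactly coherent state.
    """
    order = sorted(net.backbone_nodes)
    neigh = {x: [] for x in order}
    for s, t, sg in net.backbone_edges:
        neigh[s].append((t, sg))
        neigh[t].append((s, sg))
    gauge = {}
    for root in order:
        if root in gauge:
            continue
        gauge[root] = 1
        queue = [root]
        while queue:
            x = queue.pop(0)
            for y, sg in neigh[x]:
                if y not in gauge:
                    gauge[y] = sg * gauge[x]
                    queue.append(y)
    frustrated = sum(
        1 for s, t, sg in net.backbone_edges if gauge[t] != sg * gauge[s]
    )
    return gauge, frustrated


def generate_contrast(
    net: TwoLayerNetwork, cfg: SynthConfig, name: str | None = None
) -> Contrast:
    """Contrast with a coherent perturbation of amplitude ``a`` planted.

    A gene downstream of node ``x`` through an edge of sign ``sigma`` gets
    ``beta = a * s(x) * sigma + N(0, se^2)`` where ``s`` is the coherent
    gauge and ``se = noise_sd / sqrt(pseudo_n)`` is the standard error of a
    fold-change estimated from ``pseudo_n`` replicates with per-replicate
    noise ``noise_sd``; decoy genes get pure noise.  t-statistics are
    synthesised as ``beta / se``, so the reported uncertainty matches the
    injected estimation error and the delta-method CI is honestly
    calibrated against this generator.  ``amplitude = 0`` yields a null
    contrast.
    """
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 0x5EED]).generate_state(1)[0] % (2**31)
    )
    gauge, _ = coherent_gauge(net)
    a = cfg.amplitude
    se_true = max(cfg.noise_sd, 1e-9) / np.sqrt(cfg.pseudo_n)
    sd = cfg.noise_sd / np.sqrt(cfg.pseudo_n)
    beta, se = {}, {}
    for s, g, sg in sorted(net.transcript_edges):
        b = a * gauge[s] * sg + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        beta[g] = float(b)
        se[g] = float(se_true)
    for i in range(cfg.n_genes_background):
        g = f"BG{i:05d}"
        beta[g] = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        se[g] = float(se_true)
    # drop decoys that are exactly 0 with sd == 0: no derivable t-statistic
    if sd == 0:
        for g in [g for g, b in beta.items() if b == 0.0]:
            del beta[g]
            del se[g]
    if name is None:
        name = f"contrast-a{cfg.amplitude:g}-seed{cfg.seed}"
    return Contrast(name=name, beta=beta, se=se, provenance="synthetic")


def write_contrast(contrast: Contrast, path) -> None:
    """Write a contrast as the TSV table the loader expects."""
    import pandas as pd

    genes = sorted(contrast.beta)
    fc = np.array([contrast.beta[g] for g in genes])
    se = np.array([contrast.se.get(g, np.nan) for g in genes])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.isfinite(se) & (se > 0), fc / se, 0.0)
    pd.DataFrame({"nodeLabel": genes, "foldChange": fc, "t": t}).to_csv(
        path, sep="\t", index=False
    )
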