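"""Contrast handling, constrained smoothing, and perturbation scoring.

The measured log2 fold-changes ``beta`` on the transcript layer are treated
as fixed boundary values; the backbone differential values ``f`` minimise the
signed-smoothness objective ``sum_{x->y} (f(x) - sigma(x->y) f(y))^2`` over
all edges of both layers subject to ``f = beta`` on the genes.  The unique
minimiser is the linear map ``f = -L3^{-1} L2 beta``, after which the
network perturbation amplitude is the edge-averaged coherence quadratic form
``f^T Q f / |E|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .network import (
    LaplacianBlocks,
    TwoLayerNetwork,
    build_laplacian_blocks,
    prune_underrepresented,
    restrict_to_scorable,
)

__all__ = [
    "Contrast",
    "NpaResult",
    "load_contrasts",
    "match_contrast",
    "solve_differential_values",
    "compute_npa",
    "node_contributions",
]


@dataclass
class Contrast:
    """One treatment-vs-control comparison.

    ``beta`` maps gene symbol to log2 fold-change; ``se`` maps gene symbol to
    the standard error ``|foldChange / t|`` recovered from the reported t- or
    z-statistic.  Genes with ``t == 0`` (only legal when the fold-change is
    also 0) carry no ``se`` entry and are excluded from the variance of the
    confidence interval.
    """

    name: str
    beta: dict
    se: dict
    provenance: str = ""

    def __post_init__(self):
        missing = set(self.se) - set(self.beta)
        if missing:
            raise ValueError(f"se entries without beta: {sorted(missing)[:5]}")
        bad = {g: s for g, s in self.se.items() if not (np.isfinite(s) and s > 0)}
        if bad:
            raise ValueError(f"non-positive/non-finite se: {bad}")


def load_contrasts(path, aggregate_duplicates: str | None = None) -> list:
    """Load one or more contrasts from a TSV/CSV table.

    The table needs columns ``nodeLabel`` (gene symbol), ``foldChange``
    (log2) and ``t`` (t- or z-statistic); an optional ``contrast`` column
    turns a long-format table into several contrasts.  Standard errors are
    derived as ``|foldChange / t|``.

    Duplicate gene symbols within a contrast raise unless
    ``aggregate_duplicates="mean"``, which averages fold-changes and combines
    standard errors as the root mean square.  A zero or missing ``t`` is
    accepted only for a zero fold-change (the gene is then excluded from the
    CI variance); otherwise it is an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"nodeLabel", "foldChange", "t"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if "contrast" in df.columns:
        groups = [(str(k), g) for k, g in df.groupby("contrast", sort=True)]
    else:
        groups = [(path.stem, df)]
    out = []
    for cname, g in groups:
        dup = g["nodeLabel"].duplicated()
        if dup.any():
            if aggregate_duplicates is None:
                dups = sorted(g.loc[dup, "nodeLabel"].unique())
                raise ValueError(
                    f"{path} [{cname}]: duplicate nodeLabel entries "
                    f"{dups[:5]}; pass aggregate_duplicates='mean' to average"
                )
            if aggregate_duplicates != "mean":
                raise ValueError(
                    f"unknown aggregation mode {aggregate_duplicates!r}"
                )
        beta, se = {}, {}
        for label, rows in g.groupby("nodeLabel", sort=True):
            fcs = rows["foldChange"].to_numpy(float)
            ts = rows["t"].to_numpy(float)
            ses = []
            for fc, t in zip(fcs, ts):
                if not np.isfinite(t) or t == 0.0:
                    if fc != 0.0:
                        raise ValueError(
                            f"{path} [{cname}]: gene {label!r} has "
                            f"foldChange {fc} but t={t}; cannot derive se"
                        )
                    ses.append(np.nan)
                else:
                    ses.append(abs(fc / t))
            ses = np.asarray(ses)
            beta[str(label)] = float(np.mean(fcs))
            if np.isfinite(ses).any():
                se[str(label)] = float(np.sqrt(np.mean(ses[np.isfinite(ses)] ** 2)))
        out.append(Contrast(name=cname, beta=beta, se=se, provenance=str(path)))
    return out


def match_contrast(
    net: TwoLayerNetwork,
    contrast: Contrast,
    min_downstream: int = 5,
    case_insensitive: bool = False,
):
    """Map a contrast onto the transcript layer and re-filter the network.

    Transcript edges whose gene was not measured are dropped (absence of a
    measurement is not evidence of no change), after which the footprint
    pruning and scorability filters are re-applied so the reduced network
    still satisfies their contracts.

    Returns
    -------
    (net, beta, se) : (TwoLayerNetwork, ndarray, ndarray)
        The reduced network, plus ``beta`` and ``se`` aligned to the gene
        order of its Laplacian blocks (``se`` is NaN for genes without a
        standard error).
    """
    if case_insensitive:
        lut = {g.lower(): g for g in contrast.beta}
        mapping = {g: lut.get(g.lower()) for g in net.gene_nodes}
    else:
        mapping = {g: (g if g in contrast.beta else None) for g in net.gene_nodes}
    matched = {g for g, m in mapping.items() if m is not None}
    if net.gene_nodes and not matched:
        raise ValueError(
            f"{net.name} / {contrast.name}: no transcript-layer gene matched"
        )
    frac = len(matched) / max(len(net.gene_nodes), 1)
    if frac < 0.5:
        warnings.warn(
            f"{net.name} / {contrast.name}: only {100 * frac:.1f}% of "
            f"transcript-layer genes matched",
            stacklevel=2,
        )
    if matched != set(net.gene_nodes):
        tedges = tuple(e for e in net.transcript_edges if e[1] in matched)
        genes = frozenset(g for _, g, _ in tedges)
        from dataclasses import replace

        net = replace(net, transcript_edges=tedges, gene_nodes=genes)
    net = restrict_to_scorable(prune_underrepresented(net, min_downstream))
    gene_order = tuple(sorted(net.gene_nodes))
    beta = np.array([contrast.beta[mapping[g]] for g in gene_order])
    se = np.array(
        [contrast.se.get(mapping[g], np.nan) for g in gene_order]
    )
    return net, beta, se


def solve_differential_values(blocks: LaplacianBlocks, beta: np.ndarray) -> np.ndarray:
    """Backbone differential values ``f = -L3^{-1} L2 beta``.

    This is the unique minimiser of the constrained smoothing objective; the
    solve uses a symmetric factorization of ``L3`` rather than an explicit
    inverse.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(blocks.gene_order),):
        raise ValueError(
            f"beta has shape {beta.shape}, expected ({len(blocks.gene_order)},)"
        )
    cho = scipy.linalg.cho_factor(blocks.L3)
    return -scipy.linalg.cho_solve(cho, blocks.L2 @ beta)


def propagation_matrix(blocks: LaplacianBlocks) -> np.ndarray:
    """The linear map ``K = -L3^{-1} L2`` with ``f = K beta``.

    Factored once per network and reused across contrasts and permutation
    nulls.
    """
    cho = scipy.linalg.cho_factor(blocks.L3)
    return -scipy.linalg.cho_solve(cho, blocks.L2)


def compute_npa(blocks: LaplacianBlocks, f: np.ndarray) -> float:
    """Network perturbation amplitude ``f^T Q f / |E|`` (nonnegative).

    Equals the explicit edge-average ``(1/|E|) sum_e (f(e0) + sigma(e)
    f(e1))^2`` over backbone edges; a coherent perturbation (each edge
    relation satisfied with a common amplitude ``a``) scores ``4 a^2``.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (blocks.n_backbone,):
        raise ValueError(
            f"f has shape {f.shape}, expected ({blocks.n_backbone},)"
        )
    return float(f @ blocks.Q @ f) / blocks.E_size


def node_contributions(blocks: LaplacianBlocks, f: np.ndarray) -> np.ndarray:
    """Additive per-node split of the amplitude: ``f * (Q f) / |E|``.

    The symmetric quadratic-form decomposition: contributions sum exactly to
    the score; individual entries may be negative when a node opposes the
    dominant coherent pattern.
    """
    f = np.asarray(f, dtype=float)
    return f * (blocks.Q @ f) / blocks.E_size


@dataclass
class NpaResult:
    """Scored perturbation of one network by one contrast."""

    network: str
    contrast: str
    score: float
    f: dict
    contributions: dict
    ci_low: float
    ci_high: float
    p_o: float | None = None
    p_k: float | None = None
    significant: bool = False
    label: str = ""
    o_null: dict = field(default_factory=dict)
    k_null: dict = field(default_factory=dict)

    @property
    def ci_passes(self) -> bool:
        return self.ci_low > 0

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "contrast": self.contrast,
            "score": self.score,
            "f": dict(sorted(self.f.items())),
            "contributions": dict(sorted(self.contributions.items())),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_o": self.p_o,
            "p_k": self.p_k,
            "significant": self.significant,
            "label": self.label,
            "o_null": self.o_null,
            "k_null": self.k_null,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NpaResult":
        return cls(**d)
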