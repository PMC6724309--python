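"""Significance assessment: delta-method CI and the O/K permutation nulls.

Three statistics decide whether an amplitude is a true positive:

* a 95% confidence interval propagating the per-gene fold-change standard
  errors through the quadratic form (must exclude zero);
* the **O** statistic — a null built by permuting the gene labels across the
  transcript layer, testing whether the score depends on *which* genes sit
  in each footprint;
* the **K** statistic — a null built by relabeling backbone node identities
  on the functional-layer edge list (footprints stay put), testing whether
  the score depends on how the backbone wires the footprints together.

A perturbation is called significant only when all three pass.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import (
    Contrast,
    compute_npa,
    match_contrast,
    propagation_matrix,
    solve_differential_values,
)
from .network import LaplacianBlocks, TwoLayerNetwork, build_laplacian_blocks

__all__ = [
    "PermutationNull",
    "confidence_interval",
    "permutation_O",
    "permutation_K",
    "significance_label",
    "derive_seed",
]


@dataclass(frozen=True)
class PermutationNull:
    """Summary of one permutation null distribution.

    ``p_value`` uses the add-one estimator ``(1 + #{null >= observed}) /
    (1 + n_perm)`` so the smallest achievable p is ``1/(n_perm+1)`` and p is
    never zero.
    """

    kind: str
    n_perm: int
    null_scores: np.ndarray
    observed: float
    p_value: float
    quantile95: float
    seed: int

    def summary(self) -> dict:
        q = self.null_scores
        return {
            "kind": self.kind,
            "n_perm": self.n_perm,
            "observed": float(self.observed),
            "p_value": float(self.p_value),
            "min": float(np.min(q)),
            "median": float(np.median(q)),
            "q95": float(self.quantile95),
            "max": float(np.max(q)),
            "seed": int(self.seed),
        }


def _null_from_scores(kind, null, observed, seed) -> PermutationNull:
    null = np.asarray(null, dtype=float)
    n = null.size
    p = (1.0 + int(np.sum(null >= observed))) / (1.0 + n)
    return PermutationNull(
        kind=kind,
        n_perm=n,
        null_scores=null,
        observed=float(observed),
        p_value=p,
        quantile95=float(np.quantile(null, 0.95)),
        seed=int(seed),
    )


def derive_seed(root_seed: int, *tags: str) -> int:
    """Deterministic child seed for (network, contrast, statistic) tuples."""
    h = zlib.crc32("|".join(tags).encode("utf-8"))
    return (int(root_seed) * 1_000_003 + h) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Confidence interval
# ---------------------------------------------------------------------------

def confidence_interval(
    blocks: LaplacianBlocks,
    beta: np.ndarray,
    se: np.ndarray,
    level: float = 0.95,
):
    """First-order (delta-method) confidence interval for the amplitude.

    Writing the score as the quadratic form ``NPA = beta^T M beta`` with
    ``M = K^T Q K / |E|`` and ``K = -L3^{-1} L2``, its gradient is
    ``2 M beta`` and, with independent genes,
    ``Var(NPA) ~= 4 sum_g (M beta)_g^2 se_g^2``.  Genes whose ``se`` is NaN
    (no usable t-statistic) are excluded from the variance sum.  Returns
    ``NPA -+ z * sqrt(Var)``; the interval "passes" when its lower bound is
    strictly positive.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if se.shape != beta.shape:
        raise ValueError("se and beta must be aligned")
    usable = np.isfinite(se)
    if np.any(se[usable] <= 0):
        raise ValueError("standard errors must be positive")
    f = solve_differential_values(blocks, beta)
    score = compute_npa(blocks, f)
    # (M beta)_g = (K^T Q f)_g / |E|; reuse the solve through K^T = -L2^T L3^{-1}
    import scipy.linalg

    cho = scipy.linalg.cho_factor(blocks.L3)
    mb = -(blocks.L2.T @ scipy.linalg.cho_solve(cho, blocks.Q @ f)) / blocks.E_size
    var = 4.0 * float(np.sum((mb[usable] ** 2) * (se[usable] ** 2)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return score - half, score + half


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

def _require_perm_args(n_perm: int):
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")


def permutation_O(
    net: TwoLayerNetwork,
    contrast: Contrast,
    n_perm: int = 500,
    seed: int = 0,
    min_downstream: int = 5,
) -> PermutationNull:
    """Transcript-layer reshuffling null ("O" statistic).

    Each draw applies one uniform random permutation to the gene labels
    across all transcript edges — per-node footprint sizes and the sign
    multiset are preserved — which is equivalent to permuting the entries of
    ``beta`` over the gene order, so the propagation matrix is factored once
    and each permuted score is two matrix products.
    """
    _require_perm_args(n_perm)
    net, beta, _ = match_contrast(net, contrast, min_downstream=min_downstream)
    blocks = build_laplacian_blocks(net)
    return permutation_O_blocks(blocks, beta, n_perm=n_perm, seed=seed)


def permutation_O_blocks(
    blocks: LaplacianBlocks, beta: np.ndarray, n_perm: int = 500, seed: int = 0
) -> PermutationNull:
    """O-statistic null from prebuilt blocks and an aligned ``beta``."""
    _require_perm_args(n_perm)
    m = len(blocks.gene_order)
    if m < 3:
        raise ValueError("transcript permutation needs at least 3 distinct genes")
    rng = np.random.default_rng(seed)
    K = propagation_matrix(blocks)
    observed = compute_npa(blocks, K @ beta)
    # columns = permuted beta vectors; scores vectorised via the F matrix
    P = np.empty((m, n_perm))
    for k in range(n_perm):
        P[:, k] = beta[rng.permutation(m)]
    F = K @ P
    null = np.einsum("ik,ij,jk->k", F, blocks.Q, F) / blocks.E_size
    return _null_from_scores("O", null, observed, seed)


def permutation_K(
    net: TwoLayerNetwork,
    contrast: Contrast,
    n_perm: int = 500,
    seed: int = 0,
    min_downstream: int = 5,
) -> PermutationNull:
    """Functional-layer reshuffling null ("K" statistic).

    Each draw relabels backbone node identities uniformly at random on the
    backbone edge list only — footprints stay attached to the original
    identities — then rebuilds the Laplacian blocks and rescores.  The
    backbone topology is preserved as an unlabeled signed graph while its
    alignment with the footprints is destroyed.
    """
    _require_perm_args(n_perm)
    net, beta, _ = match_contrast(net, contrast, min_downstream=min_downstream)
    blocks = build_laplacian_blocks(net)
    return permutation_K_blocks(blocks, beta, n_perm=n_perm, seed=seed)


def permutation_K_blocks(
    blocks: LaplacianBlocks, beta: np.ndarray, n_perm: int = 500, seed: int = 0
) -> PermutationNull:
    """K-statistic null from prebuilt blocks and an aligned ``beta``."""
    _require_perm_args(n_perm)
    n = blocks.n_backbone
    if n < 2:
        raise ValueError("backbone relabeling needs at least 2 backbone nodes")
    rng = np.random.default_rng(seed)
    B = blocks.L3 - np.diag(blocks.transcript_degree)  # backbone-only Laplacian
    Dt = blocks.transcript_degree
    observed = compute_npa(blocks, solve_differential_values(blocks, beta))
    L2b = blocks.L2 @ beta
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        # relabeling x -> perm[x]: conjugate the backbone blocks, keep
        # footprints (Dt, L2b) on the original identities
        inv = np.argsort(perm)
        Bp = B[np.ix_(inv, inv)]
        Qp = blocks.Q[np.ix_(inv, inv)]
        L3p = Bp + np.diag(Dt)
        try:
            f = -np.linalg.solve(L3p, L2b)
        except np.linalg.LinAlgError:
            # a relabeled component may lose all transcript support; use the
            # minimum-norm solution there (free nodes pinned to 0)
            f = -np.linalg.lstsq(L3p, L2b, rcond=None)[0]
        null[k] = (f @ Qp @ f) / blocks.E_size
    return _null_from_scores("K", null, observed, seed)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def significance_label(result, alpha: float = 0.05, trend: float = 0.1) -> str:
    """Compact marker string for the two permutation statistics.

    ``*O``/``*K`` for p below ``alpha``, ``.O``/``.K`` for p in the trend
    band ``[alpha, trend)``, nothing otherwise.  The CI carries its own
    ``*`` flag (``ci_low > 0``) reported separately on the result.
    """
    parts = []
    for p, tag in ((result.p_o, "O"), (result.p_k, "K")):
        if p is None:
            continue
        if p < alpha:
            parts.append("*" + tag)
        elif p < trend:
            parts.append("." + tag)
    return "".join(parts)


def is_significant(result, alpha: float = 0.05) -> bool:
    """All-three rule: CI excludes zero and both permutation p-values < alpha."""
    return (
        result.ci_low > 0
        and result.p_o is not None
        and result.p_o < alpha
        and result.p_k is not None
        and result.p_k < alpha
    )
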