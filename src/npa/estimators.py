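"""Estimator front-end: :class:`NPAScorer` and :class:`BIFAggregator`.

Both follow the scikit-learn estimator protocol (``get_params`` /
``set_params``, ``fit``, fitted attributes with a trailing underscore), so
they compose with ``sklearn.base.clone`` and pipeline-style tooling; the
computational primitives live in :mod:`npa.network`, :mod:`npa.core`,
:mod:`npa.stats`, :mod:`npa.leading` and :mod:`npa.bif`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import bif as _bif
from .core import (
    Contrast,
    NpaResult,
    compute_npa,
    match_contrast,
    node_contributions,
    solve_differential_values,
)
from .leading import leading_nodes
from .network import TwoLayerNetwork, build_laplacian_blocks
from .stats import (
    confidence_interval,
    derive_seed,
    is_significant,
    permutation_K_blocks,
    permutation_O_blocks,
    significance_label,
)

__all__ = ["NPAScorer", "BIFAggregator", "score_network", "aggregate_bif"]


def _as_contrast(X) -> Contrast:
    if isinstance(X, Contrast):
        return X
    if isinstance(X, pd.DataFrame):
        df = X
        required = {"nodeLabel", "foldChange", "t"}
        if not required.issubset(df.columns):
            raise ValueError(f"missing columns {sorted(required - set(df.columns))}")
        beta, se = {}, {}
        for label, fc, t in zip(df["nodeLabel"], df["foldChange"], df["t"]):
            g = str(label)
            if g in beta:
                raise ValueError(f"duplicate nodeLabel {g!r}")
            beta[g] = float(fc)
            if np.isfinite(t) and t != 0:
                se[g] = abs(float(fc) / float(t))
            elif fc != 0:
                raise ValueError(f"gene {g!r}: foldChange {fc} with t={t}")
        return Contrast(name="contrast", beta=beta, se=se)
    raise TypeError(f"cannot interpret {type(X).__name__} as a contrast")


class NPAScorer(BaseEstimator):
    """Score one two-layer network against an expression contrast.

    Parameters
    ----------
    network : TwoLayerNetwork
        The causal network to score (unfiltered; filters run at fit time).
    min_downstream : int, default 5
        Footprints smaller than this are removed before scoring.
    n_perm : int, default 500
        Draws for each permutation null.
    cutoff : float, default 0.8
        Leading-node cumulative-contribution cutoff.
    alpha : float, default 0.05
        Significance level for the permutation statistics; the CI level is
        ``1 - alpha``.
    case_insensitive : bool, default False
        Fold gene-symbol case when matching the contrast.
    random_state : int, default 0
        Root seed; per-statistic child seeds are derived from it and the
        (network, contrast) names, so results are reproducible and
        independent of evaluation order.

    Attributes
    ----------
    score_ : float
        The network perturbation amplitude.
    f_ : dict
        Backbone differential values.
    contributions_ : dict
        Additive per-node decomposition of ``score_``.
    ci_ : (float, float)
        Delta-method confidence interval.
    p_o_, p_k_ : float
        Permutation p-values (transcript- and functional-layer nulls).
    significant_ : bool
        All-three decision rule.
    leading_nodes_ : LeadingNodeSet
        Ranked decomposition (only when ``score_ > 0``).
    result_ : NpaResult
        Everything above bundled for serialization.
    """

    def __init__(
        self,
        network: TwoLayerNetwork = None,
        *,
        min_downstream: int = 5,
        n_perm: int = 500,
        cutoff: float = 0.8,
        alpha: float = 0.05,
        case_insensitive: bool = False,
        random_state: int = 0,
    ):
        self.network = network
        self.min_downstream = min_downstream
        self.n_perm = n_perm
        self.cutoff = cutoff
        self.alpha = alpha
        self.case_insensitive = case_insensitive
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the full scoring pipeline on one contrast.

        ``X`` is a :class:`~npa.core.Contrast` or a DataFrame with columns
        ``nodeLabel``, ``foldChange``, ``t``.
        """
        if self.network is None:
            raise ValueError("network must be set before fitting")
        contrast = _as_contrast(X)
        net, beta, se = match_contrast(
            self.network,
            contrast,
            min_downstream=self.min_downstream,
            case_insensitive=self.case_insensitive,
        )
        blocks = build_laplacian_blocks(net)
        f = solve_differential_values(blocks, beta)
        score = compute_npa(blocks, f)
        contrib = node_contributions(blocks, f)
        ci = confidence_interval(blocks, beta, se, level=1 - self.alpha)
        o = permutation_O_blocks(
            blocks,
            beta,
            n_perm=self.n_perm,
            seed=derive_seed(self.random_state, net.name, contrast.name, "O"),
        )
        k = permutation_K_blocks(
            blocks,
            beta,
            n_perm=self.n_perm,
            seed=derive_seed(self.random_state, net.name, contrast.name, "K"),
        )

        self.network_matched_ = net
        self.blocks_ = blocks
        self.score_ = score
        self.f_ = dict(zip(blocks.node_order, f.tolist()))
        self.contributions_ = dict(zip(blocks.node_order, contrib.tolist()))
        self.ci_ = (float(ci[0]), float(ci[1]))
        self.p_o_ = o.p_value
        self.p_k_ = k.p_value
        self.o_null_ = o
        self.k_null_ = k
        result = NpaResult(
            network=net.name,
            contrast=contrast.name,
            score=score,
            f=self.f_,
            contributions=self.contributions_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            p_o=o.p_value,
            p_k=k.p_value,
            o_null=o.summary(),
            k_null=k.summary(),
        )
        result.significant = is_significant(result, alpha=self.alpha)
        result.label = significance_label(result, alpha=self.alpha)
        self.significant_ = result.significant
        self.result_ = result
        self.leading_nodes_ = (
            leading_nodes(result, cutoff=self.cutoff) if score > 0 else None
        )
        return self

    def score(self, X=None, y=None) -> float:
        """The fitted amplitude (refits when ``X`` is given)."""
        if X is not None:
            self.fit(X)
        if not hasattr(self, "score_"):
            raise ValueError("NPAScorer is not fitted yet")
        return self.score_


class BIFAggregator(BaseEstimator):
    """Aggregate scored (network x contrast) cells into the impact factor.

    Parameters
    ----------
    families : dict, optional
        Network name -> family label; networks missing from the map fall
        back to their own ``NpaResult`` network name as a singleton family
        only if ``families`` is None entirely.
    reference : str, default "auto"
        Reference contrast id, or "auto" for the highest raw impact.

    Attributes
    ----------
    raw_bif_, relative_bif_ : dict
        Contrast -> raw weighted sum / percent of the reference.
    reference_ : str
    family_fractions_ : dict
    delta_ : dict
        Contrast -> pattern similarity vs. the reference, in [-1, 1].
    result_ : BifResult
    """

    def __init__(self, families: dict | None = None, reference: str = "auto"):
        self.families = families
        self.reference = reference

    def fit(self, X, y=None):
        """``X`` is an iterable of :class:`~npa.core.NpaResult`."""
        results = list(X)
        if self.families is None:
            families = {r.network: r.network for r in results}
        else:
            families = self.families
        res = _bif.compute_bif(results, families, reference=self.reference)
        self.raw_bif_ = res.raw
        self.relative_bif_ = res.relative
        self.reference_ = res.reference
        self.family_fractions_ = res.family_fractions
        self.delta_ = res.delta
        self.weights_ = res.weights
        self.result_ = res
        return self


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def score_network(network: TwoLayerNetwork, contrast, **params) -> NpaResult:
    """One-call scoring: ``NPAScorer(network, **params).fit(contrast).result_``."""
    return NPAScorer(network, **params).fit(contrast).result_


def aggregate_bif(results, families=None, reference="auto") -> _bif.BifResult:
    """One-call aggregation via :class:`BIFAggregator`."""
    return BIFAggregator(families=families, reference=reference).fit(results).result_
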