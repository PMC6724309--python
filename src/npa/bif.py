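"""Biological Impact Factor: aggregating network perturbations across families.

When several networks (grouped into families such as cell stress or cell
fate) are scored against the same contrasts, the significant amplitudes are
summed with weights that discount large families and redundant (overlapping)
networks, yielding one raw impact per contrast.  Impacts are reported
relative to a reference contrast (the strongest, by default) as percentages,
with per-family contribution fractions and a cosine similarity index
``delta`` in [-1, 1] describing how much each contrast's underlying backbone
perturbation pattern resembles the reference's.

The weighting (inverse family size times an inverse mean-Jaccard overlap
discount) and the delta index are this package's explicit choices; both sit
behind small strategy hooks so alternative schemes can be dropped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BifResult", "network_weights", "compute_bif", "compute_delta"]


@dataclass
class BifResult:
    """Family-weighted aggregation of significant network perturbations."""

    raw: dict
    relative: dict
    reference: str
    family_fractions: dict
    delta: dict
    weights: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "raw": dict(sorted(self.raw.items())),
            "relative": dict(sorted(self.relative.items())),
            "reference": self.reference,
            "family_fractions": {
                c: dict(sorted(v.items()))
                for c, v in sorted(self.family_fractions.items())
            },
            "delta": dict(sorted(self.delta.items())),
            "weights": dict(sorted(self.weights.items())),
        }


def _index_results(results):
    """results -> (networks, contrasts, cell lookup)."""
    cells = {}
    for r in results:
        cells[(r.network, r.contrast)] = r
    networks = sorted({n for n, _ in cells})
    contrasts = sorted({c for _, c in cells})
    return networks, contrasts, cells


def _backbone_sets(cells, networks):
    out = {}
    for (n, _), r in cells.items():
        out.setdefault(n, set(r.f))
    return {n: out[n] for n in networks}


def network_weights(backbone_sets: dict, families: dict) -> dict:
    """Family- and overlap-discounted weights.

    ``w_i = (1 / |family(i)|) * 1 / (1 + mean Jaccard overlap of network i's
    backbone node set with every other network)``.  Disjoint networks in a
    family of two get 1/2 each; heavy node sharing shrinks the weight
    further so redundant mechanisms are not double counted.
    """
    networks = sorted(backbone_sets)
    missing = [n for n in networks if n not in families]
    if missing:
        raise ValueError(f"networks without a family: {missing}")
    fam_size = {}
    for n in networks:
        fam_size[families[n]] = fam_size.get(families[n], 0) + 1
    weights = {}
    for n in networks:
        others = [m for m in networks if m != n]
        if others:
            jac = []
            a = backbone_sets[n]
            for m in others:
                b = backbone_sets[m]
                union = len(a | b)
                jac.append(len(a & b) / union if union else 0.0)
            obar = float(np.mean(jac))
        else:
            obar = 0.0
        weights[n] = (1.0 / fam_size[families[n]]) / (1.0 + obar)
    return weights


def compute_bif(results, families: dict, reference: str = "auto") -> BifResult:
    """Aggregate scored (network x contrast) cells into the impact factor.

    Non-significant cells contribute zero.  ``reference="auto"`` picks the
    contrast with the highest raw impact; relative impacts are percentages
    of the reference's raw value.  If no cell at all is significant the
    impact is zero everywhere (with a warning) and relative values are 0.
    """
    results = list(results)
    networks, contrasts, cells = _index_results(results)
    if not networks:
        raise ValueError("no results given")
    weights = network_weights(_backbone_sets(cells, networks), families)

    raw = {}
    fam_raw = {}
    for c in contrasts:
        total = 0.0
        per_fam = {}
        for n in networks:
            r = cells.get((n, c))
            if r is None or not r.significant:
                continue
            part = weights[n] * r.score
            total += part
            per_fam[families[n]] = per_fam.get(families[n], 0.0) + part
        raw[c] = total
        fam_raw[c] = per_fam

    if all(v == 0.0 for v in raw.values()):
        warnings.warn("no significant network perturbation; BIF is 0", stacklevel=2)
        rel = {c: 0.0 for c in contrasts}
        ref = reference if reference != "auto" else contrasts[0]
        fractions = {c: {} for c in contrasts}
        delta = {c: 0.0 for c in contrasts}
        return BifResult(raw, rel, ref, fractions, delta, weights)

    if reference == "auto":
        ref = max(contrasts, key=lambda c: (raw[c], c))
    else:
        if reference not in raw:
            raise ValueError(f"unknown reference contrast {reference!r}")
        ref = reference
    if raw[ref] <= 0:
        raise ValueError(f"reference contrast {ref!r} has zero impact")

    rel = {c: 100.0 * raw[c] / raw[ref] for c in contrasts}
    fractions = {
        c: {fam: v / raw[c] for fam, v in fam_raw[c].items()} if raw[c] > 0 else {}
        for c in contrasts
    }
    delta = compute_delta(results, ref, weights=weights)
    return BifResult(raw, rel, ref, fractions, delta, weights)


def compute_delta(results, reference: str, weights: dict | None = None) -> dict:
    """Cosine similarity of backbone perturbation patterns vs. the reference.

    For each contrast, the differential values of every network (zeroed when
    that cell is not significant) are concatenated, each network scaled by
    ``sqrt(w_i / |backbone_i|)`` so that no single large network dominates;
    delta is the cosine between that vector and the reference's.  A contrast
    with no significant perturbation at all gets delta 0.
    """
    results = list(results)
    networks, contrasts, cells = _index_results(results)
    if weights is None:
        families = {n: "all" for n in networks}
        weights = network_weights(_backbone_sets(cells, networks), families)
    node_orders = {
        n: sorted(_backbone_sets(cells, networks)[n]) for n in networks
    }

    def pattern(c):
        parts = []
        for n in networks:
            r = cells.get((n, c))
            order = node_orders[n]
            scale = np.sqrt(weights[n] / len(order))
            if r is None or not r.significant:
                parts.append(np.zeros(len(order)))
            else:
                parts.append(scale * np.array([r.f[x] for x in order]))
        return np.concatenate(parts)

    vref = pattern(reference)
    nref = np.linalg.norm(vref)
    if nref == 0:
        raise ValueError(
            f"reference contrast {reference!r} has an all-zero perturbation pattern"
        )
    delta = {}
    for c in contrasts:
        if c == reference:
            delta[c] = 1.0
            continue
        v = pattern(c)
        nv = np.linalg.norm(v)
        delta[c] = float(np.clip(v @ vref / (nv * nref), -1.0, 1.0)) if nv > 0 else 0.0
    return delta
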