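# Methods

## Model

A two-layer causal network couples a signed, directed backbone `G = (V, E)`
(functional entities: activities, abundances) to a transcript layer `V0`
(genes) through signed footprint edges. A contrast supplies log2 fold-changes
`β` on `V0` together with standard errors `se = |foldChange / t|` recovered
from the reported t- or z-statistics; the package consumes these statistics
and never fits the expression model itself.

The backbone differential values `f` minimise

    Σ_{x→y} ( f(x) − σ(x→y) f(y) )²     s.t.  f|_{V0} = β ,

the sum running over all edges of both layers. Every edge is treated as
undirected inside the quadratic forms (both displayed sums are symmetric in
the endpoints given the sign); directions are kept in the data model because
the scorability filter is a directed-reachability rule. With `L3` (backbone ×
backbone) and `L2` (backbone × gene) the blocks of the signed Laplacian of
the full two-layer graph — `L3[x,x]` = total degree of `x`, off-diagonals
`−Σ signs` — the minimiser is `f = −L3⁻¹ L2 β`, computed via one Cholesky
factorization of `L3` per network and reused across contrasts and
permutations (equivalent to explicit inversion well below 1e−10).

The amplitude is the coherence quadratic form over backbone edges,

    NPA = fᵀ Q f / |E| ,  Q[x,x] = backbone degree, Q[x,y] = +Σ signs ,

equal to the explicit edge average `(1/|E|) Σ (f(e0) + σ(e) f(e1))²`. Note
the sign asymmetry: the objective uses the minus convention (smoothness along
signed edges) while the score uses the plus convention, so a sign-coherent
perturbation of amplitude `a` is rewarded with the maximal score `4a²`.
Parallel backbone edges are summed term by term (opposite signs cancel in
off-diagonals; both count toward degrees and `|E|`); self-loops are rejected
at read time because neither displayed sum defines them.

### Filters

1. *Footprint pruning* (`min_downstream`, default 5): a backbone node with
   1–4 transcript edges has its whole footprint removed — too thin a readout
   to constrain the node.
2. *Scorability*: a backbone node is kept when a measured node (one with a
   footprint) is reachable from it, or reaches it, along directed backbone
   paths (itself included). The node is then tethered to data; untethered
   nodes are removed with their edges. Pruning runs first since it can strip
   a node's footprint and change scorability. `L3` is declared singular below
   a reciprocal condition number of 1e−12, which after these filters can only
   arise from a backbone component with no transcript support; the error
   names the components.

Genes measured in the contrast but absent from the network are ignored; genes
in the network but absent from the contrast have their transcript edges
dropped (absence of measurement is not evidence of no change) and the filters
re-run.

## Statistics

*Confidence interval.* `NPA = βᵀMβ` with `M = KᵀQK/|E|`, `K = −L3⁻¹L2`; the
first-order delta-method variance with independent genes is
`Var ≈ 4 Σ_g (Mβ)_g² se_g²` and the interval is `NPA ± z_{0.975}√Var`. Genes
without a usable t-statistic (t = 0 with β = 0) are excluded from the
variance sum. Against a 10,000-draw parametric bootstrap the delta-method SD
agrees within 15% when `se/|β| ≤ 0.3`; at larger relative noise the quadratic
nonlinearity (bias `tr(M)·se²` and a chi-square-like tail) makes the linear
approximation optimistic, which is a known limitation.

*O statistic.* Gene labels are permuted uniformly across the transcript
edges, preserving per-node footprint sizes and the sign multiset. This is
algebraically a permutation of the `β` entries, so the null is vectorised
through the precomputed `K`. p-values use the add-one estimator
`(1 + #{null ≥ observed}) / (1 + n_perm)`; the smallest achievable p is
`1/(n_perm+1)` and p is never 0. Default `n_perm = 500`.

*K statistic.* Backbone node identities are relabelled uniformly at random on
the backbone edge list only; footprints stay with the original identities.
The backbone topology survives as an unlabeled signed graph while its
alignment with the footprints is destroyed. Each draw conjugates the
backbone-only Laplacian and `Q` by the permutation and re-solves. If a
relabelled component loses all transcript support the minimum-norm
(least-squares) solution is used for that draw. A structural property worth
knowing: on a backbone whose signs admit a uniform coherent state (e.g. all
edges +1), every relabelling preserves each edge's coherence, the null is
degenerate at the observed score and p = 1 — the K test has power only
against sign-heterogeneous structure.

*Decision rule.* A perturbation is significant iff the CI excludes zero and
both permutation p-values are < 0.05 ("all three"); p-values in [0.05, 0.1)
are labelled as trends (`.O`/`.K`). The 95% null quantile is reported for
display but the p-value is primary. One root seed drives everything; child
seeds are derived per (network, contrast, statistic) via CRC32, so results
are reproducible and independent of evaluation order.

## Leading nodes and modules

Contributions use the symmetric quadratic-form split `f ∘ (Qf) / |E|`, which
sums exactly to the score; this decomposition formula is this package's
choice (it is the standard exact split of a quadratic form). Individual
contributions can be negative (nodes opposing the dominant pattern); they are
ranked as-is and sort last — an alternative reference implementation might
rank by absolute contribution. The leading set is the shortest prefix whose
cumulative contribution reaches `cutoff × score` (default 0.8, boundary
inclusive, ties broken lexicographically). Module extraction scores each node
by its mean contribution fraction across contrasts minus a size penalty and
grows greedily from the top node, absorbing the best neighbour while the
adjusted score is nonnegative; the result is always backbone-connected. This
is a documented greedy stand-in for heuristic maximum-scoring-subgraph
searches; community sub-clustering is left as a hook.

## BIF

Significant cells contribute `w_i · NPA_i(c)` with
`w_i = (1/|family(i)|) · 1/(1 + ō_i)`, `ō_i` the mean Jaccard overlap of
backbone node sets with the other networks — family size and node sharing
both discount redundant mechanisms. Raw sums are reported relative to a
reference contrast (auto: the largest raw value) as percentages. The δ index
concatenates per-network `f` vectors (zeroed where not significant), scales
each network by `√(w_i/|backbone_i|)`, and takes the cosine against the
reference (δ(ref) = 1 by construction; a contrast with no significant cell
gets δ = 0). The exact weighting and similarity formulas are explicit design
choices of this package, isolated behind `network_weights` / `compute_delta`
so alternative schemes can be swapped in; they satisfy the intended
qualitative properties (family normalisation, overlap discount, δ ∈ [−1, 1],
δ = 1 for identical mechanisms, invariance of relative BIF and δ under a
global rescaling of all contrasts).

## Synthetic data

The generator draws a connected Erdős–Rényi backbone (rejection sampling, up
to 100 tries), random edge orientations, negative signs with probability 0.3,
footprints of 5–20 genes on 80% of nodes (sizes chosen to survive the
five-downstream filter), and 50 decoy genes. A contrast plants a coherent
backbone state `s` (BFS gauge propagation; on frustrated backbones the
best-effort gauge is recorded and exact recovery is not asserted, only
NPA > 0): gene `g` downstream of `x` through sign `σ` gets
`β_g = a·s(x)·σ + N(0, se²)` with `se = noise_sd/√pseudo_n` (default
`pseudo_n = 10`), and `t = β/se`, so the reported uncertainty equals the
injected estimation error and the CI is honestly calibrated against the
generator. `a = 0` gives pure nulls.

What passing tests show — and don't. The generator provides exchangeable
footprints and independent Gaussian gene noise; real transcriptomes have
correlated genes, shared genes between footprints, noise that scales with
expression, and curated (non-random) backbone topology. Calibration and
coverage results here validate the machinery, not robustness to those
realities.

## Problem sizes and numerical choices

Test and acceptance runs use 10–15-node backbones with ~100–300 genes,
`n_perm = 500`, 200 datasets for calibration/coverage and 50 seeds for
recovery — sizes at which the full suite completes in seconds while the
binomial 99% bands are already informative. Degenerate inputs are errors,
not silent fallbacks: empty transcript layers, unmatched contrasts, singular
`L3`, zero-score leading-node requests, and a zero reference pattern in δ all
raise with specific messages. Duplicate contrast rows must be explicitly
aggregated (`mean` fold-change, RMS standard error). Scoring-relevant
orderings (node, gene) are lexicographic so matrices are reproducible
regardless of input row order.
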