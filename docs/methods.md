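# Methods

## The model

Qualitative class I HLA–peptide binding assays are represented as an
undirected weighted bipartite graph: allele nodes, peptide nodes, and an
edge of weight 2 (positive) or 1 (negative) per assayed pair.  Three
analyses are built on this object.

**Data preparation.**  Source grades are harmonised to binary labels
(IEDB's graded positives all count positive; AntiJen "weak binder" counts
negative; SYFPEITHI entries are ligand records and therefore positive).
Duplicate (allele, peptide) pairs are collapsed by the proportion of
positives, with the 0.5 boundary counting positive; every identical raw row
counts once toward the proportion (no per-source weighting — the simplest
reading of a majority vote).  Alleles and peptides supported by fewer than
`min_count = 2` records are removed iteratively until a fixed point.  The
fixed point is the bipartite 2-core, the unique maximal subgraph with all
degrees ≥ 2, so the result is independent of removal order; the test suite
checks this against repeated single-node deletion in random order.

**Module detection.**  Communities are found with the Clauset–Newman–Moore
fast greedy algorithm, delegated to python-igraph's `community_fastgreedy`
and cut at the maximum-modularity level of the merge dendrogram.  Modularity
is the general Newman–Girvan quantity `Q = Σ_c [W_c/m − (d_c/2m)²]`
(m total edge weight, W_c within-community weight, d_c community degree),
reimplemented from first principles and used to re-score every partition
independently of igraph; the two agree to 1e-12 in the tests.  The weighted
form is the default because the null model permutes weights — an unweighted
flag exists for sensitivity analysis.  The general (not bipartite-specific)
modularity is used throughout; Barber's bipartite variant is out of scope.
Determinism comes from the fixed node ordering of the network container;
igraph's internal tie-breaking is deterministic for a fixed input order.

**Null model.**  Replicate i shuffles the multiset of edge weights uniformly
over the fixed edge set with seed `base_seed + i` (topology untouched,
positive/negative counts conserved exactly) and re-clusters with identical
parameters.  The empirical p-value uses the add-one estimator
`(1 + #{Q_null ≥ Q_real}) / (1 + replicates)`.  An alternative rewiring null
(redraw edges, keep node counts and weight counts) is available as
`mode="rewire"` but is not the default.

**Module profiles.**  Peptides are bucketed by length (7, 8, 9, 10, 11,
\>11); column percentages are shares of a length bucket across modules.
Residues are categorised as polar charged (R, D, E, H, K), polar uncharged
(N, C, Q, G, S, T, Y) or apolar (A, I, L, M, F, P, W, V).  Allele rows are
the gapless aligned peptide-binding region, mature-chain residues 2–182, so
1-based row position i is residue i+1.  Position-specific pseudo-sequences
concatenate the groove residues contacting a peptide position in ascending
residue-number order.  The shipped contact map
(`data/contact_positions_synthetic.yaml`) is a synthetic reconstruction from
the classical pocket A–F literature, not an authoritative list, and is meant
to be replaced by users with their preferred contact definition.  Within- vs
between-module identity is tested one-sidedly (within > between) with a
Mann–Whitney rank test by default; identities of overlapping pairs are not
independent, so a label-permutation test of the mean difference is provided
and preferred for small module counts.  Modal-residue ties in the
difference-highlighting table break toward the alphabetically smallest
residue for determinism.

**Nebula.**  For a queried pair the two one-sided estimates are

    P(h_i, p_x) = w̄_i + Σ_j (w_{j,x} − w̄_j) S_ij / D

with j over the alleles connected to p_x (the peptide side mirrors the
roles), w̄ the node's mean over **all** its incident edges (not only
co-rated ones, on both sides of the formula and inside the correlations),
and S the Pearson correlation over the shared neighbourhood centred on those
node means; S = 0 for an empty shared set or a flat profile.  F is the mean
of the defined sides and the call is positive iff F ≥ UL = 1.5, the midpoint
of the two weights (boundary inclusive).  F is not clamped to [1, 2].

Numerical/degenerate policy: the denominator D is `Σ S` in the default
`literal` mode and `Σ|S|` in `absolute` mode (the classical Resnick
collaborative-filtering convention).  |D| < 1e-12 drops the deviation term
(node-mean fallback, flagged); a side whose node has no remaining edge is
undefined; if both sides are undefined the global training mean is used (and
flagged) so validation never abstains.  The signed literal denominator can
cancel or go negative, which flips the contribution of anti-correlated
neighbours and can produce unbounded F; it is kept as the default for
fidelity to the published formula, but `absolute` is the robust choice and
is what the synthetic validation experiments use (see below).

The queried pair's own edge is excluded from every mean, similarity,
neighbour sum and the global fallback.  Exclusion is structural — the
predictor simply never reads that matrix entry — so leave-one-out is a loop
over edges with no graph copies, and k-fold training networks (held-out
entries zeroed, full node index retained) traverse bit-identical arithmetic:
k = n_edges cross-validation reproduces leave-one-out exactly.

**Validation.**  Folds partition the *edges* (nodes may appear in both
halves), sizes differing by at most one; iteration i of repeated k-fold uses
seed `base_seed + i`.  Per iteration the per-edge predictions of all folds
are pooled before computing metrics.  Sensitivity, specificity and accuracy
use positive = binder; AUC is the midrank Mann–Whitney statistic, checked in
the tests against exhaustive concordant/discordant/tie pair counting.
Edges predicted by the global-mean fallback are included in the metrics and
counted separately in the report.

## The synthetic generator

The generator emulates the statistical structure of curated class I binding
data at desk scale: a planted-module bipartite topology, module-dependent
binary labels, a 9-mer-dominated length mixture (68.8% 9-mers, 26.3%
10-mers), per-module anchor-position category biases at P2 and the
C-terminal position, and a groove-region alignment whose contact residues
are module-diagnostic.

Default preset ("benchmark small"): 3 modules × 7 alleles × 200 peptides.
Within-module pairs connect with probability 0.35 (each peptide topped up to
≥ 2 within-module edges, and each allele to ≥ 2 edges, so the preset passes
the degree filter unchanged); cross-module pairs connect with probability
0.04.  Labels are drawn independently given the pair's modules: positive
with probability 0.99 within and 0.01 across.  These rates were chosen by
design analysis, not fitted: with pair-module-conditional labels the best
achievable ranking (a module oracle) is bounded by the label purity, and
rates of 0.9/0.1 would cap *any* predictor's LOO AUC near 0.76; 0.99/0.01
leaves an oracle bound ≈ 0.96, and the cross-density 0.04 makes the
cross-module anti-correlations estimable, so a correct implementation
measurably recovers the planted signal (LOO AUC ≈ 0.92–0.95 across seeds)
while weight shuffling still destroys it.  `with_signal(t)` anneals both
rates linearly to their midpoint, removing the label signal entirely at
t = 0 (labels i.i.d., AUC → 0.5).

Because the informative similarities in this construction are *negative*
(alleles of different modules anti-correlate over shared peptides), the
literal signed denominator systematically misreads them; the synthetic
validation experiments therefore run in `absolute` mode.  On real data,
where allele families share positively correlated fine-grained preferences,
the two modes are closer.

What the generator does **not** emulate: per-peptide binder propensities
(real peptides are coherently binders or non-binders across many alleles,
which is a large part of why collaborative filtering works well on real
data), assay noise correlated by source, the real 39.6%/60.4% class balance
(the preset is ≈ 82% positive because label purity is what carries the
planted signal), overlapping or nested modules, and any sequence → label
coupling in the default preset (a coupled mode via the anchor-category bias
exists but is off by default).  Passing the synthetic checks therefore
demonstrates correctness of the algorithms under a known ground truth, not
expected performance on experimental data.

Alignment generation: one founder per module on a shared random backbone
(non-contact positions diverge between founders at rate 0.10); every contact
column carries a distinct residue per module, members mutate at 0.05 per
residue (contact columns 5× slower).  With zero mutation, between-module
pseudo-sequence identity at contact positions is exactly 0 and within-module
identity 1.

## Problem sizes and reproducibility

The default test-and-acceptance scale is the 21 × 600 preset
(≈ 1,950 edges): leave-one-out takes well under a minute, the 50-replicate
null a few seconds, and 20 iterations of two-fold cross-validation under a
minute.  These sizes are the package's chosen desk-scale study conditions;
`scripts/acceptance.py` reports the size alongside every quantity.  All
randomness (generator, null replicates, folds, permutation tests) flows
from explicit integer seeds; replicate i of any batched procedure uses
`base_seed + i`, and identical seeds are bit-reproducible.

## Known limitations

- The fast greedy algorithm is delegated to igraph; only the modularity
  re-scoring is independent.  Other community algorithms (Louvain, Infomap)
  are out of scope except as test oracles.
- Only weights {1, 2} are supported; quantitative (IC50) affinities are not.
- The general Newman–Girvan modularity is applied to a bipartite graph, as
  is conventional in this pipeline, although bipartite-specific variants
  exist.
- The literal denominator can produce F far outside [1, 2] on adversarial
  neighbourhoods (an example appears when scoring anti-correlated alleles);
  use `absolute` mode when that matters.
- The network-based-inference (NBI) comparator is supported only as a
  plug-in scorer through the validation machinery; no NBI formula is
  shipped.
- Full-scale runs (hundreds of alleles, tens of thousands of peptides) are
  supported by the same code paths but leave-one-out is then
  O(edges × neighbourhood) and takes hours on one CPU.
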