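# Methods

## The model

The package scores pairs of ontology terms drawn from two different GO
categories by asking how strongly their annotated gene sets are associated in
a weighted gene co-function network, after correcting for annotation depth.

**Gene–gene association (iterative ranking).** Let E be the weighted
undirected co-function network over genes V, U its row-normalized adjacency
(u_ij = e_ij / Σ_k e_ik; rows of isolated genes are zero), and O the raw
adjacency rescaled by its maximum weight so all entries lie in [0, 1]. The
association matrix is the fixed point of

    R(t+1) = α O + (1 − α) U R(t),       R(0) = O,

stopped when θ = ‖R(t+1) − R(t)‖₁ (maximum absolute column sum) drops below a
threshold. Because U is (sub)row-stochastic and O is entrywise in [0, 1],
every iterate stays in [0, 1], and the map is a contraction with factor
(1 − α), so the fixed point is unique and the iteration converges linearly;
it equals the direct solve of (I − (1 − α)U) R = α O, which the package also
implements (`closed_form_ranking`) and uses as an exact cross-check in tests.
Row normalization makes U asymmetric, so the converged R is symmetrized by
averaging with its transpose (co-function association carries no direction),
the diagonal is overwritten with 1, and the entries are clamped to [0, 1]
with an assertion that the clamp only absorbs floating-point fuzz.

The unit diagonal is not cosmetic: in the soft set difference below, the
factor (1 − r_ii) = 0 makes every shared gene fully covered, which is what
makes |G − G| = 0 hold *exactly* for identical sets. Genes annotated in GO
but absent from the network score 0 against everything and 1 against
themselves — the conservative choice.

**Soft set overlap.** For propagated annotation sets G₁, G₂ the soft
difference

    |G₁ − G₂| = |G₁| − Σ_{gi∈G₁} (1 − Π_{gj∈G₂} (1 − r_ij))

treats 1 − Π(1 − r_ij) as the probability that gene gi is "covered" by at
least one gene of G₂ under independent associations. Sim_net plugs both
directed differences into the crisp-union formula
(|G₁∪G₂| − |G₁−G₂| − |G₂−G₁|)/|G₁∪G₂|. With R = I (no network information)
this collapses to the crisp overlap formula, a reduction the tests verify
against plain set arithmetic. Given r ∈ [0, 1] and the unit diagonal, each
soft difference lies in [0, |G·\G·'s crisp bound|], so Sim_net ≤ 1 always;
the disjoint/unconnected case is exactly 0.

**Shallow-annotation weight.** After true-path propagation a near-root term
annotates almost its whole category, so any overlap score would rate
unrelated high-level pairs highly. Sim_GO = √((1 − |G₁|/|G_C₁|)(1 −
|G₂|/|G_C₂|)) is 0 at the roots and → 1 for specific terms; the final score
is the product Sim = Sim_net · Sim_GO. Pairs in which either term annotates
the whole category universe are retained with score 0 rather than dropped,
keeping the output shape predictable; terms with *empty* propagated sets are
excluded (the similarity is undefined — a division by zero).

**Association network.** All cross-category pairs are scored; an empirical
null is built by scoring uniformly sampled (with replacement) random
cross-category term pairs; right-tail p-values use the add-one estimator
p = (1 + #{null ≥ s})/(1 + n_null); Benjamini–Hochberg converts them to
q-values; pairs with q below the FDR threshold (default 0.05) survive. The
random-pair null mirrors the negative model of the evaluation protocol
itself. Each surviving pair initially contributes both directed edges; then,
per term t₁ with filtered neighbor set T₂, the edge t₁ → t₂ is deleted
whenever some t₃ ∈ T₂ is a descendant of t₂. The rule runs in a single pass
over the original neighbor sets (deletions do not shrink T₂ mid-pass), and
mutually non-ancestral targets are both kept. Interpretation note: the rule
removes the directed edge entirely, which matches its goal of keeping only
the most specific relationships; an audit test re-applies the rule to the
exported network.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (restart weight) | 0.1 | weight of the original adjacency vs diffusion; smaller α → more weight on indirect paths. 0.1 is the strongest-diffusion setting commonly used with this iteration. |
| θ threshold | 1e-6 | stop when the L1 operator norm of the iterate difference falls below this; far below any gap that affects ranking. The fixed-point residual after stopping is ≤ θ(1−α)/α, so tests that compare against the closed-form solve at 1e-8 iterate to θ = 1e-12. |
| max_iter | 1000 | cap; non-convergence is flagged, not raised. |
| FDR threshold | 0.05 | q-value cut for the association network. |
| n_null | 10 000 | null-sample size for empirical p-values (CLI/library default). Desk-scale runs in the test suite use 1 000, which still floors p at ~1e-3 — ample for a 0.05 FDR on thousands of pairs. |
| dense limit | 6 000 nodes | above this U is kept sparse during iteration; results are identical to the dense path within 1e-8 (tested). |

Annotation propagation follows is_a and part_of (the GO true-path
convention); regulates-type relations are ignored; cross-namespace parent
edges are dropped with a warning. Evidence codes are not filtered by default;
`--exclude-iea` (or `exclude_evidence=`) removes IEA rows. Genes are compared
as bare identifier strings, case-sensitively — identifier mapping between the
GAF and the network is the caller's responsibility.

## The synthetic benchmark

`crogo2.synthetic` generates the four inputs from scratch: two rooted k-ary
trees as categories (default: ternary, 40 terms, hence 27 leaves each),
disjoint gene blocks (7 genes) on the leaves, and a co-function network in
which, for each of 8 planted cross-category leaf pairs, the union of the two
blocks is wired at p = 0.8 (weights U(0.5, 1)) over a p = 0.01 background;
400 genes in total. The gold standard lists the planted pairs as positives
and an equal number of uniformly sampled non-planted cross-category pairs as
randoms. Planted relatedness is encoded **only** in the network — planted
leaves never share genes — so recovering it exercises the diffusion pathway
of the score, not crisp overlap. In `indirect` mode the two blocks are wired
to a small shared hub set (2 hubs, drawn from genes left over after the leaf
blocks) with direct cross-block edges forbidden, making the relation visible
only through length-2 paths: the direct-links-only baseline
(`raw_association`, R = post-processed O) cannot see it, the diffusion can.
The `null` preset plants nothing and is used for FDR calibration.

What the generator does *not* emulate: yeastNet's degree distribution, GO's
term-size distribution, annotation incompleteness and evidence-code
structure, or gold standards derived from pathway→EC→term mappings. Passing
the synthetic benchmark therefore shows that the method recovers
network-encoded cross-category structure under controlled conditions, not
that any particular organism-scale figure is reproduced. Default sizes keep
a full generate–diffuse–score–evaluate cycle under a couple of seconds, so
multi-seed protocols (recovery over 5 seeds, calibration over 20) run in
well under five minutes.

## Numerical and design notes

- R⁰ = O makes the α → 1 limit exact at t = 0; the α = 1 − 1e-12 limit
  returns R ≈ O (tested).
- The method is invariant to global rescaling of edge weights (U is
  normalized per row, O by the maximum). A consequence worth knowing:
  raising one edge's weight *past* the network maximum is arithmetically the
  same as weakening every other edge, so the converged r between its
  endpoints need not increase in that regime; monotonicity holds while the
  raised weight stays at or below the maximum, and that is the regime the
  property test covers.
- Empirical p-values use the add-one (pseudo-count) estimator, so p ≥
  1/(n_null + 1) > 0 and BH is well defined.
- ROC curves group tied scores into single steps (the standard estimator);
  the trapezoidal AUC then equals the Mann–Whitney U statistic with ties
  counted 0.5, which the tests verify by brute force. TP rates at FP = 5, 10,
  15% use the conservative step value (no interpolation).
- The robustness protocol pairs the intact-network AUC with edge-deleted
  AUCs by deletion seed, reducing variance at small scale.
- Ties in the direction rule (t₂, t₃ mutually non-ancestral) keep both
  edges; the rule only fires on genuine ancestor–descendant relations.
- Degenerate inputs: empty networks and all-zero weight files are errors;
  isolated network nodes get zero diffusion rows; duplicate network edges
  merge keeping the maximum weight; obsolete ontology terms are parsed,
  flagged, and excluded from propagation and scoring.

## Limitations

- Within-category semantic similarity is out of scope, as are the ASR / VSM
  / direct-overlap baselines beyond the raw-adjacency degenerate mode;
  externally computed score files can be evaluated through `crogo2 evaluate`
  for side-by-side comparisons.
- Organism-scale term-association networks (thousands of terms, a
  ~100k-edge co-function network) require the corresponding GO release, GAF,
  and network files; the pipeline supports that scale (sparse iteration
  path) but ships no organism data.
- The empirical-FDR machinery (random-pair null + BH) is one defensible
  choice; nulls that match annotation-set sizes would be stricter for
  size-correlated biases and are not implemented.
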