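# Methods

## Model

The package scores species on rooted, dated phylogenies by expected loss of
phylogenetic diversity (PD). The assumptions are the standard ones of the
probabilistic PD framework: species go extinct independently, each with a
probability p over a fixed (50-year) horizon; a branch of the tree is lost
only if every tip descended from it is lost; protecting a species fixes its
survival without changing anyone else's p. Under these assumptions the
expected unique PD of species *i* is

    ED2_i = TBL_i + Σ_{j≥2} L_{i,j} · Π_{k ∈ C_{i,j} \ {i}} p_k

and EDGE2_i = ED2_i · p_i is the expected PD loss averted by securing the
species. The fair-proportion score ED1 and the original EDGE1 =
ln(1+ED1) + GE·ln 2 (GE ∈ 0..4) are computed alongside for comparison.

## Extinction probabilities

Red List categories map to probabilities anchored at CR = 0.97, halving per
step down: EN 0.485, VU 0.2425, NT 0.12125, LC 0.060625. Within-category
uncertainty is modelled by ranking species' "true" risk on a continuous
axis x ∈ [0,1]. The axis layout is a declared convention (the protocol
describes the rank plot but does not parameterise it): five equal-width
intervals ordered LC→CR with each anchor at its interval midpoint (0.1,
0.3, 0.5, 0.7, 0.9). A degree-4 polynomial is interpolated through the five
(midpoint, anchor) points — five points, five coefficients, so the
interpolant is unique and exact — and clipped to [0.0001, 0.9999] on
evaluation so no species is ever certainly safe or certainly lost.

Sampling is uniform in rank, not in probability: a data-sufficient category
draws x on its interval; DD and NE draw on the whole axis. We verified
numerically (dense grid, 50,001 points) that the fitted quartic is strictly
increasing on [0,1]; consequently each category's sampled median equals its
anchor exactly, and the DD/NE median equals the VU anchor (the curve's
value at x = 0.5). Clipping bites only near x = 1 (the raw curve reaches
≈1.36 there), producing a point mass at 0.9999 inside the CR interval
without moving the CR median. EW species are pinned at the upper clip bound
0.9999: they are extinct in the wild, so their unprotected extinction is
near-certain; the value is configurable in the shipped constants file.
EX species are never scored; if their tips remain on a tree they keep
p = 0.9999 so that relatives' ED2 correctly reflects their near-certain
absence rather than diluting it.

The anchors, intervals, bounds and GE integers ship in
`src/edge2/data/protocol_constants.yaml` under a version number so future
revisions remain comparable with existing prioritisations.

## Uncertainty propagation

Each iteration t pairs one tree (cycled deterministically through the
distribution in input order; sampling with replacement is available behind
a flag) with one fresh p draw per species from NumPy substream t of the run
seed. The same draw serves as the species' GE2 and as the p_k inside its
relatives' ED2 products, so an iteration is one coherent realisation; a
switch decouples the two draws for future GE2 ≠ p extensions. The iteration
count is constrained to the protocol band 100 < n ≤ 1000 unless explicitly
overridden.

Final per-species scores are medians across iterations (IQRs reported).
Certainty is the fraction of iterations in which the species' EDGE2
strictly exceeds that iteration's across-species median; strictness
guarantees selected species are genuinely in the upper half. The
per-iteration median is taken over all scored species, including DD/NE
(draws exist for all); whether the protocol intends DD/NE inclusion is not
stated, so this choice is documented here and exposed through the scored
set itself. Species absent from some trees are summarised over the
iterations where they are present, with the presence count reported.

List rules: EDGE ⇔ category ∈ {VU, EN, CR, EW} and certainty ≥ 0.95;
Borderline ⇔ same categories and 0.80 ≤ certainty < 0.95 (the boundary is
closed at 0.80 for stability under finite-n granularity); Research ⇔ DD/NE
and ≥ 0.95; Watch ⇔ LC/NT and ≥ 0.95. Research and Watch use the same 0.95
threshold as the EDGE list (configurable); EW species may qualify for
Borderline under the same gate as threatened categories. Ranks are assigned
within the full scored set and within each list, ties broken by (score
descending, label ascending).

## Numerical choices

- Per-branch descendant p products are accumulated in log space during one
  postorder pass, so a branch with thousands of secure descendants
  contributes a well-behaved ~0 rather than underflowing; a full-tree ED2
  evaluation is O(tree size).
- Traversal always runs to the root of the supplied tree with no
  truncation; deep branches self-truncate numerically, which also makes
  scores insensitive to grafting the study clade into a larger secure tree
  (tested).
- Unbranched internal nodes are collapsed at parse time by summing branch
  lengths; total PD is invariant under collapsing. Zero-length branches are
  allowed and contribute zero. Branch lengths are used at face value in MY
  with no ultrametricity requirement, since imputed tree sets need not be
  ultrametric.
- Taxa on trees but missing from the assessment table are treated as NE
  (the protocol explicitly covers unassessed species); a strict mode aborts
  instead.
- All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence(seed).spawn`, making every output byte a function of
  (inputs, configuration, seed).

## The independent oracle

`ed2_oracle` recomputes a species' expected unique PD by enumerating all
2^(n−1) survive/perish outcomes of the other tips (or Monte-Carlo sampling
them beyond 20 tips) and measuring, per outcome, the path length up to the
first branch with another surviving descendant. It shares no arithmetic
with the production traversal and is used to validate it to 1e-10 on random
trees, and to generate the expected values of the worked fixtures at test
time rather than hard-coding them.

## Synthetic data

The generator emulates the protocol's two inputs. Trees come from a
forward-time Gillespie birth–death simulation (pure birth by default for
speed and reproducibility; default birth rate 0.25/MY gives clade depths of
a few tens of MY, comparable to a genus- or family-level radiation). Tree
distributions are made by perturbing a base tree: multiplicative log-normal
branch-length jitter (default sigma 0.1) and regrafting a fraction of tips
(default 10%) to random branches, standing in for the placement uncertainty
of imputed species. Categories are assigned uniformly, with Red-List-like
frequencies, or phylogenetically clustered via a sticky Markov copy down
the tree (a child keeps its parent's category with probability 0.8 by
default).

What this does not emulate: real posterior tree sets have correlated,
clade-specific uncertainty rather than i.i.d. jitter; real Red List
frequencies vary by clade; taxon sampling in real trees is neither complete
nor random. Passing tests therefore demonstrate correctness of the
computations and the protocol logic under controlled conditions, not that
any particular empirical ranking is recovered.

Default problem sizes used in the test suite and examples (64-tip trees,
≤10-tree distributions, 100–1000 iterations) were chosen as representative
desk-scale clades; the pipeline itself is linear in tree size × iterations.

## Known limitations

- The rank-axis construction (equal-width intervals, midpoint anchors) is a
  convention; the protocol's published figure shows but does not
  parameterise it. Any alternative layout that preserves monotonicity and
  the anchor medians would be equally faithful.
- The sum of per-species EDGE2 scores is not the tree-level expected PD
  loss (shared branches are counted once per descendant); the tree-level
  quantity is exposed separately as `expected_pd_loss`.
- Action-specific extinction-risk reductions (GE2 as an avertable delta
  rather than p) and alternative DD/NE imputation schemes are out of scope,
  though the decoupled-draw switch leaves room for the former.
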