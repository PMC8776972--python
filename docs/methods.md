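# Methods

## Model

`fdinet` treats food–drug interaction discovery as link prediction on a
homogeneous graph of chemicals. The premise is that structural similarity is
informative for interaction potential: if a food constituent is structurally
close to a drug known to perturb a metabolic pathway, the constituent is a
candidate perturber of the same pathway. Representing drugs and per-food
compound instances as nodes of one type lets every similarity subnetwork —
drug–drug (DD), food–food (FF), food–drug (FD) — double as evaluation ground
truth: links of any type can be hidden and recovery measured, which matters
because no curated FDI gold standard of useful size exists.

Key assumptions, stated explicitly:

- **Similarity is ECFP4/Tanimoto.** Morgan fingerprints of radius 2 hashed
  to 2048 bits, compared with the Tanimoto coefficient. Radius 2 is the
  standard ECFP4 configuration; the bit length is the common community
  default and is configurable (`fingerprint(radius=, n_bits=)`). Two
  spellings of a molecule canonicalize to the same fingerprint.
- **A compound matters in proportion to its abundance.** Within each food,
  the contribution score `c_i = content_i / Σ content_j` (computed over the
  compounds that survive filtering — exclusions make renormalization
  necessary) scales similarity edges: FD edges by the compound's
  contribution, FF edges by the larger of the two contributions, DD edges
  not at all.
- **Sparsity by thresholds.** A Tanimoto threshold (default 0.6, inclusive)
  is applied to the raw profile, the contribution update follows, then a
  relaxed second threshold (default 0.5; 0.3 for the exploratory batch) is
  applied to the *updated* weight. Applying the second cut to the updated
  weight (rather than re-testing the raw Tanimoto) is the reading this
  package adopts; a caller can instead re-threshold raw scores by invoking
  `apply_threshold` a second time before the update.

## Graph variants and bridges

Thresholding leaves many disconnected components (the *disjoint* graph).
Some neighborhood scorers are uninformative across components, so a *joint*
variant chains components: component order is shuffled by the seed, one node
is drawn uniformly from each, and consecutive anchors are connected by
bridge edges of weight `1e-5`. A chain adds the fewest edges able to connect
the graph (exactly components − 1) and the near-zero weight keeps bridges
nearly inert in weighted scorers. Bridges are tagged: evaluators never count
them as recoverable links, shortest-path predictions that traverse one are
flagged (`uses_bridge`) and can be excluded, but they do participate in
neighborhood structure — that participation is the very reason the joint
variant exists.

## Scorers

- **SP_2 / SP_3**: Dijkstra shortest paths under summed edge weights; a
  non-adjacent pair is a candidate when its minimum-weight path has exactly
  2 or 3 edges, and scores are ranked *descending* (weights are
  similarities, so a larger minimal sum means stronger support). The
  single Dijkstra path defines the score; equal-weight alternatives are not
  accumulated. The inverted convention (similarity → distance, ascending
  rank) is available via `rank_predictions(ascending=True)`.
- **CN, Jaccard, Dice, Adamic–Adar, resource allocation** operate on the
  unweighted neighbor structure of the thresholded graph. Adamic–Adar uses
  the natural logarithm (the network-science convention; the base is a
  module constant). Dice is `2|∩|/(|Γa|+|Γb|)` and satisfies
  `Dice = 2J/(1+J)` identically.
- **L3** sums `w_au · w_uv · w_vb / √(k_u k_v)` over 3-edge paths with
  endpoint-excluded intermediates; the numerator uses edge weights, the
  degrees are unweighted counts.

Candidate pairs are only ever *new* links: pairs adjacent in the scored
graph are never emitted. Neighborhood methods emit the pairs that can score
above zero (≥ 1 common neighbor; for L3, ≥ 1 three-edge path). Ranking is
descending by score with deterministic lexicographic tie-breaks, ranks
1..n.

## Evaluation protocols

`split_links` removes a seeded fraction (default 30%) of eligible links —
DD only, or all non-bridge links — and the removed set is the positive
class. Four harnesses: (1) recover removed DD links, all methods;
(2) as (1) but only removed links confirmed by an external known-DDI list
count; (3) recover removed links of any type; (4) hold literature (food,
drug) gold pairs out of the graph entirely (any edge joining the pair's
drug to a compound of the pair's food is dropped before inference) and
report the fraction recovered among food-level predictions.

Metric choices that needed a decision:

- precision@top-k uses `k = ceil(percent/100 × n)`, guaranteeing `k ≥ 1` on
  short lists.
- The confusion sweep runs from the minimum to the maximum predicted score
  in steps of 0.1 (so the grid is method-dependent — SP and CN scores can
  exceed 1 — a comparability caveat across methods, kept as specified).
  "Positive" is strictly greater than the threshold. Held-out links the
  method never proposed count as false negatives at every threshold, so
  `tp + fn` is threshold-invariant.
- ROC area integrates (FPR, TPR) by trapezoid with the (0,0) and (1,1)
  corners anchored — the strict `>` at the minimum threshold otherwise
  never reaches the all-positive corner. Precision–recall area drops
  undefined-precision points (`tp + fp = 0`) before integration. Points
  are sorted by (x, y); vertical runs contribute zero width.
- Food-level reporting takes, per (food, drug), the maximum compound-level
  score, listing contributing compounds best-first.

## Synthetic fixtures

The generators produce the minimal schema subset the filters actually read,
deterministically (same spec ⇒ byte-identical files), with a manifest
naming exactly the records that must survive — parser correctness is a
round-trip property, not a spot check.

- **Drug corpus**: configurable mixes of approved/experimental,
  small-molecule/biotech, with an exact fraction of approved small
  molecules carrying a metabolism-related interaction description. The
  metabolism filter is a case-insensitive keyword match on the description
  text; the source databases describe such interactions in prose, so any
  machine rule is a convention — this one is the simplest that separates
  the fixture's two description families.
- **Drug SMILES** mix a vetted list of real drug-like and food-constituent
  molecules with homologous analog series (alcohols, acids, amines,
  alkylbenzenes of growing chain length). Real approved-drug space contains
  families of close analogs; the series reproduce that clustered similarity
  structure so thresholded fixture graphs have a non-trivial DD subnetwork.
  Neighboring homologs at chain length ≥ 5 exceed the 0.6 Tanimoto band.
- **Food corpus**: content amounts uniform on [1, 1000] mg/100 g (the
  scale of real per-100 g composition records); rows the filters must
  reject (ARTICLE citations, EXPERIMENT source types, missing amounts,
  missing health effects, a compound without SMILES) are always present.
  Some rows report (min, max) ranges; the parser collapses ranges by a
  configurable mode — min, max (default: the conservative
  exposure-at-worst choice) or mean.
- **Planted two-cluster graph** (150 nodes by default, `p_in = 0.7`,
  `p_out = 0.05`, weights uniform on [0.6, 1.0]): used for recovery
  experiments. The dense within-cluster blocks emulate the near-cliques
  that Tanimoto thresholding leaves among close analogs; the sparse
  cross-cluster background supplies the low-scoring candidate pairs against
  which recovery is measurable. Within one homogeneous random block a
  common-neighbor score carries no information about which pairs were
  edges, so recovery above chance is driven entirely by the two-density
  contrast — a useful reminder of what these scorers can and cannot do.

What the fixtures do **not** emulate: realistic food composition vectors,
correlated chemical families within one food, licensing-scale corpus sizes,
or the heavy-tailed degree distributions of the real similarity network.
Passing tests demonstrate algorithmic correctness and protocol behavior,
not real-data performance.

## Problem sizes and numerics

Default pipeline runs use fixture corpora of ~30 drugs and ~10 foods and
repeat splits 3 times; evaluation experiments in the test suite use planted
graphs of 80–150 nodes with 10 repeats and 100-permutation baselines —
sizes chosen so a full run completes in seconds on one core while leaving
each protocol statistically meaningful. Scorer–oracle agreement is asserted
to 1e-12 (pure floating-point arithmetic agreement); per-food contribution
sums to 1 within 1e-9. One run seed fans out to per-stage sub-seeds via
`numpy.random.SeedSequence([seed, stage_index])`, so stages can be re-run in
isolation; split seeds derive from `(seed, repeat_index)` the same way. All
derived seeds stay below 2^31.

Degenerate inputs: a food whose included contents sum to zero is an error
naming the food; an unparseable SMILES raises an error carrying the string,
but a *parseable* molecule with an empty fingerprint scores 0 against
everything rather than aborting a batch; a confusion sweep over a single
distinct score returns counts with both areas undefined; common neighbors
of degree ≤ 1 (impossible in a simple graph, possible on degenerate input)
contribute 0 to Adamic–Adar with a warning rather than dividing by log 1.

## Known limitations

- The two-node-type representation of foods (food-item nodes linked to
  compound nodes) is collapsed here into per-food compound nodes with
  contribution-scaled edges; food-level results come from aggregation at
  report time. An explicit food-item-node graph is a possible extension.
- Neighborhood scorers ignore edge weights (L3 excepted), so the
  contribution update influences them only through which edges survive the
  second threshold.
- The shortest-path score keeps only the single Dijkstra path; accumulating
  equal-length alternatives could stabilize SP_3, whose single-path scores
  degrade with path length.
- The sweep's fixed 0.1 step on unbounded score ranges makes areas
  comparable within a method across repeats, but not across methods.
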