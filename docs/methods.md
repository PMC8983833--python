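# Methods

## Evidence scoring

The pipeline starts from GWAS summary statistics.  Lead variants are selected
at genome-wide significance (`p_threshold`, default 5×10⁻⁸, strict `<`) and
expanded with linkage-disequilibrium proxies at `r² ≥ r2_min` (default 0.8);
each proxy carries the best (smallest) p-value among the leads it tags.
Expansion at high r² is the conventional reading of LD proxy selection: an
`r² < 0.8` rule would admit essentially unlinked variants and defeat the
purpose of the expansion.

Per-gene seed scores combine a bounded GWAS significance weight
`w(v) = min(−log₁₀ p_v, 12)/12` with evidence-specific geometry:

* **nGene** — max over variants within `ngene_window` (default 500 kb) of
  `w(v)·decay(dist)`; decay is linear `1 − dist/window` by default, with an
  exponential option `exp(−3·dist/window)`.  Distance is TSS-to-variant;
  strand is used only to define the TSS.
* **cGene** — max over variants falling inside a Hi-C fragment linked to the
  gene of `w(v)·(link_score/max link_score)`.  Interval overlap converts the
  1-based variant position to 0-based before the half-open comparison.
* **eGene** — max over eQTL records whose variant is in the expanded set of
  `min(−log₁₀ p_eQTL, 12)/12`; the eQTL p-value itself measures the
  variant-gene link, so no extra GWAS weight is applied.

Scores are max-normalized to [0, 1] per predictor.  The −log₁₀ cap at 12 and
the decay shapes are boundedness/rank-stability choices, all exposed in
`PredictorConfig`; ranks, not absolute seed values, drive everything
downstream.

## Network propagation

Each predictor's seeds are renormalized to sum 1 and diffused by random walk
with restart on the column-stochastic (degree-normalized, edge-weighted)
adjacency; isolated nodes self-transition.  Restart 0.75 is the common
choice for gene networks and keeps most mass near the seeds; convergence is
declared at L1 change < 10⁻¹⁰ (max 1000 iterations, error on
non-convergence).  The candidate universe is exactly the network's node set;
genes off the network are unscored.  The fixed point equals
`r·(I − (1−r)W)⁻¹·p0`, which the test suite verifies against a direct linear
solve on random graphs.

## Predictor filtering and combination

Proof-of-concept positives are genes with a drug at development phase ≥ 2;
controls are a seeded uniform sample of `control_ratio` (default 10) times as
many non-positive genes, drawn once per run.  Importance is Breiman
permutation importance over a bagged forest of decision trees (default 500):
per tree, the drop in out-of-bag accuracy when one predictor's out-of-bag
values are permuted, averaged over trees.  Regulatory predictors survive only
if their importance is ≥ that of nGene (ties kept: "no less informative").

Affinities become empirical p-values `rank/N` (descending affinity, average
ranks on ties, exact 1 for zero-affinity genes).  Combination methods:

* direct: `sum`, `max`, `harmonic` (`Σ s(i)/i²` over descending scores, the
  aggregation style of the Open Targets-like baseline);
* `fisher`: `−2Σ ln p` vs χ² with 2k df;
* `logistic`: `L = −Σ ln(p/(1−p))` with p clamped to [10⁻¹⁶, 1−10⁻¹⁶],
  `t* = L·sqrt(3(5k+4)/(kπ²(5k+2)))` vs Student t with 5k+4 df;
* `orderstat` (default): the joint cumulative `Q = k!·V_k` of the sorted rank
  ratios under the uniform null, with `V_i = Σ_j (−1)^(j−1)(V_{i−j}/j!)·
  r_{k−i+1}^j`.  Q is itself a probability, but its null distribution under k
  independent uniforms is not uniform, so it is calibrated against a cached
  Monte-Carlo table of 100,000 seeded uniform-null draws per k; the
  empirical tail probability is the combined p.

Combined scores for meta methods are `−log₁₀ p`; the final rating rescales
the combined score to [0, 5] by min–max, with ranks by descending score and
lexicographic tie-break, matching the rating-scale convention of
prioritization portals.

## Benchmarking

AUC uses the Mann–Whitney formulation (ties get half credit), making it
threshold-free and invariant under monotone transforms.  Precision–recall is
swept over every distinct score (tied scores enter together); F-max is the
maximum harmonic mean of precision and recall.  The naive baseline counts
distinct drugs per gene.

## Enrichment

The running enrichment score increments by `rating^θ` (normalized over set
members; θ default 1, θ=0 giving the classic Kolmogorov–Smirnov statistic)
at members and decrements uniformly at non-members; ES is the signed
extremum and the leading prioritization is the members at or before the
positive peak.  With only a single ranked list available, the permutation
null re-draws member positions uniformly (gene-label permutation); NES
divides ES by the mean same-sign permuted |ES|, and FDR follows the standard
pooled-NES procedure.  Sets overlapping the list in fewer than 3 genes are
skipped.  Note that truncating the ranked list changes the miss-step and
hit-weight normalizations, so ES is a property of the full list; the leading
edge is defined positionally, not by invariance under truncation.

Over-representation of thresholded lists (top 10% for hallmark-style
collections, top 1% for pathways, top 5% for the disease map — all config)
uses the one-sided hypergeometric tail with Benjamini–Hochberg FDR; odds
ratios use the Haldane half-count correction when a denominator cell is zero
(zero overlap reports OR = 0).

## Crosstalk and attack analysis

Nodes of the (optionally pathway-restricted) network are scored
`rating − q90(ratings)` (quantile configurable), so "highly prioritized" is
relative to the analyzed gene set.  The crosstalk is the connected subgraph
maximizing total node score: exact subset enumeration up to 15 nodes;
beyond that, positive-score components are merged greedily through
lowest-penalty paths (entering a node costs `max(0, −score) + 10⁻⁶`, the ε
breaking zero-cost ties deterministically), accepting merges only when the
total rises, then pruning negative-score leaves.  On random 12-node graphs
the heuristic recovers the enumerated optimum in the large majority of
instances and never exceeds it.

Significance permutes node scores across nodes and re-runs the search; a
normal fit to the null totals supplies the parametric upper tail (the only
route to p-values far below 1/n_perm), with the empirical count reported
alongside.  On small or dense graphs the null statistic has atoms (every
permutation connects all positive nodes), so the empirical p is conservative
there; calibration approaches uniform on larger sparse graphs, which is the
regime of real pathway networks.

The disconnection effect of removing a node set is
`1 − |largest remaining component| / |remaining nodes|`; an
`original`-denominator variant (dividing by |V|) is available since printed
percentages in the literature are ambiguous between the two.  Attack
analysis enumerates all completions of a fixed removal context (e.g. all
partners of an anchor gene) exhaustively and ranks by effect, ties
lexicographic.

## Cross-disease map

The supra-hexagonal lattice has a central hexagon plus complete rings —
`1 + 3r(r−1)` hexagons at radius r (91 at the default radius 6) — on axial
coordinates with the 6-neighbor relation.  The SOM is batch-trained:
deterministic initialization on the plane of the two principal axes of the
data, then epochs that assign every gene to its best-matching hexagon
(Euclidean distance, ties to the lowest index) and replace each prototype by
the Gaussian-neighborhood-weighted mean of assigned genes.  The neighborhood
radius decays linearly from the lattice radius to 1 over 50 rough epochs and
from 1 to 0.5 over 100 fine epochs.  Batch training with deterministic
initialization makes the map seed-free and test-stable.

Clusters come from the U-height landscape (mean codebook distance to lattice
neighbors): hexagons descend to local minima, which keeps each cluster a
connected patch; plateaus drain to the lowest-index hexagon so flat regions
form one cluster.  The natural number of clusters is the number of local
minima; if a target count is configured, adjacent clusters with the closest
mean codebook vectors are merged, preserving connectivity.

Disease relationships use distance `1 − Spearman ρ` over genes (consistent
with the pairwise correlation analysis; Euclidean is available), a
neighbor-joining tree (scikit-bio's Q-criterion implementation), and a
majority-rule consensus over trees from gene-bootstrap resamples, with split
supports equal to bootstrap fractions.

## Synthetic study conditions

The prioritization fixture defaults to 2000 genes on 4 chromosomes (TSS
every ~50 kb), 5000 variants, and 25 planted causal genes of which 40% are
distal-only (split between Hi-C and eQTL wiring).  Planted genes are spaced
so that no distal gene has any significant variant within the proximity
window — their signal is reachable only through the regulatory link; leads
carry p = 10^U, U ~ Uniform(−12, −8), background p-values are uniform, and
LD blocks of 10 consecutive background variants carry r² ~ Uniform(0.8, 1).
Decoy Hi-C/eQTL links (200 each) add realistic false wiring.  The network is
a preferential-attachment graph (attachment 3) with the planted genes
rewired into one dense connected module.  60% of planted genes plus 5
random decoys are marked phase ≥ 2, emulating a partially overlapping
clinical ground truth.  The rating fixture plants 689 genes × 7 diseases
with an 80-gene shared-high block and an 80-gene single-disease block over
low-rating background noise, clipped to [0, 5].

What the fixture does not emulate: realistic human LD structure and allele
frequencies, real gene coordinates, biased GWAS power across allele
frequencies, cell-type-specific regulatory sharing, or literature-driven
network degree bias.  Passing recovery tests therefore demonstrates the
machinery — evidence integration, propagation, filtering, combination —
under its own assumptions, not performance on real disease data.

Problem sizes in the test suite and the acceptance script (e.g. 5 fixture
seeds, 100 random graphs for the propagation cross-check, 10,000 null draws
for combiner calibration, 12–15-node graphs for the enumeration oracles) are
chosen so a full run completes in minutes on one CPU while leaving the
Monte-Carlo error well below the asserted margins.

## Known limitations

* Seed-score formulas (decay shapes, the −log₁₀ cap, per-table link-score
  rescaling) are package conventions; only ranks are consumed downstream,
  but absolute seed values should not be interpreted.
* The order-statistic calibration is Monte-Carlo (cached per k); combined
  p-values below ~10⁻⁵ are resolution-limited by the 100,000-draw table.
* The crosstalk heuristic is not exact above 15 nodes; it is validated
  against enumeration at small sizes and by its structural invariants
  (connectivity, no negative leaves) elsewhere.
* Gene identity is by case-sensitive symbol with no alias resolution; inputs
  must be pre-harmonized to a single gene model.
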