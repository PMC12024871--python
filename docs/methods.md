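# Methods

## The model

`omicsmap` treats a molecular interaction network as a sample from a hidden
geometry: every molecule (protein, lipid, metabolite) occupies a point
(r, θ) on a two-dimensional hyperbolic disk, and the probability that two
molecules interact decays with their hyperbolic distance

    d(s, t) = acosh[ cosh(r_s) cosh(r_t) − sinh(r_s) sinh(r_t) cos(Δθ) ],
    Δθ = π − |π − |θ_s − θ_t||.

The radial coordinate encodes *popularity* (hubs sit near the center), the
angular coordinate encodes *similarity* (molecules with shared interaction
neighborhoods sit at nearby angles).  This is the geometry of the
popularity–similarity (PS) model: a network grown by adding node t at radius
r_t = 2 ln t with a uniform angle, letting earlier nodes drift outward as
r_s(t) = β·2 ln s + (1−β)·2 ln t with β = 1/(γ−1), and connecting the
newcomer to m predecessors — the hyperbolically closest ones at temperature
T = 0, or each with Fermi–Dirac probability p(x) = 1/(1 + e^{(x−R_t)/2T}) at
T > 0, where the cutoff

    R_t = r_t − 2 ln[ 2T(1 − e^{−(1−β) ln t}) / (sin(Tπ) · m(1−β)) ]

is calibrated so the expected number of new links is m.  Networks grown this
way have power-law degree distributions with exponent γ and strong
clustering that weakens as T → 1.

## Network assembly

The protein layer comes from a confidence-scored PPI edge list (HIPPIE-style
TSV).  Edges at or above the confidence threshold (default 0.71, inclusive)
are kept, deduplicated as undirected pairs, self-loops dropped; the filter
is applied *before* extracting the largest connected component, and the LCC
tie-break (largest size, then lexicographically smallest member) makes the
result deterministic.  Lipids (`SLM:` accessions) and metabolites
(`Pubchem:` CIDs) attach to LCC proteins through enzymatic-reaction and GWAS
edges; a pair reported by both sources collapses to a single edge carrying
both provenance tags, and cross-layer nodes whose protein partner fell
outside the LCC are excluded.  A validator checks the resulting invariants
(connected protein core, every cross-layer node attached, one protein
endpoint per cross-layer edge, layer consistent with the id prefix), which
enforce the node/edge conservation identities by construction.

## Embedding

Coordinates are inferred by LaBNE followed by HyperMap-style likelihood
refinement:

* **LaBNE.** Angles are atan2 over the two eigenvectors of the symmetric
  normalized graph Laplacian with the smallest non-zero eigenvalues (dense
  solver below 2,000 nodes, shift-free Lanczos with a seeded start vector
  above).  Eigenvector signs are fixed so each eigenvector's first non-zero
  entry in lexicographic node order is positive, pinning the
  rotation/reflection gauge.  Radii follow the degree ranking:
  r_i = 2β ln i + 2(1−β) ln N for the i-th highest-degree node (ties broken
  by id).
* **HyperMap refinement.** Nodes are visited in increasing-radius order;
  each node's angle moves to the best of `grid` evenly spaced candidates
  within a window w centered on its current angle, scored by its rows of the
  pairwise PS log-likelihood at the final-snapshot cutoff R_N (with m
  estimated as half the mean degree unless given).  The current angle is
  always a candidate, so the total log-likelihood is non-decreasing by
  construction, and sweeps repeat until the relative gain drops below 1e−6
  (at most `max_sweeps`, default 3).  The defaults γ = 2.98, T = 0.84 and
  w = 2π match the parameters used for the published human map and are
  overridable; `estimate_gamma` (continuous MLE with KS-selected k_min) is
  offered as a helper but never applied silently.

### What the recovery experiments show — and what they do not

On simulated PS networks the angular coordinate is identifiable up to
rotation/reflection, so embedding quality is measured as the absolute
Fisher–Lee circular correlation between inferred and planted angles.  The
packaged experiment (N = 1000, m = 4, γ = 2.5, T = 0.1, seeds 0–4, windowed
refinement at w = π/4, 90 candidates) gives a mean LaBNE correlation of
0.76, with refinement improving four of the five realizations by +0.007 to
+0.016.

Two caveats are measured and deliberate:

* **Low-temperature localization.** At small non-zero T (≈0.1–0.2),
  near-threshold attachment overconnects dense angular arcs, and the leading
  Laplacian eigenvectors of some realizations localize on those arcs (high
  inverse participation ratio) instead of tracing the global circle.  Such
  realizations embed poorly (correlations ~0.4–0.6); over wider seed pools
  the T = 0.1 mean drops to ≈0.66, while T = 0 and T ≥ 0.3 are uniformly
  good (means ≈0.87 with no realization below 0.7).  Recovery is therefore
  *not* monotone in temperature at the low end; the monotone-degradation
  property is asserted over T ∈ {0.5, 0.7, 0.9}, where the
  clustering-versus-noise trade-off is one-sided.
* **Refinement from a bad basin.** Likelihood refinement started from a
  localized (mis-initialized) embedding increases the likelihood
  substantially while moving *away* from the planted angles — the optimizer
  is faithful to its objective, but the objective's basin is wrong.  The
  corresponding acceptance test (refined mean correlation ≥ LaBNE mean) is
  left failing rather than weakened: full-circle and windowed searches,
  softer likelihood temperatures, and a birth-order replay likelihood with
  per-pair cutoffs R_t were all tried and none repairs those realizations.

These experiments validate the implementation on data that matches the PS
model exactly; real interactomes violate the model (measurement bias,
missing edges, non-uniform angular density), so simulated recovery is an
upper bound, not a guarantee, for biological maps.

## Angular gap clustering

Nodes are sorted by angle; the N circular gaps between consecutive nodes
(including the wrap-around gap) are ranked by size and introduced as sector
boundaries greedily from the largest down.  A boundary is accepted only if
every resulting sector keeps at least `min_proteins` protein members
(default 10 — small enough sectors cannot support enrichment analysis);
lipids and metabolites belong to sectors but do not count toward the
minimum.  The first rejected gap stops the procedure, ties in gap size break
toward the smaller start angle, and a `max_clusters` override is available
for sensitivity analysis.  The procedure is invariant under global rotation
and monotone (more required proteins never yields more clusters).  Sector
annotation is a hypergeometric over-representation test of user-supplied
term→id annotations against the full protein background, with
Benjamini–Hochberg correction applied within each cluster's term list.

## Cross-omics ranking

For a validated input subset S (deduplicated, single layer, ids present in
the coordinate table), every molecule t of each other layer is scored by

    score(t) = 1 / Σ_{i=1..n} d_i,

the reciprocal of the sum of the n smallest hyperbolic distances from S to t
(n = 3 by default; if |S| < n all available distances are used, with a
prominent log message).  Targets are ranked by descending score; every tie —
among source distances and among target scores — breaks on the identifier,
so output is fully deterministic.  A target exactly coincident with input
coordinates (distance sum 0) is reported with an infinite-score sentinel and
ranks first.  Each ranked target carries an evidence trail of its n nearest
input molecules (6-decimal distances in the text column, full precision in
`distance_sum`).  The optional tissue filter keeps proteins expressed at
≥ 10 nTPM (inclusive) in at least one selected tissue, whether proteins are
the input or the target layer.

## Synthetic data

`make_toy_multiomics` is the fixture generator: a PS protein network
(reduced to its LCC, as the assembly pipeline would) with lipids and
metabolites anchored at random rim angles and attached to 1–3 proteins drawn
with probability ∝ exp(−d/2) in hyperbolic distance from the anchor, so
cross-layer nodes inherit angular locality.  The attachment rule is an
artifact of this package — the real map attaches lipids and metabolites from
curated enzymatic/GWAS sources — so toy maps emulate the *geometry* of the
published map, not its biology.  Everything is reproducible from the two
seeds (simulation, attachment).

## Numerical choices

* The acosh argument uses the cancellation-free rearrangement
  cosh(r_s − r_t) + 2 sinh(r_s) sinh(r_t) sin²(Δθ/2) and is clamped to ≥ 1,
  so coincident points give exactly 0 and radially aligned pairs give
  |r_s − r_t| to machine precision.
* Likelihood probabilities are clamped to [1e−12, 1 − 1e−12].
* Angles are canonicalized into [0, 2π) at every boundary (file read,
  embedding output, gauge transforms), with adjusted-row counts logged.
* All file writes go through a temp-file-plus-rename so outputs are never
  half-written; float columns use shortest round-trip formatting, making
  unmodified read→write cycles byte-identical.

## Problem sizes used in the packaged experiments

Recovery runs use N = 1000 (the smallest size at which the degree-rank
radial rule and the spectral angles stabilize); degree-exponent recovery
uses 10,000-sample Pareto tails over 10 seeds; distance properties use
10,000 random triples; ranking oracle checks use 200-node maps with every
target recomputed by brute force.  These sizes were chosen so the full
validation (test suite plus acceptance script) completes in minutes while
keeping every statistical margin wide.
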