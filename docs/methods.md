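# Methods

## Webs, symmetrization and dichotomization

A web is a directed binary graph of predator→prey links with set
semantics (no duplicate edges). Self-loops are legal — aggregation can
turn within-group feeding (e.g. cyprinids eating smaller cyprinids)
into a loop on the aggregate node — and are kept in the web so flow
tables can display them, but they are excluded from every metric: the
dyad-based density D = 2L/N(N−1) has no self-loop term, and degree,
distance and betweenness follow the same convention.

Before metric computation a web is *symmetrized*: each dyad's
interaction sum x_ij + x_ji is collapsed to presence/absence, so a
mutual-predation pair contributes one undirected link. The number of
mutual dyads is recorded (`mutual_pairs`) and reported in output
metadata, because it is exactly the gap between the directed link
count L and the undirected link count the density formula uses. The
published density values at the most aggregated level are only
consistent with this undirected reading (e.g. D = 0.418 on a 14-node
web implies 38 links, one fewer than the 39 directed links — one
mutual dyad), so `global_metrics` reports L as the directed count but
computes D from the symmetrized link set.

Labels are matched case- and whitespace-insensitively but the original
casing is preserved for output; sources mix all-caps family codes with
species binomials.

## Aggregation

A scheme is an ordered list of label mappings applied cumulatively
(the T3 web is the raw web pushed through T1, T2 and T3). Unmapped
labels pass through. Within one step a label cannot be both a source
and a target, and each source has a single target; violations raise a
scheme error rather than being resolved silently. Because the five
steps touch disjoint taxonomic groups, steps commute — a property the
test suite checks — and aggregation commutes with merging section webs
into a master web. Node and link counts are monotone non-increasing
along any scheme since relabeling followed by deduplication can only
collapse nodes and edges.

## Global metrics

- **N, L**: node count; deduplicated directed link count.
- **D** = 2·links/(N(N−1)) on the symmetrized, dichotomized, loop-free
  web.
- **CL**: degree-weighted mean of the local clustering coefficients,
  Σ deg_i·c_i / Σ deg_i. Nodes of degree < 2 have no defined triangle
  fraction; they get c_i = 0 and their weight (0 or 1) keeps their
  influence marginal. This is deterministic and avoids dropping nodes
  from the average.
- **d**: mean breadth-first geodesic over *reachable* unordered pairs.
  Unreachable pairs are excluded rather than infinite so disconnected
  mid-aggregation webs still get a finite d. Webs with no links have
  undefined d and raise.
- **SW** = CL/d, exactly; the identity is asserted across the embedded
  published metric table at 3-decimal precision.

The exact software variant behind the published "weighted overall
clustering coefficient" cannot be pinned down from its description
alone, so CL-dependent checks against published numbers go through the
SW = CL/d identity (using published CL and d), not through recomputed
CL on rebuilt webs.

## Local metrics

nDC_i = deg_i/(N−1), a fraction in [0, 1]. nBC_i is Brandes/Freeman
betweenness with fractional credit over equal-length geodesics,
normalized by (N−1)(N−2)/2 and scaled to [0, 100] percent — matching
the scales the published shared-node table uses (0.651 vs 13.593).
Isolated nodes get 0 for both. Betweenness is cross-checked against an
exhaustive shortest-path-enumeration oracle on all randomized graphs
of ≤ 7 nodes.

## REGE

The regular-equivalence similarity iterates from an all-alike start:
a pair (i, j) is rescored by how well each trophic partner k of i can
be matched by a partner m of j playing the same role, prey matched
with prey and consumer with consumer, weighted by the current
similarity of k and m:

    num_ij = Σ_k max_m R_km · (min(x_ik, x_jm) + min(x_ki, x_mj))
    den_ij = Σ_k max_m (max(x_ik, x_jm) + max(x_ki, x_mj))

with the update (num_ij + num_ji)/(den_ij + den_ji) — the two-sided
ratio keeps the matrix exactly symmetric. When one node of a pair has
partners and the other has none, the partnered node's unmatched
obligations still count in its one-sided denominator, so the pair's
similarity drops to 0; a pair of *two* fully isolated nodes has a zero
denominator and is given similarity 100 by convention (they are
vacuously equivalent, and the convention is deterministic). The
iteration is monotone non-increasing entrywise, preserves 100 for
strictly regularly equivalent pairs, and is permutation-equivariant —
all property-tested.

REGE runs on the **directed** web by default even though metrics use
the symmetrized one: the guild interpretation (detritus, producers and
water mites group together because all three only have consumers
eating them) requires edge direction. A symmetrized mode is available
behind a flag for sensitivity analysis. Three iterations is the
default (the conventional choice; context propagates one neighborhood
ring per pass) and the count is recorded in the output.

Clustering is agglomerative on dissimilarity 100 − S, average linkage
by default (single/complete selectable; no linkage is canonical for
this analysis). Dendrograms export as Newick with branch lengths equal
to merge-height differences.

## Two-web comparison

Shared nodes are matched by normalized label equality plus an explicit
synonym list (family-code vs genus spellings, size/age-split labels);
an ambiguous match is an error, never a guess. Medians are computed on
the values as published (3-decimal inputs), no rescaling. The
Mann–Whitney statistic uses midranks; the reported U is min(U₁, U₂),
the convention under which near-complete separation gives a small U
(52.5 with n₁ = n₂ = 30 is only consistent with this convention). The
two-sided p uses the normal approximation with tie-corrected variance
and no continuity correction; an exact-permutation p is available for
small samples without cross-group ties. The published p for the
betweenness test (0.102) differs from the tie-corrected asymptotic
value on the same inputs (0.099); since the original convention is
unstated, bound-type conclusions (significant / not at 0.05) are the
stable quantity and U is the exact one.

## Synthetic data

The niche model is the primary web generator: species i draws a niche
value n_i ~ U(0,1), a feeding range r_i = x·n_i with
x ~ Beta(1, 1/(2C) − 1) so the expected directed connectance L/n²
matches the target C, and a range centre c_i ~ U(r_i/2, n_i); i eats
every species whose niche value falls in the interval. The
smallest-niche species gets r = 0, guaranteeing a basal node. It is
preferred over Erdős–Rényi because it produces the interval-diet,
trophic-level structure REGE is meant to detect; an ER generator is
kept as a structureless null. Defaults (n = 50, C = 0.12) sit inside
the 0.04–0.2 raw-connectance range typical of compiled river webs.
Calibration is checked over 200 seeds: mean realized connectance
within 3 standard errors of the target.

The taxonomy generator emulates the layered node table: fish species
(some split into _SMALL/_LARGE variants at rate 0.2), invertebrate
family codes, producers (15% of species), and a never-aggregated
Detritus node, with a five-step scheme wired accordingly. Section webs
place detritus/producers at the bottom of the niche axis and fish at
the top before applying the interval rule, so resources are basal by
construction.

What the generators do **not** emulate: empirical degree
heterogeneity from uneven sampling effort, body-size correlations,
parasites, and the specific taxonomic composition of any real river.
Passing tests on synthetic webs therefore demonstrate correctness of
the algorithms and the stated invariants, not ecological fidelity of
any particular web.

Embedded fixtures carry the published per-node centrality tables for
the two rivers' 30 shared nodes and the published global-metric table
verbatim at printed precision, plus hand-built worked webs (path,
triangle, star, twin predator–prey dyads).

## Problem sizes and determinism

All generators take explicit seeds and are deterministic given one;
pipeline re-runs are byte-identical. The randomized oracle suites use
200 small graphs (≤ 7 nodes) for betweenness, 500 tied sample pairs
for Mann–Whitney, 100 (web, scheme) pairs for aggregation
monotonicity, and 200 seeds at n = 50 for niche calibration — sizes
chosen to give tight Monte-Carlo error while keeping the whole suite
in a few seconds on one CPU.

## Known limitations

- Rebuilding the published section webs needs the deposited
  predator–prey spreadsheets; the package ships the converter-ready
  readers and the full pipeline but not that data. The full-data
  replication tests report the data as missing when
  `data/po_sections/` is absent.
- REGE similarity values are algorithm- and iteration-specific; only
  the qualitative guild structure, not the numeric similarity scale,
  should be compared across implementations.
- The comparison stage treats the published 3-decimal centralities as
  exact inputs; it does not propagate rounding error.
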