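# Methods

## Model and scope

`coexsim` compares weighted, undirected gene networks in which an edge
weight in (0, 1] encodes the strength of coexpression between two genes.
Networks being compared are assumed to live on a shared gene namespace
(same species and annotation), so comparison is by *exact* matching of
node identifiers and edges — no alignment, no orthology mapping. The
common subnetwork of two networks is the set of genes present in both
plus the set of edges present in both; each common edge keeps the weight
it has in each parent.

Two conventions deserve note because the definitions alone do not fix
them:

- **Common node counting.** The node count of the common subnetwork
  includes shared genes that participate in no shared edge. Relative
  size is a statement about node sets; edge information enters only
  through the significance factor.
- **Empty common edge set.** When two networks share nodes but no edges,
  the coexpression significance is defined as 0 (hence COEXsim = 0):
  no shared coexpression, no significance. The alternative — leaving a
  0/0 mean undefined — would make the measure partial for no benefit.

COEXsim is not bounded above by 1: a pair whose few shared edges are much
heavier than either network's average can exceed it. The package does
not cap the value; thresholds are calibrated empirically anyway.

For the fuzzy (weighted-Jaccard) measure, set cardinality is the
sigma-count (sum of memberships) and the universe is the union of the
two edge sets. Absent edges have membership 0 in both operands and would
contribute nothing to either sum, so the sparse computation is exact,
not an approximation. Two edgeless networks have an undefined (0/0)
fuzzy similarity and raise an error.

Exact self-similarity: both measures return exactly 1.0 (not merely
within floating-point tolerance) for a network against itself; the
geometric means in the denominators are computed as `a` when `a == b`
so that the identity cancels algebraically.

## Graphlet baseline

The baseline treats networks as unweighted graphs (edge present ⇔ weight
> 0) and summarizes each node by its graphlet-orbit participation
counts. Counting enumerates every connected induced subgraph on up to
4 (default) or 5 nodes once, via the ESU algorithm, and classifies it up
to isomorphism by exhaustive permutation against a canonical catalogue
built at first use; classifications are memoized by local edge bitmask,
so the permutation cost is paid once per isomorphism type, not per
subgraph. This is deliberately a desk-scale implementation: it is exact
and simple, and comfortable for networks up to a few hundred nodes at
moderate density, but it is not an ORCA-style combinatorial counter and
will be slow on dense graphs with many thousands of 4–5-node subgraphs.

Orbits 0–14 (graphlets on 2–4 nodes) follow the standard numbering:
orbit 0 is the edge orbit (count = degree), orbits 1/2 the path ends and
middle, orbit 3 the triangle, and so on through K₄ (orbit 14). For the
5-node graphlets the package assigns orbits 15–72 in a deterministic
internal order (graphlets sorted by edge count, then maximum degree,
then degree sequence, then canonical certificate; orbits within a
graphlet by degree, then sorted neighbour degrees). Any fixed ordering
yields the same graphlet correlation distance, since the distance is a
norm over all orbit pairs.

The graphlet correlation matrix is the Spearman correlation (average
ranks) between orbit-count columns after appending one dummy all-ones
row, the standard device that keeps all-zero orbit columns from
producing undefined correlations. Columns that are constant even with
the dummy row are assigned correlation 1 with identical columns and 0
otherwise; the diagonal is forced to 1. Spearman is computed as Pearson
on ranks directly, because `scipy.stats.spearmanr` refuses inputs with
constant columns, which legitimately occur here. GCD is the Euclidean
norm of the upper-triangle difference of two such matrices.

The distance-to-similarity transform is `(max − GCD)/max` over the
observed distance matrix: similarity 1 at distance 0, 0 at the largest
observed distance. The sign-uncorrected variant `(GCD − max)/max`
(which maps distance 0 to −1) is available behind `--eq7-verbatim` for
auditability, but it is an anti-similarity and is not used anywhere
else in the package.

## Validation and calibration

Validation correlates a measure's full pairwise profile against an
externally supplied gold-standard similarity matrix (e.g., GO semantic
similarity between the terms that seeded the networks) using Spearman's
rank correlation; the p-value uses the t-approximation with n − 2
degrees of freedom. The default pair scope is `full` — all |L|² cells
including the diagonal and both orientations, so 20 networks contribute
400 network pairs. `offdiag` and `upper` scopes are available for users
who prefer to exclude diagonal inflation; rank correlation is invariant
under monotone transforms, so the choice mainly affects ties and the
effective n.

Threshold calibration uses a group design: a "similar group" of G
networks known to be mutually related, plus unrelated controls. Within
the full pairwise matrix the G×G within-group block — *including* the
diagonal, so a 5-member group contributes 25 values — is the similar
population and every remaining cell the "other" population. The
representative value of each population is the median (the score
distributions are skewed, so means would be dominated by a few heavy
pairs). The decision threshold per measure is the arithmetic mean of
the similar-group medians over the (typically two) calibration
experiments. Selection applies both thresholds strictly (>): a pair
must exceed the COEXsim *and* the fuzzy threshold. Selection accepts
rectangular matrices (e.g., 8 disease modules × 5 aging modules); on a
square matrix with identical label sets, self-pairs and duplicate
orientations are skipped.

Reported thresholds are conventionally rounded (the calibration
medians 0.15200/0.10554 average to 0.12877, quoted as 0.1288; the fuzzy
medians 0.00720/0.00389 average to 0.005545, quoted as 0.0055);
internal selection uses unrounded values unless the user passes the
printed ones. Both give the same selection on the published module
pairs, and the tests check this.

## Synthetic data generator

The generator stands in for the two kinds of real inputs the workflow
expects — GO-term-seeded coexpression networks and WGCNA modules —
neither of which can be rebuilt deterministically from a desk (they
depend on an external network service and on cohort expression data).

- `random_network`: Erdős–Rényi topology at `edge_density` with i.i.d.
  weights from `uniform(a,b)` or `beta(α,β)` restricted to (0, 1].
  Defaults: 120 nodes, density 0.2, `uniform(0.05, 0.95)` — a few
  hundred to a couple of thousand edges, the scale at which the real
  networks are used here.
- `perturbed_pair`: keeps ⌈`node_overlap`·n⌉ of the base's nodes,
  retains each base edge among kept nodes independently with
  probability `edge_retention`, jitters retained weights with Gaussian
  noise (sd `weight_jitter_sd`, default 0.05) clamped into (0, 1], and
  redraws fresh nodes and fresh edges (at the base density) for the
  rest. Overlap is planted on nodes first and edges second, mirroring
  the node-term × edge-term structure of COEXsim.
- `planted_groups`: one base per group, members are independent
  perturbed siblings; all bases and controls share a small common node
  core (`between_overlap` fraction) whose edges are drawn independently,
  so cross-group similarity is weak but not exactly zero. Controls are
  independent networks, not siblings of anything.

All randomness flows through `numpy.random.Generator` streams spawned
from a single seed; regenerated outputs are byte-identical.

What the generator does *not* emulate: scale-free/modular degree
structure of real coexpression networks, correlated weights (weights
here are i.i.d.), and the soft-thresholding pipeline that produces
WGCNA modules. Passing tests therefore demonstrate that the measures
and calibration machinery behave as designed under controlled overlap;
they do not certify performance on any particular cohort's data.

A note on what the measures reward, visible in the generator tests:
fuzzy similarity grows steadily with edge retention (it is a mass
ratio), while COEXsim is nearly flat in retention once the common edge
set is reliably nonempty — its significance factor is a *relative mean
weight*, insensitive to how many edges survive. COEXsim instead tracks
node overlap. The two measures are complementary by construction, which
is why selection requires both.

## Calibrate-then-select experiment

The end-to-end synthetic experiment mirrors the two-stage shape of the
real workflow: thresholds are calibrated on groups of *moderately*
similar networks (node overlap 0.6, edge retention 0.6 — calibration
groups are related processes, not near-copies), then applied to a
separate set of strongly overlapping pairs (node overlap 0.8, edge
retention 0.8) plus controls. This matters structurally: the similar-
group median sits near the middle of the within-group score
distribution by construction, so a threshold calibrated on the *same*
population it is asked to recover would strictly exclude about half of
it. Calibrating on a weaker-overlap population and selecting on a
stronger one — exactly how the published procedure uses GO-term groups
to calibrate and disease-vs-aging modules to select — yields near-
complete recovery with no false selections in the package's acceptance
runs.

Problem sizes used in tests and the acceptance script: 120-node,
density-0.2 networks for the calibration/selection experiment (100
replicates in the test suite, 50 in the acceptance script); 40-node,
density-0.1 networks for the three-measure Spearman validation (the
graphlet baseline participates there, and exhaustive orbit counting is
the cost driver); ≤6-node graphs for the brute-force graphlet oracle.

## Numerical conventions

- Duplicate edge rows keep the maximum weight; edge endpoints are
  stored lexicographically sorted; self-loop rows are skipped with a
  warning (the node is kept).
- Default input transform is `abs`: signed correlation weights become
  magnitudes before the (0, 1] range check. `clamp01` caps weights at 1
  but treats nonpositive weights as errors; `none` validates as-is.
- Medians are midpoints of sorted values (mean of the two central
  values for even counts).
- Similarity matrices are written at 5 decimal places.
- Adjacency input must be symmetric to 1e-8; symmetry and identity
  properties of the measures are tested to 1e-12.

## Known limitations

- Orbit counting is exhaustive-enumeration based; dense networks beyond
  a few hundred nodes are out of its comfortable range.
- The exact orbit configuration used by any particular published GCD
  analysis may differ (the 73-orbit set is behind a flag; the default
  is the 15-orbit set); GCD here is a comparison baseline, not a
  reference implementation.
- Gold standards (e.g., GO semantic similarity) are consumed as
  precomputed matrices; computing them is out of scope.
- No significance test is attached to an individual pair score; the
  calibration thresholds are the intended decision device.
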