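# Methods

This note records the models, conventions and numerical choices behind
`wconn`, in the order the pipeline runs them.

## Edge-weight construction and post-processing

A streamline table holds one row per tractography streamline: canonicalized
endpoints (i < j), length in mm, COMMIT and SIFT2 weights, and per-metric
medians (R1 in 1/s, FA, RD, ICVF). The eight structural weightings are:

| weight | rule | volume-normalized |
| --- | --- | --- |
| NoS | streamline count per pair | yes |
| LoS | mean streamline length | no |
| SIFT2 | sum of SIFT2 streamline weights | yes |
| COMMIT | `alpha_ij = sum_k x_ijk l_k / Lbar_ij` | yes |
| R1, FA, RD, ICVF | mean across streamlines of per-streamline medians | no |

Node-volume normalization divides by the mean endpoint volume,
`W' = 2W / (v_i + v_j)`: symmetric, the identity for unit volumes, and
homogeneous of degree −1 in the volumes. Dividing by the *sum* instead
differs only by a global factor of 2 and would change nothing downstream;
the mean was chosen for its identity property.

Construction order mirrors two-stage tractogram filtering: NoS, LoS and
SIFT2 are built from the full table; streamlines with COMMIT weight below
1e-12 are then removed and COMMIT plus the four tractometry weightings are
built from the filtered table. The edge-level COMMIT filter afterwards
zeroes, per subject, every weighting at edges whose COMMIT weight is below
threshold, which makes the binary map identical across weightings within
subject — the premise that lets edge weights alone drive all comparisons
(checked programmatically in the tests). The group consensus mask keeps
edges nonzero in at least 50% of subjects, ties included (with an even
subject count, "half" is attainable and retained). Group averaging takes the
subject-wise mean per edge excluding zero entries; masked edges with no
nonzero entry stay zero and are counted in the build report.

FC is the Pearson correlation of node time series, Fisher-Z transformed with
r clipped to +-(1 - 1e-15) so a perfectly duplicated node yields a large
finite value instead of infinity.

## Synthetic cohorts

The generator's job is to reproduce the *statistical shape* of a real
multi-subject tractography cohort, at a scale where every downstream stage
runs in seconds. Defaults: 90 nodes in 8 modules (nodes placed at
module centers + 12 mm Gaussian scatter inside a 150 mm cube), 10 subjects,
target density 0.25, connection probability proportional to
`exp(-0.02 mm^-1 * d) * (1 + 1.5 * [same module])` rescaled to the target
density and forced connected by the Euclidean minimum spanning tree.
Volumes are lognormal around 1,000 mm^3 (sigma 0.3).

Couplings are imposed through a Gaussian copula on edge-level latents. For a
target Spearman rho the latent Pearson correlation is `r = 2 sin(pi rho / 6)`;
any monotone marginal transform then preserves the Spearman value exactly,
so lognormal marginals give the streamline-specific weightings their heavy
tails (sample skewness > 1) while affine-normal marginals keep tractometry
near-normal (|skewness| < 0.5) without disturbing the configured couplings.
Default length couplings: NoS −0.45, SIFT2 −0.45, COMMIT −0.60, RD −0.30,
R1 +0.40, FA +0.30, ICVF +0.30 — the sign pattern of the weight–length
relationships the analysis expects. NoS, SIFT2 and COMMIT share half of
their length-independent latent variance (they are all estimates of
connection strength), which is what propagates the FC coupling to all three.

The R1 latent adds a coupling to the length-independent part of the COMMIT
latent that depends on the edge-length tercile: −0.60 in the shortest
tercile, 0 in the middle, +0.35 in the longest. Pooled over all edges this
yields a modestly negative residual R1–COMMIT correlation (~−0.2) that is
negative for every subject, while binned correlations flip sign from the
shortest to the longest bin.

Streamline materialization: per-edge counts are rounded lognormal
(`log-mean 2.0`, sigma 0.7) carrying the *relative* volume factor so that
builder-side volume normalization recovers the engineered value; per-edge
COMMIT/SIFT2 totals carry the absolute volume factor for the same reason.
Lengths jitter around the Euclidean endpoint distance (sigma 5%, floored at
1 mm). A configurable fraction (default 0.3) of streamlines receives a
COMMIT weight below 1e-12; the edge total is distributed over the survivors
by a Dirichlet split, so filtering recovers the engineered edge value, and
an edge whose streamlines are all sub-threshold genuinely disappears.
Subjects share one topology and one set of edge latents; each subject gets
independent edge dropout (default 5%) and multiplicative weight noise
`exp(N(0, 0.2^2))`. With zero noise and zero dropout the cohort is
deterministic and all subjects are identical by construction.

FC time series are sampled from `Sigma = (1 - c) I + c R`, `c = 0.6`,
`T = 500`, where R is the eigenvalue-clipped positive-definite repair of
`I + A` and A carries *rank-normalized* group-SC weights (scaled to at most
0.9). The rank transform is deliberate: it is monotone (so every Spearman
relationship with SC survives) and gives all edges a workable coupling
magnitude, which raw heavy-tailed weights would not.

What the generator does **not** emulate: spatial autocorrelation of
weights beyond the distance kernel, hemispheric symmetry, realistic BOLD
autocorrelation (FC samples are i.i.d. in time), tractography biases such
as gyral-crown seeding, and any voxel-level structure. Passing tests on
synthetic cohorts therefore validate the *pipeline machinery and its
statistical behavior*, not claims about real brains.

Parameter-recovery convention: coupling recovery is measured on
subject-level edge values pooled across subjects (a 90-node, 10-subject
cohort yields ~9,000 masked edge observations), which is also how
subject-level points are pooled in the analyses themselves.

## Edgewise statistics

Quantiles use linear interpolation between order statistics (numpy default,
"type 7") everywhere, including the CQD. Zero edges are treated as absent
and excluded from every dispersion sample; a CQD with fewer than two usable
values, or with Q1 + Q3 = 0, is NaN and excluded downstream with counts
logged. Length bins: `w = (max - min) / 8`, five bins of width `w`, one
final bin of width `3w`; boundary values fall to the lower bin and the
global maximum to the final bin. Module scheme 2 assigns within-module edges
of VIS/SMN to "unimodal", of DMN/CONT/DAN/SVAN to "transmodal", and
everything else (between-module edges plus within-SUB/LIMB) to the third
group, so each edge lands in exactly one group.

Permutation testing permutes the edge labels of one vector uniformly
(`n_perm` draws), with `p = (1 + #extreme) / (n_perm + 1)`. The reported
convention is one-sided with the direction taken from the observed sign.
Note a sign-adaptive one-sided p is uniform on (0, 1/2] under the null —
that is a property of the convention, not a bug — so calibration checks fix
the direction explicitly (`direction="greater"`), under which the p-value is
uniform on (0, 1]. The permutation null preserves no spatial autocorrelation;
it is a deliberate, documented simplification.

## Null models

Binary surrogates use Maslov–Sneppen double-edge swaps ((a–b, c–d) ->
(a–d, c–b)), rejecting self-loops and multi-edges; the budget is counted in
*attempted* swaps (`swaps_per_edge * |E|`; attempted budgets are reproducible
across graphs, acceptance counts are not). Degree sequences are preserved
exactly — integer equality, never approximately. Weighted surrogates place
the original weight multiset (preserved exactly) on the rewired topology and
anneal weight-pair swaps toward the original strength sequence with energy
`E = sum_i (s_i - s_i_target)^2`, Metropolis acceptance, `T0 = 1e-3 * E0`,
geometric cooling 0.99 per sweep (one sweep = |E| proposals), at most 10^4
sweeps, early stop after 100 stagnant sweeps, returning the best state (so
best energy is non-increasing by construction). Ensemble generation at desk
scale uses a faster schedule (cooling 0.90, patience 20), which still
matches strengths to Pearson r > 0.999 on ~100-node networks; on graphs
small enough to enumerate, the default schedule attains the brute-force
global optimum. The hot loops are numba-compiled.

## Topology

Conventions, fixed once:

- Weights are max-normalized to (0, 1] before the `L = -log W` transform, so
  the strongest edge has length zero and absent edges are infinite. Inputs
  already on (0, 1] can skip the normalization (`normalize=False`).
  A uniform-weight network would map *every* edge to length zero; the
  continuous-limit semantics there is the hop count, so unit lengths are
  substituted. A single zero-length edge also makes shortest-*path counts*
  (not distances) formally ambiguous; path-based centralities resolve such
  ties by Dijkstra settle order, and oracle validation uses generic positive
  lengths where counts are well defined.
- Clustering is the Onnela geometric-mean triangle intensity on the
  max-normalized weights; with equal weights it reduces to the binary
  triangle fraction.
- Characteristic path length averages shortest-path distances over reachable
  ordered pairs, excluding self-pairs; partial disconnection is flagged with
  the unreachable-pair count, full disconnection is an error.
- Small-worldness normalizes clustering *within node* against the null mean
  for that node and then averages (nodes with zero null clustering are
  excluded and logged); path length is normalized by the null mean; `S` is
  the quotient. Degenerate null ensembles (copies of the observed network)
  give exactly S = 1.
- Betweenness (unnormalized) and closeness run on the -log length graph;
  eigenvector centrality is power iteration on W with a 5% diagonal shift
  (keeps the dominant eigenvalue unique on bipartite graphs without changing
  the eigenvector), tolerance 1e-10, at most 10^4 iterations.
- Hubness: +1 for membership in the top ceil(0.2 N) by strength,
  betweenness, closeness and eigenvector centrality, +1 for the bottom
  ceil(0.2 N) clustering; rank ties break by node index, which makes scores
  deterministic on symmetric graphs.
- Rich-club degree k always uses the binary map. The weighted coefficient
  divides the weight inside the degree->k subgraph by the sum of the equally
  many strongest weights anywhere in the network (the ranked-weight
  estimator); the binary coefficient is the subgraph density. Normalization
  divides by the null-ensemble *mean* curve; detection is the strict
  `phi_norm > 1` criterion (with a 1e-9 guard against float-exact ones), no
  significance test. At extreme k the club subgraph holds O(1) edges and the
  observed curve is a single draw whose sampling noise dwarfs any tolerance,
  so quantitative self-consistency checks restrict to k levels with at least
  10 club edges.

The planted-structure validation network deserves a note: its topology is a
*degree-typical* sample (bimodal degree sequence realized by Havel–Hakimi and
then heavily Maslov–Sneppen randomized), so the observed graph is itself
typical of the degree-preserving null distribution and the planted rich club
lives entirely in the weights (core–core edges 2.5x stronger). This is what
makes the shuffled-weight control clean: with a topologically atypical dense
core, detection would leak through the binary structure and no weight
shuffle could abolish it.

## Pipeline

A single JSON config drives `simulate -> build -> stats -> nulls ->
topology`. The `desk` preset (60 nodes, 6 subjects, 20/50 nulls, 1,000
permutations) is sized for interactive runs; the `paper` preset pins the
study-scale constants (50/1,000 nulls, consensus 0.5, COMMIT threshold
1e-12, 6 bins, 414 nodes, 50 subjects). Every random draw derives from the
master seed via fixed-offset child seeds recorded in the manifest; stages
re-run only when their recorded input hashes change, and identical
config+seed reproduces identical artifacts. The acceptance script and test
suite run everything at desk scale — 90-node cohorts, 20-null small-world
and 200-null rich-club ensembles — sizes chosen so the full validation
completes in minutes on a single core while keeping every estimator in its
well-behaved regime.

## Known limitations

- The permutation null ignores spatial autocorrelation; p-values on real
  spatially smooth maps would be optimistic.
- Strength matching is approximate by construction (exact degree, exact
  weight multiset, annealed strengths); on networks whose strength sequence
  is a near-sufficient statistic for weight placement, weighted rich-club
  effects are intrinsically hard to detect against these nulls.
- The FC generator produces temporally white series; autocorrelation-driven
  variance inflation of correlation estimates is not modeled.
- Tractometry weightings are simulated directly at the edge-latent level;
  partial-volume blurring is mimicked only as low dispersion, not as spatial
  mixing.
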