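# Methods

This note records the models implemented in `lollinet`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate.

## Walk model

A weighted undirected network with nonnegative weights w_ij (in the intended
application, absolute partial correlations |ρ_ij| between regional time
series) defines degrees d_i = Σ_j w_ij. Plain row normalization
p_ij = w_ij/d_i destroys the distinction between strongly and weakly
connected nodes — a node with three 0.1-weight edges gets the same
transition probabilities as one with three 0.9-weight edges. The self-loop
normalization fixes the total degree of every node at d_ref (by default the
network's maximum degree d_max) by adding a self edge of weight d_ref − d_i.
The resulting chain has transition matrix P′ = A′/d_ref, is irreducible
whenever the underlying positive-weight graph is connected (self loops
cannot disconnect it), and is aperiodic as soon as any node has a positive
self loop. Self loops count as steps: a weakly connected node spends most of
its time in place, which is the intended physical reading of reduced
connectivity.

**Reference degree.** `normalize(graph, d_ref=...)` accepts an external
reference degree ≥ the graph's own d_max. This matters for the
chain-isolation study: subtracting a constant from every edge weight of a
graph is otherwise a pure rescaling, and hitting times are scale-invariant
(P′, ℒ and H are unchanged when all weights are multiplied by c > 0 — a
property test asserts this). Normalizing each decayed graph against the
*baseline* graph's d_max converts the removed edge weight into self-loop
mass, so a uniform weakening of the network slows the walk and raises mean
hitting times, as it should under the reading that lower overall activity
means lower connectivity rather than a relabeling of the same walk.

## Hitting times: three routes

- **Spectral** (the production route): eigendecomposition of the symmetric
  normalized Laplacian ℒ = I − P′ (symmetric because D′ is a multiple of
  the identity), then
  h_ij = Σ_{k>1} (d′/λ_k)(μ_kj²/d′_j − μ_ki μ_kj/√(d′_i d′_j)), which with
  uniform normalized degrees reduces to N·Σ_{k>1}(μ_kj² − μ_ki μ_kj)/λ_k.
  Eigenvalues are sorted ascending and the null eigenvector is identified
  by λ < 10⁻¹⁰ rather than trusting index order; if more than one
  eigenvalue falls below the tolerance the graph is reducible and the
  computation is refused. The formula is basis-invariant within repeated
  eigenspaces, so the orthonormal basis `eigh` returns is sufficient; the
  maximally degenerate case (K_n, one (n−1)-fold eigenvalue) is covered by
  a test against the closed form h = n − 1.
- **Linear** (first oracle): for each target j, the first-step equations
  h_ij = 1 + Σ_k p′_ik h_kj solved directly. Exact to solver tolerance and
  implementation-independent of the spectral route.
- **Monte-Carlo** (second oracle): mean first-visit step counts over
  simulated trajectories, with standard errors; walks exceeding a step cap
  are censored, and more than 1% censoring voids the estimate.

Agreement between all three (spectral vs linear to 10⁻⁶ relative on random
weighted graphs; Monte-Carlo within 3 SE) is asserted in the test suite.
Disconnected input is an error, not an infinite hitting time: the spectral
formula divides by λ₂, and every downstream statistic presumes a single
component. Degrees below 10⁻¹² are treated as isolated nodes.

A classical anchor: every off-diagonal hitting time of the complete graph
K_n equals n − 1 exactly (normalization is a no-op on regular graphs), which
both solvers reproduce to 10⁻⁸ for n up to 100.

## Tail statistics

**Kelley skewness** is the percentile contrast P90 + P10 − 2·P50, computed
with linear interpolation between order statistics (numpy's default
percentile rule; the value depends on this convention, so it is fixed and
documented). The **raw** form, in hitting-time units, is the package
default: group effects on hitting-time distributions are differences of
tens of steps, which the bounded coefficient form (divided by P90 − P10,
confined to [−1, 1]) cannot express. The coefficient form is available
behind a flag. Distributions whose spread is floating-point noise relative
to their magnitude (a complete graph's hitting values) are treated as
degenerate: raw Kelley reports 0, the coefficient and the normality test
report undefined rather than amplified round-off.

**Pearson skewness** is the moment coefficient g₁ = m₃/m₂^{3/2} — the most
common referent of the name in statistical software — used descriptively
alongside the D'Agostino–Pearson omnibus normality test (scipy's
implementation; z statistic for skewness plus the 2-df combined χ²).

**Chain index.** For a node i with incident weights sorted descending
(ties broken toward the lower node index), let i₁, i₂ carry the two largest
weights w₁ ≥ w₂. The node sits on a chain motif iff w₂ strictly exceeds
every remaining incident weight and the two strong neighbors are only
weakly connected to each other: w(i₁,i₂) < γ·w₂, with γ = 0.5 by default
(the source analysis gives no threshold; γ is exposed as configuration).
Then ζ_i = w₁ + w₂ − Σ remaining weights; interior nodes of an isolated
unit path score the maximum ζ = 2, and ζ strictly decreases as off-path
weight accumulates. Exact ties between w₂ and the third weight fail the
strictness condition. Nodes not on a motif carry ζ = NaN.

**Chain motifs.** Two counts are provided. `count_chain_motifs` counts
induced 3-node paths (open triads) after binarizing at a threshold
(default: any positive weight), via Σ_j C(deg_j, 2) − 3·#triangles, with an
exhaustive triple-enumeration oracle for small graphs.
`count_chain_motif_nodes` counts nodes satisfying the chain-motif
membership rule above; on unit-weight graphs this means degree-2 nodes with
non-adjacent neighbors — genuine three-node linear pieces. The distinction
matters in the modularity regression (below).

## Synthetic generators

- Graph families: complete; lollipop (clique + path attached at one clique
  node; the package uses the path-equals-one-third split as the
  hitting-maximal default); G(n,m) and G(n,p) Erdős–Rényi; Watts–Strogatz
  rings (defaults ring_k = 4, β = 0.1, the conventional small-world regime
  — the source gives no parameters); stochastic block models with
  p_in = 0.7, q_out = 0.1 and community sizes drawn uniformly from
  [30, 170] until the node budget is filled, the last community truncated.
  The size range is the package's choice: it reproduces the reported
  regimes of 2–6 communities and Louvain modularity ≈ 0.03–0.43 at 180
  nodes, the low end arising from draws with one dominant community.
  Generators that must deliver connected graphs redraw with an incremented
  seed up to a bounded retry count. All randomness flows through one seeded
  `numpy` generator per call; no global state.
- Chain-isolation sequences: baseline G(50, p=0.6) with unit weights; a
  10-node simple path sampled by a self-avoiding random walk (bounded
  retries). In `isolate_chain` mode every edge incident to a chain node
  *except* the consecutive path edges — including chain-internal chords —
  loses δ = 0.05 per iteration for 19 iterations, leaving cross weights at
  0.05; in `global_reduction` mode every edge decays. Weights that would
  cross zero clamp at 10⁻⁶ with a warning to preserve connectivity. All
  iterations are normalized against the baseline d_max (see above).
- Gaussian panels: T iid draws from N(0, Ω⁻¹) with Ω_ij = −c·w_ij off the
  diagonal and Ω_ii = 1 + c·d_i (strict diagonal dominance guarantees
  positive definiteness; violations raise with the offending coupling
  named). The population partial correlation is then positive exactly on
  the structure's edges. Temporal autocorrelation, hemodynamics, motion and
  physiological confounds are deliberately absent: only the spatial
  conditional-independence pattern matters to the statistics under test, so
  passing recovery tests says nothing about preprocessing robustness on
  real scans.

## Partial-correlation estimation

Columns are standardized, the covariance estimated with Ledoit–Wolf
shrinkage by default (180 regions against typical scan lengths make the raw
covariance ill-conditioned; a fixed shrinkage in [0,1] and the raw inverse
for small exact cases are also available), then
ρ_ij = −Ω_ij/√(Ω_ii Ω_jj) from the precision matrix Ω, symmetrized and
clipped to [−1, 1] within 10⁻¹² tolerance. Singular or extremely
ill-conditioned covariances are refused with advice to use shrinkage.
Partial correlations are computed per subject; group averaging is an
explicit separate step, never implicit concatenation.

## Simulation studies and their scales

Problem sizes were chosen so each study runs in seconds to a couple of
minutes on one core while keeping its statistical claim testable:

- `run_family_comparison` (100 nodes, 100 reps for the stochastic
  families): lollipop max hitting > 120,000; complete-graph Kelley exactly
  0; lollipop Kelley an order of magnitude beyond random and small-world.
  At reduced size (n = 20) the lollipop-dominance and
  lollipop > random > complete orderings persist, but small-world Kelley
  turns slightly negative, so no ordering against the complete graph is
  claimed for it at that scale.
- `run_isolation_study` (50 nodes, 100 seeds): isolation raises final
  Kelley skewness in ≥ 95% of seeds; global weakening raises the mean in
  ≥ 95% while its relative skewness change stays below the isolation
  mode's.
- `run_modularity_regression` (edge grid 200–1000 by 50 and 1000–2500 by
  100, 10 graphs per grid point, connected draws only — about 300 usable
  graphs per master seed against 15,243 in the original sweep): OLS of
  Kelley skewness on edge count, Louvain modularity and the chain-motif
  count. The motif regressor defaults to `count_chain_motif_nodes`: the raw
  induced-path count is nearly a deterministic function of the edge count
  in G(n,m) (correlation > 0.99), which makes the two coefficients jointly
  unidentifiable, whereas the membership count varies independently within
  an edge level and yields a motif coefficient near +10 alongside a
  strongly positive modularity coefficient. The edge-count coefficient is
  tiny and shares most of its variance with modularity (r ≈ −0.9 across
  the grid); its sign is not stable in this pipeline and comes out
  slightly positive — a known limitation documented rather than tuned
  away.
- `run_sbm_study` (180 nodes, 40 graphs per batch, disconnected or
  degenerate draws filtered): Kelley skewness regressed on Louvain
  modularity and mean degree, both robustly negative — block models
  without chain topologies still produce skewness, which is why the chain
  index (and not skewness alone) is needed to attribute skewness to linear
  structure.
- `run_lollipop_sweep` (99 nodes, all clique/path splits): the split
  maximizing the maximum hitting time. The classical one-third result
  concerns the simple degree-normalized walk, which is the sweep's default
  and lands at exactly m* = 33; under the self-loop normalization the
  path's large self loops slow it disproportionately and the maximizing
  fraction shifts to ≈ 0.42 — both walks are exposed.

Louvain community detection is delegated to networkx's seeded
implementation; modularity of a complete graph is 0 (single community), and
the two-clique-plus-bridge oracle value 20/21 − 1/2 anchors the test.

## Group harnesses

`compare_nodes` runs per-node two-sample or paired t tests on to-hitting
profiles (column means of H excluding the diagonal) or chain indices
(NaN off-motif entries omitted pairwise), Bonferroni-adjusts over the
number of nodes, and ranks by absolute effect; top-k extraction (k = 10 by
convention) is built in. Family-wise type-I control under identical groups
is property-tested.

`fit_skewness_model` regresses per-subject skewness on a contrast plus
covariates: unpaired designs use OLS with dummy-coded group (explicit
reference), dummy-coded gender (reference female) and mean-centered age;
paired designs reduce the subject random effect to within-subject
differences regressed on covariates — the paired-contrast equivalent of a
random-intercept model, which fully captures a two-condition
subject pairing without mixed-model machinery. Rank-deficient designs,
single-level contrasts and unbalanced pairings are refused.

## Known limitations

- The walk model is undirected and ignores the sign of partial
  correlations (weights are |ρ|); anticorrelation structure is invisible.
- The Gaussian panel generator emulates only spatial conditional
  dependence; claims about real fMRI preprocessing chains are out of scope.
- The sign of the edge-count coefficient in the modularity regression is
  not identifiable at the scales this package runs (see above).
- Hitting times require a connected graph; pipelines fail loudly (with the
  stage name) rather than imputing infinite values.
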