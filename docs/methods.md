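# Methods

## Network construction

A subject's structural connectome is a weighted, undirected graph over the
90 cortical + subcortical regions of the AAL parcellation. Edges are
defined by deterministic-tractography streamline counts: regions i and j
are connected when FN_ij ≥ t with t = 3 by default (inclusive — an edge
with exactly three streamlines survives, which is how a "threshold of 3"
is conventionally applied). The weight is

    w_ij = FN_ij · FA_ij / ((V_i + V_j)/2),

fiber count times the tract's mean fractional anisotropy, normalized by
the arithmetic mean of the two region volumes (mm³) so that large regions,
which accumulate more spurious streamlines, are not over-weighted. FA is
taken as provided; no FA floor is applied before weighting.
`validate_threshold_stability` recomputes all global metrics for t = 1…5
so threshold sensitivity can be inspected; raising t can only remove
edges, never add them.

Matrices read from disk are symmetrized by averaging the two triangles
when the asymmetry is within 1e-8 (write-out round-off); larger asymmetry
is rejected as corrupt, since tractography connectivity matrices are
nominally symmetric. Node order is fixed by the atlas file; indices are
0-based internally and 1-based in reports.

## Graph metrics

Path-based metrics use edge length 1/w, the convention of the weighted
brain-network toolbox lineage (stronger connections are shorter). All-pairs
shortest paths are computed with Dijkstra's algorithm on the sparse length
graph; disconnected pairs are ∞.

- Cp is computed on the binarized topology of the thresholded graph:
  cc_i = E_i / (D_i(D_i−1)/2) with E_i the number of edges among i's
  neighbours, 0 for degree < 2, averaged over all N nodes. A weighted
  (Onnela geometric-mean) variant exists behind
  `clustering_coefficient(net, weighted=True)` but is not the default,
  because the edge-counting form is the standard printed definition.
- Eg = (1/(N(N−1))) Σ_{i≠j} 1/L_ij; disconnected pairs contribute zero.
- Lp is the harmonic-mean characteristic path length, i.e. exactly 1/Eg.
  This identity (asserted to 1e-10 in tests) keeps Lp finite for graphs
  with isolated pairs; no largest-component restriction is applied. A
  fully edgeless graph gets Lp = ∞ with a warning.
- Eloc is the mean over nodes of Eg of the weighted subgraph induced on
  each node's neighbours (the node itself excluded); subgraphs with fewer
  than two nodes contribute zero.
- Betweenness is Brandes' algorithm (networkx) on the weighted graph,
  unnormalized: B(i) sums δ_jk(i)/δ_jk over unordered pairs, so a star
  centre on m leaves scores m(m−1)/2. A normalized variant (divide by
  (N−1)(N−2)/2) is available for cross-size comparison. Shortest-path tie
  counting uses exact float equality; with continuous weights, distinct
  paths tie only when their lengths are bit-identical, and the exhaustive
  enumeration oracle (which uses a 1e-12 relative tie tolerance) agrees
  with it on every tested instance.

## Null models and small-worldness

γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩, σ = γ/λ, with the null means taken
over 100 degree-preserving random networks per subject (default; the
ensemble size is a parameter). Nulls are built by Maslov–Sneppen
double-edge swaps — pick edges (a,b), (c,d), replace with (a,d), (c,b)
unless a self-loop or duplicate would result — with each edge's weight
travelling through the swap, so both the degree sequence and the edge
weight multiset are exact invariants of every draw. Ten accepted swaps
per edge (with a bounded number of attempts) is the default mixing
intensity; degenerate graphs with no legal swap return unchanged with a
warning. Seeding is hierarchical: one master seed, per-null generators
spawned as `SeedSequence(master, spawn_key=(k,))`, making ensembles
bit-reproducible and order-independent. σ is computed per subject and
then averaged, not on group-mean networks.

## Group statistics

- One-way ANOVA (scipy omnibus) with post hoc pairwise t tests on the
  pooled within-group error and Bonferroni adjustment (p_adj = min(1, 3p)
  for three groups), run only when the omnibus p < 0.05 — the SPSS-style
  recipe.
- `anova_from_summary` rebuilds the omnibus F from per-group means, SDs
  and sizes alone (SSB about the weighted grand mean; SSW = Σ(n_g−1)sd²),
  which lets printed demographic tables be checked without raw data; it is
  exactly `anova_oneway` when the summaries are exact.
- ANCOVA is a full-versus-reduced linear-model comparison: the partial F
  for the group factor compares metric ~ group + covariates against the
  covariates-only model. With no covariates this reduces to one-way
  ANOVA. Default covariates: age, sex (encoded M=0/F=1), education. The
  pipeline defaults to ANCOVA for the global metrics; plain ANOVA is a
  config switch.
- Partial correlation regresses both variables on the covariates and
  takes the Pearson correlation of the residuals, with a t-based p value
  on n − 2 − k degrees of freedom.
- Hub reports average nodal betweenness within a group and take the top
  ceil(0.10·N) regions (9 of 90). An exact tie at the cutoff keeps the
  lower region index and warns; ties do not occur with continuous data.
- Region-wise betweenness comparisons are run on all 90 regions,
  uncorrected by default (Bonferroni and Benjamini–Hochberg FDR are
  switches), and every report carries the chosen mode. Score
  correlations run within each patient group, restricted to the regions
  with significant group differences unless `correlate_all_regions` is
  set.

## Synthetic cohort generator

The generator emulates a memory-clinic cohort (default 36 NC / 21 SCD /
33 aMCI) so the full pipeline is testable without clinical data.

Base topology: a ring lattice over 90 regions with k = 8 neighbours,
each edge rewired to a uniform random target with probability p = 0.1
(Watts–Strogatz construction, implemented directly so the rewired edge
set is known). The rewired edges are the long-range shortcuts. The
disease effect multiplies the FN and FA means on shortcut edges and on
edges incident to one designated hub region (PCUN.R, the right
precuneus) by (1 − a), with a = 0.15 for SCD and 0.30 for aMCI — a
graded disconnection of distant regions, recorded in the ground-truth
record rather than asserted as biology. Because FN and FA attenuate
jointly, the edge weight FN·FA/volume inherits the effect monotonically,
and the constraint a_SCD ≤ a_aMCI guarantees the planted ordering
Eg(NC) > Eg(SCD) > Eg(aMCI) in expectation.

Per-edge draws: FN ~ negative binomial (mean 20, dispersion 5; realistic
overdispersed streamline counts), FA ~ Beta(2,2) scaled to [0.2, 0.7]
(white-matter FA range), shared symmetrically per edge; volumes ~
lognormal(log 8000 mm³, 0.3). Each subject also carries a global
lognormal FN scale (σ = 0.15) representing between-subject differences in
tract count yield; this is the dominant source of between-subject
variance in Eg (total CV ≈ 0.16) and was set, once, so that at the design
sample sizes the NC–aMCI efficiency contrast is well powered while the
NC–SCD contrast usually is not — the significance pattern the cohort is
meant to exhibit. Demographics are group-independent (age ~ N(62, 9²)
truncated to 50–80 y, education ~ N(10.5, 4²) truncated at 0, P(F) = 0.6),
so covariates are non-confounding by default.

Cognitive scores follow score = intercept_group + slope·z(B_hub) + ε:
group intercepts near published memory-clinic norms (e.g. MMSE
28.1/27.9/25.0), and the delayed-recall score additionally loads on the
subject's hub betweenness, standardized by constants (centre 140, scale
110) measured once under the default spec, with slope 1.05 and noise SD
2.4 giving a planted partial correlation near 0.4. Scores use an
independently spawned generator, so skipping them (`with_scores=False`)
leaves the network draw bit-identical.

What the generator does **not** emulate: anatomical edge geometry,
distance-dependent connection probability, realistic regional volume
covariance, measurement noise correlated across neighbouring tracts, or
any true biology of SCD/aMCI. Passing tests therefore demonstrate that
the pipeline recovers effects of the planted kind at realistic sizes and
noise levels — not that it would detect any particular clinical effect.

## Numerical and design choices

- Weight matrices are re-symmetrized as (W + Wᵀ)/2 after construction so
  symmetry is exact despite float arithmetic.
- ANCOVA returns F = 0 when the covariates-only model already fits to
  numerical precision (relative residual < 1e-12), avoiding a 0/0 ratio.
- Rank-deficient designs raise an error naming the first collinear
  column.
- Problem sizes in the test and acceptance suites are chosen for
  single-CPU runs: metric-oracle equivalence uses 200 random graphs of at
  most 8 nodes (exhaustive path enumeration is exact there); the
  σ > 1 sweep uses 100 synthetic subject networks at 30 nulls each
  (single-network σ checks use the full 100); planted-effect recovery
  uses 50 cohorts and type-I calibration 200 cohorts at the full
  90-subject design.
- The pipeline accepts a `threads` option as API surface; results are
  independent of it by contract and the current implementation is
  serial.

## Known limitations

- Betweenness tie handling differs in principle from a tolerance-based
  count when two paths have *nearly* equal lengths; with continuous
  weights this is unobservable, but exactly-weighted integer graphs with
  near-tie path sums could count differently than a tolerant oracle.
- Eloc recomputes Dijkstra per neighbour subgraph, which is O(N · k³)
  per network — fine at N = 90, slow for atlases an order of magnitude
  larger.
- The generator's group effect lives only on shortcut and hub-incident
  edges; analyses sensitive to lattice-edge properties will see no group
  difference by construction. Even at extreme attenuation (a → 1) global
  efficiency falls only to roughly 60 % of the control mean, because the
  intact lattice backbone still carries all pairs.
- With a single designated hub region, hub-identity differences between
  groups (beyond the planted betweenness reduction) are emergent, not
  controlled.
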