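# Methods

## Model and procedure

The pipeline analyzes a subjects × regions table of mean cortical
thickness (mm) on a fixed 64-region parcellation (32 gyral-based regions
per hemisphere).  The covariance network is a group-level object: one
matrix per group, with entry (i, j) the Pearson correlation of the
age/sex-adjusted thickness residuals of regions i and j.  Adjustment is
ordinary least squares on an intercept + age + sex design; with two
nuisance covariates this residualize-then-correlate route is the partial
correlation and is numerically stable at the small group sizes (≈38) the
design targets.  Covariate columns that are constant within a subject
subset are absorbed by the intercept rather than treated as an error,
because permuted subgroups can legitimately end up single-sex.

Binarization keeps exactly `round(S·N(N−1)/2)` edges (half-up rounding;
the choice of rounding rule is conventional and documented rather than
derived).  Edges are ranked by signed correlation by default — positive
covariance is read as connectivity, the common convention for thickness
networks — with `ranking="absolute"` available since the treatment of
negative correlations is genuinely open.  Ties at the cutoff break by
correlation descending then lexicographic (i, j) ascending, making edge
sets bit-reproducible and nested across the sparsity grid.

### Graph statistics

All graphs are undirected, unweighted; distances are hop counts computed
by a level-synchronous all-pairs BFS (boolean matrix powers), exact and
fast at N = 64.  Whole-network measures: `E_glob` (mean 1/d over ordered
pairs, 1/∞ = 0) and `E_loc` (mean over nodes of `E_glob` of the
neighbor-induced subgraph; nodes with < 2 neighbors contribute 0).
Per-node: degree, clustering `C_i = 2T_i/(K_i(K_i−1))` (0 for K < 2),
Brandes betweenness with fractional counting over tied shortest paths
(the verbal "number of shortest paths that pass" is ambiguous under
ties; fractional counting matches standard toolboxes), and
`B_i = b_i/mean(b)` so the hub threshold 1.5 reads as "1.5× the average
region"; when every b_i is 0 (complete graphs) B_i is defined as 0.

The hierarchy exponent β is −slope of the OLS fit of log C on log K over
nodes with K ≥ 2 and C > 0 — the only defensible domain for a log–log
fit; raw per-node points are fitted without degree binning.  Fits with
fewer than two eligible nodes or no degree spread raise rather than
return a number, and the permutation machinery records such levels as
missing (NaN), never as zero.

Modularity uses seeded Louvain optimization of Newman Q (networkx),
with module ids renumbered by smallest member for determinism.  No
Kernighan–Lin refinement pass is added: on the validation fixtures
(two-triangles bridge, exhaustively verified optimum Q = 5/14; planted
2-block graphs at p_in = 0.9 / p_out = 0.05) the seeded Louvain pass
already attains the planted optima, so refinement would add code paths
without measurable benefit at these graph sizes.  Participation
coefficient `P_i = 1 − Σ_m (K_im/K_i)²` and within-module degree z-score
`Z_i` (population SD; Z = 0 where a module's SD is 0) are computed
directly.

### Subsystems, hubs, inter-system efficiency

Inter-system efficiency between systems A and B is the mean of 1/d over
cross-system pairs, with distances taken in the subgraph induced by
A ∪ B: "the connection submatrix" implies paths may not route through
third systems, and the two readings genuinely differ.  Within-union
pairs of the same system are excluded from the average.

Hub rule: `B_i > 1.5` and `K_i > mean K`, means over all 64 regions, at
the hub sparsity (default 0.23, the level at which both groups' networks
are typically fully connected).  Level: strictly below-mean clustering →
hierarchically high.  The inequality is strict; in the degenerate case
where every clustering coefficient equals the mean (e.g. a pure star,
all C = 0) no hub can classify as high.  Connector classification
defaults to `P > 0.05`, `Z > 1.0`; the thresholds are exposed because
published usage is inconsistent (0.05 vs 0.6 for P appear side by side
in the literature this follows), and 0.05/1.0 is the operative pair for
the connector-hub counts reported there.

### Permutation inference

For each of `n_perm` permutations, subjects are reassigned to groups of
the original sizes and the full construction — residualization, partial
correlation, ranking, binarization at every grid level, metric — is
recomputed; covariates stay attached to subjects.  The p-value is the
add-one estimator `(1 + #{null ≥ observed})/(n_perm + 1)` (never exactly
zero); the significance flag is exceedance of the 95th percentile of the
null in the configured tail, matching the critical-value convention.
Tail direction is explicit per metric (default: group 1 > group 2).  No
correction is applied across sparsity levels; per-level tests are
reported as-is, a deliberate limitation inherited from the analysis
convention this implements — neighboring levels are strongly dependent
(nested edge sets), so significant runs of levels should be read
qualitatively.  Randomness comes from one `numpy` Generator seeded with
the root seed; permutations are drawn sequentially from it, so results
are platform-reproducible bit for bit.

## Synthetic cohorts

The generator emulates the data the pipeline expects rather than the
imaging process: regional thickness is
`mu_j + β_age·age + β_sex·sex + sd·(λ f_{s(j)} + ε)`, with one latent
factor per subsystem, factor correlation matrix Φ, `λ = √within_r` and
`sd(ε) = √(1 − within_r)`.  Population correlations are then exactly
`within_r` within a subsystem and `between_r` across (Φ_st is set to
`between_r/within_r`); positive definiteness of Φ is checked and
violations raise a configuration error.  Group B multiplies selected
Φ entries by a deficit factor, changing only the targeted inter-system
coupling.  Defaults: 81 + 38 subjects, means uniform on 2–4 mm,
`sd = 0.2` mm, `within_r = 0.5`, `between_r = 0.15`, age uniform on
25–40 y with slope −0.01 mm/y, sex effect 0.05 mm, balanced Bernoulli
sex.  A 0.5 mm floor clips pathological draws; if more than 0.1% of
values hit it the configuration is rejected as not thickness-like.

What the generator does **not** emulate: spatial autocorrelation on the
cortical surface, hemispheric asymmetries, non-Gaussian thickness
distributions, scanner/site effects, and any real relationship between
the five-subsystem partition and anatomy.  Passing tests therefore
demonstrate the pipeline's statistical behavior (calibration, power,
determinism, metric correctness), not that any particular clinical
contrast will reproduce on real data.

The packaged region→subsystem map satisfies the published counts
(14/14/18/10/8) and anatomical anchors, but a handful of borderline
assignments (precuneus, isthmus cingulate, inferior temporal, transverse
temporal) are reconstructions; the map ships as data so users can
substitute their own.

## Numerical and design choices

- Half-up edge-count rounding; stable argsort for tie-breaking.
- Hop-count BFS via boolean matrix powers; O(diameter·N³) bit-ops,
  exact, and the fastest option at N = 64 inside the permutation loop.
- Degenerate inputs raise typed errors (zero-variance residual column
  naming the region, collinear designs, edgeless graphs for modularity,
  under-determined hierarchy fits) rather than returning sentinels.
- Type-I calibration runs 200 null-cohort replicates of 30 + 15
  subjects at 200 permutations over a 5-level grid — group sizes scaled
  to keep the full validation suite comfortably re-runnable while
  leaving the per-test permutation machinery identical to production
  settings; empirical rejection ≈ 0.05 (asserted within [0.02, 0.08]).
- Power validation plants a 50% executive–language coupling deficit
  (within_r 0.6, executive–language between_r 0.30 halved in group B) at
  the full 81/38 design and 500 permutations over all 34 levels.

## Limitations

Weighted-network generalizations, small-world σ, rewired-null
normalization and Fisher z-transformed correlations are out of scope.
Power against realistic (small) deficits at n = 38 is modest — the
planted-deficit validation detects the effect at only a minority of
sparsity levels, and detection count varies with the random seed — which
is a property of group-level covariance designs at this sample size, not
of the implementation.  The inter-system efficiency is computed on the
union subgraph; analyses that allow routing through third systems will
produce systematically higher values.
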