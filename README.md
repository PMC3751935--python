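# corticonet

Structural covariance network analysis of regional cortical thickness.

Across a group of subjects, the thicknesses of cortical regions that are
anatomically or functionally coupled rise and fall together.  Treating the
inter-regional correlation of thickness as connectivity yields a
*structural covariance network* whose graph topology — integration,
segregation, hubs, hierarchy, modules — can be compared between clinical
groups.  `corticonet` implements that pipeline end to end for researchers
working with region-averaged thickness tables (e.g. FreeSurfer
Desikan–Killiany output):

1. **Network construction** — each region's thickness is adjusted for age
   and sex by OLS residualization; residuals are correlated pairwise
   (a partial correlation); the matrix is binarized at fixed sparsity
   `S`, keeping exactly `round(S·N(N−1)/2)` strongest edges so networks
   compared across groups have identical edge counts.  The default grid
   is `0.07 ≤ S ≤ 0.40` in steps of 0.01 (34 levels).
2. **Graph topology** — global efficiency
   `E_glob = ⟨1/d_ij⟩` and local efficiency `E_loc` (mean efficiency of
   each region's neighbor subgraph); per-region degree `K_i`, clustering
   `C_i`, betweenness `b_i` and its mean-normalized form
   `B_i = b_i/⟨b⟩`; the hierarchy exponent `β` of the power law
   `C = k^−β`; Newman modularity `Q` with participation coefficient
   `P_i` and within-module degree z-score `Z_i`.
3. **Subsystem analysis** — the packaged 64-region parcellation assigns
   each region to one of five functional systems
   (strategic/executive 14, language 14, mnemonic/emotional 18,
   sensorimotor 10, visual 8).  Inter-system integration is the mean
   inverse shortest path length `1/L` over cross-system pairs inside the
   two systems' induced subgraph.  Hubs are regions with `B_i > 1.5` and
   above-mean degree (at the hub sparsity, default 0.23); below-mean
   clustering puts a hub at a hierarchically high level.
4. **Permutation inference** — group differences in any of these
   statistics are tested by relabeling subjects (group sizes preserved)
   and recomputing the *entire* construction per permutation; the 95th
   percentile of the null is the one-tailed critical value at α = 0.05.
5. **Synthetic cohorts** — a latent-factor generator produces two-group
   cohorts with subsystem-aligned covariance blocks, age/sex
   confounding, and plantable inter-system coupling deficits, so the
   whole pipeline is testable with known ground truth.

## Worked example

```python
from corticonet import (default_parcellation, generate_cohort,
                        partial_correlation_matrix, binarize_at_sparsity,
                        global_efficiency, local_efficiency)

pmap = default_parcellation()          # 64 regions, 5 subsystems
cohort = generate_cohort(pmap, seed=1) # 81 + 38 synthetic subjects
corr = partial_correlation_matrix(cohort.thickness_a, cohort.covariates)
net = binarize_at_sparsity(corr, 0.23)
print(net.edge_count, global_efficiency(net), local_efficiency(net))
```

prints `464 0.5586 0.8561`: at sparsity 0.23 the 64-region network keeps
464 of the 2016 possible edges; the mean inverse path length between
regions is 0.56 (well integrated) and the average neighborhood
efficiency is 0.86 (strongly clustered).  Running
`examples/03_permutation_inference.py`, which plants a 50% reduction of
executive–language coupling in the smaller group, prints

```
1/34 sparsity levels significant at alpha=0.05
sparsity 0.16  diff 0.3588  crit95 0.3525  p 0.0479
group B lower at 74% of levels (planted direction)
```

— the observed drop in inter-system efficiency exceeds the permutation
null's 95% point at one sparsity level, and the deficit group sits below
the intact group at 74% of levels.  The `examples/` directory holds one
short script per capability; the `corticonet` CLI (`simulate`,
`build-network`, `metrics`, `hubs`, `internetwork`, `permtest`,
`run-all`) exposes the same stages for shell use, with `run-all` writing
correlation matrices, edge lists, metric curves, hub tables, permutation
results and a reproducibility manifest.

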