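# wmnet

Weighted white-matter connectome analysis for three-group clinical cohorts
(normal controls, subjective cognitive decline, amnestic mild cognitive
impairment), built for network-neuroscience researchers who start from
tractography-derived connectivity matrices rather than raw diffusion MRI.

## What it computes

Each subject contributes a 90×90 fiber-number (FN) matrix, a 90×90 mean
fractional-anisotropy (FA) matrix and a vector of AAL-90 region volumes.
An edge survives when its streamline count reaches the threshold
(default 3) and is weighted

```
w_ij = FN_ij · FA_ij / ((V_i + V_j) / 2)
```

On each weighted network (edge length ≡ 1/w) the package computes:

- **Cp** — mean clustering coefficient, Cp = (1/N) Σᵢ Eᵢ / (Dᵢ(Dᵢ−1)/2),
  with Eᵢ the realized edges among node i's neighbours;
- **Eg** — global efficiency, Eg = (1/(N(N−1))) Σ_{i≠j} 1/L_ij;
- **Lp** — characteristic path length in its harmonic-mean form, Lp = 1/Eg
  (finite even with disconnected pairs);
- **Eloc** — local efficiency, the mean over nodes of Eg of each node's
  neighbour-induced subgraph;
- **γ, λ, σ** — Cp and Lp normalized by their means over 100
  degree-preserving random networks (Maslov–Sneppen double-edge swaps that
  carry weights, preserving the degree sequence and weight multiset), with
  σ = γ/λ > 1 indicating small-world organization;
- **B_nod** — nodal betweenness centrality, B(i) = Σ_{j≠i≠k} δ_jk(i)/δ_jk
  over weighted shortest paths; the top 10 % of regions by group-mean
  betweenness (9 of 90) are reported as hubs.

Group statistics follow the standard clinical recipe: one-way ANOVA or
ANCOVA (age, sex, education) with Bonferroni-corrected pairwise post hocs,
Pearson χ² for sex tables, ANOVA recovered from printed mean±SD summaries,
and partial correlation between nodal betweenness and cognitive scores
(MMSE, MoCA, AVLT) within patient groups.

Because clinical diffusion data of this kind are rarely shareable, the
package includes a first-class synthetic cohort generator: a
Watts–Strogatz-style base topology whose long-range (rewired) and
hub-incident edges are attenuated in a graded NC < SCD < aMCI fashion,
with covariate-linked cognitive scores and a ground-truth record, so every
pipeline stage is testable end to end.

## Worked example

```python
from wmnet import CohortSpec, ConnectomeCohortModel

spec = CohortSpec(n_per_group={"NC": 10, "SCD": 8, "aMCI": 10}, master_seed=42)
model = ConnectomeCohortModel.from_cohort_spec(spec, n_nulls=20, seed=42)
results = model.fit()
print(results.summary())
```

```
                   Weighted White-Matter Connectome Cohort Analysis
======================================================================================
Subjects: NC=10, SCD=8, aMCI=10
FN threshold: 3   nulls/subject: 20   stats: ancova (covariates: age, sex, education)
--------------------------------------------------------------------------------------
Global metrics (group mean +/- SD; group test)
metric                    NC                 SCD                aMCI        F        p
Cp            0.4438+/-0.003     0.4403+/-0.0059     0.4426+/-0.0046    1.437   0.2592
Lp            1952+/-2.3e+02      2204+/-3.3e+02      2479+/-3.4e+02    8.160   0.0022
Eg       0.0005193+/-6.7e-05 0.0004626+/-6.9e-05 0.0004105+/-5.9e-05    7.077   0.0042
Eloc     0.0007292+/-0.00011 0.0006882+/-9.8e-05  0.0006865+/-0.0001    0.611   0.5515
gamma           6.166+/-0.11        5.988+/-0.25        6.071+/-0.15    1.373   0.2742
lambda_        1.135+/-0.021       1.167+/-0.029       1.276+/-0.029   79.615   0.0000
sigma           5.434+/-0.12        5.129+/-0.17        4.762+/-0.18   46.747   0.0000
--------------------------------------------------------------------------------------
Hubs [NC] (top 10% betweenness): SFGmed.R, TPOmid.R, SMG.R, ORBmid.R, MOG.R, ...
...
```

Reading the output: every group is small-world (σ ≫ 1, γ ≫ 1, λ near 1),
while global efficiency falls and path length rises monotonically from NC
through SCD to aMCI — the planted disconnection gradient — with a
significant group effect on Eg and Lp (ANCOVA p < 0.01) and none on Cp.
Per-subject metric tables, per-group hub reports, region-wise betweenness
comparisons and score correlations hang off `results`
(`results.global_metrics`, `results.hubs`, `results.nodal_comparisons`,
`results.correlations`), and `results.plot_global_metrics()` draws the
bar/error summaries.

The same analysis runs from the shell on delimited-text inputs:

```sh
wmnet simulate --out cohort/ --seed 7          # write fn_/fa_/vol_ files + subjects.csv
wmnet run --subjects cohort/subjects.csv --out results/ --seed 7
wmnet metrics --fn fn_NC001.csv --fa fa_NC001.csv --vol vol_NC001.csv
wmnet nulls --edge results/mean_network_NC.edge --n-nulls 100
```

`wmnet run` writes `global_metrics.csv`, `nodal_metrics.csv`,
`group_comparison.csv`, `nodal_comparison.csv`, `hubs_<group>.csv`,
`correlations.csv`, BrainNet-style `.node`/`.edge` files, and a
`manifest.json` sufficient to reproduce the run byte-for-byte.

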