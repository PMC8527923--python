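# immunotme

Quantitative analysis of the tumor immune microenvironment for multiplexed
imaging and tumor immunogenomics, built for studies that ask which features
of a tumor separate patients who benefit durably from anti-PD1 immunotherapy
(DB) from those who do not (nDB) — in particular in hypermutated colorectal
cancer, where antigen-presenting CD68+CD74+ macrophages and their spatial
interactions with cytotoxic (GzB+) and proliferating (Ki67+) CD8 T cells are
candidate correlates of response.

The package covers five layers:

* **Pixel analysis** — threshold masks per marker, boolean mask algebra, and
  marker-positive areas normalized over tissue or compartment (tumor/stroma)
  masks derived from tumor-associated markers (E-cadherin, pan-keratin).
* **Single-cell phenotyping** — per-marker min–max intensity normalization
  with percentile clipping, cell-identity assignment by highest mask
  overlap, and threshold gating of named subpopulations (CD74 ≥ 0.1 on
  macrophages, GzB ≥ 0.05 and Ki67 ≥ 0.15 on CD8 T cells, ...).
* **Spatial statistics** — nearest-neighbour distance distributions in
  1.1-μm bins; density-based (DBSCAN) clusters of a phenotype, annotated
  against the ≥5 cells/10,000 μm² high-density criterion; cluster fractions,
  cluster co-occupancy, co-infiltration correlations and high/low-region
  abundance ratios.
* **Immunogenomics** — tumor mutational burden with the 12 mutations/Mb
  hypermutation cutoff; the neoantigenic index (immunogenic / nonsilent
  mutations); clonality of immunogenic mutations via a closed-form
  cancer-cell-fraction estimator,
  `CCF = VAF · (p·CNt + (1−p)·2) / (p·m)`,
  with a 0.8 clonal threshold and a >30% purity filter; and productive TCR
  clonality, `1 − H/ln R`, with H the Shannon entropy of productive
  clonotype frequencies.
* **Statistics** — two-sided Wilcoxon rank-sum (exact for small samples),
  Benjamini–Hochberg FDR over explicitly declared family sizes, Pearson
  correlation, and single-sample gene-set enrichment (ssGSEA) for signature
  scoring such as Wnt transcriptional targets.

Because patient-level imaging/sequencing data of this kind are rarely
public, the package ships a first-class synthetic-data generator
(`immunotme.synthetic`) that emulates all input kinds with known planted
effects — clustered CD74+ macrophages with PD1+ T cells placed at controlled
distances, group-level differences in marker proportions, mutation catalogs
with controlled clonal/immunogenic fractions, and repertoires solved to a
target clonality — so every stage is testable end to end.

## Worked example

```python
from immunotme import synthetic as syn
from immunotme.config import PipelineConfig
from immunotme.pipeline import run_pipeline

# 6 DB vs 6 nDB patients, 3 regions each; plant a 0.15 difference in the
# CD74+ macrophage fraction and PD1+ satellite T cells at 15 um (DB) vs
# 60 um (nDB) from macrophage clusters
spec = syn.CohortSpec(
    n_db=6, n_ndb=6, regions_per_patient=3,
    base_scenario={"pd1_distance_um": 37.5},
    effect_sizes={"cd74_fraction": 0.15, "pd1_distance_um": -45.0},
    seed=0,
)
result = run_pipeline(PipelineConfig(), syn.generate_cohort(spec))
print(result.comparisons[["contrast", "p", "q", "median_difference"]].to_string())
```

prints

```
                              contrast             p         q  median_difference
0        cd74_mac_proportion_DB_vs_nDB  1.261945e-03  0.002524           0.142240
1  cd74_mac_cluster_fraction_DB_vs_nDB  2.589743e-01  0.258974           0.022222
2           nn_distance_PD1_vs_rest_DB  3.227837e-07       NaN         -42.386952
```

The planted 0.15 proportion difference is recovered
(`median_difference ≈ 0.14`) and declared significant after BH correction
(`q < 0.05`), and PD1+ GzB+ T cells sit a median ~42 μm closer to CD74+
macrophages than their PD1− counterparts — the negative shift expected when
PD1+ cells are planted as satellites of PDL1+ macrophage clusters. The
pooled distance contrast is reported without a q-value because it is not a
member of the per-patient BH family.

The same stages are scriptable from a shell (`immunotme simulate|pixels|
phenotype|spatial|genomics|stats|run --help`).

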