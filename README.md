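# trajcluster

Temporal state-sequence clustering of pre-index health trajectories.

Given long-format claims-style event calendars (one row per dated event per
patient), the package encodes each patient's year before an index therapy
start as a daily categorical sequence, compresses the cohort into
representative *patient-medoids* (K-means on per-state meta-features,
followed by within-partition Hamming-medoid selection), clusters the medoids
with weighted Ward agglomeration on the Hamming distance matrix, orders the
resulting clusters by severity, profiles them (median/IQR, count/percent,
chi-square and one-way ANOVA), and compares post-index survival between
clusters (Kaplan–Meier, log-rank, Cox proportional hazards — all implemented
from their defining formulas).

A synthetic claims-data generator produces cohorts with four trajectory
archetypes (ambulatory/single-stay, repeated recent exacerbations, frequent
exacerbations across the year, and long-stay) plus archetype-ordered
post-index mortality, so the whole pipeline is testable without any
restricted data.

## Command-line usage

The full pipeline in one call (simulate → select → encode → compress →
cluster → profile → survive; writes a JSON manifest and delimited-text
artifacts for every stage):

```bash
trajcluster run --out myrun --seed 1 --n 5000
```

Each stage is also runnable standalone, so any intermediate artifact can be
inspected or replaced:

```bash
trajcluster simulate --n 5000 --seed 1 --out sim
trajcluster select   --events sim/events.csv --covariates sim/covariates.csv --out sel
trajcluster encode   --events sim/events.csv --included sel/included.csv --out seq.csv
trajcluster compress --sequences seq.csv --k 100 --seed 1 --out comp
trajcluster cluster  --medoids comp --sequences seq.csv --n-clusters 4 --out clus
trajcluster profile  --labels clus/labels.csv --covariates sim/covariates.csv \
                     --events sim/events.csv --out profile.csv
trajcluster survive  --labels clus/labels.csv --covariates sim/covariates.csv --out surv
```

`trajcluster run --config run.yaml` accepts a YAML file with any
`RunConfig` field (seed, cohort size, medoid count `k_medoids`, cut size
`n_clusters`, selection rules, stage skips with user-supplied inputs, ...).

## Library layout

| module | contents |
| --- | --- |
| `trajcluster.simulate` | `GeneratorConfig`, `generate_cohort`, `generate_patient` |
| `trajcluster.cohort` | `SelectionRules`, `select_cohort`, attrition table |
| `trajcluster.encoding` | `StateAlphabet`, `encode`, sequence round-trip IO |
| `trajcluster.medoids` | meta-features, `compress`, homogeneity score |
| `trajcluster.cluster` | Hamming matrix, weighted Ward linkage, cut, severity ordering, weighted silhouette, visualization raster |
| `trajcluster.profiling` | stratified tables, chi-square, one-way ANOVA, comorbidity-score binning |
| `trajcluster.survival` | Kaplan–Meier, log-rank (global/pairwise), Cox (Breslow/Efron) |
| `trajcluster.pipeline` | `RunConfig`, `run_pipeline`, manifest |

Notes on the method:

* The homogeneity score between a patient and its medoid is
  `100 × (1 − hamming/T)`; with `k` equal to the number of distinct
  sequences it is exactly 100 and it is non-decreasing in `k`.
* Ward linkage is applied to the Hamming matrix through the Lance–Williams
  recurrence with observation weights equal to medoid member counts; with
  unit weights it reproduces `scipy.cluster.hierarchy.linkage(..., "ward")`
  exactly, and with integer weights it equals scipy's Ward on the
  weight-expanded data. Ward's variance reading assumes Euclidean geometry,
  so on Hamming distances it is the customary approximation.
* The silhouette value is computed on weighted medoids (each medoid standing
  for its members at distance zero).
* The naive `O(K³)` agglomeration is intended for the desk-scale medoid
  counts used here (hundreds); it is not tuned for `K` in the thousands.

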