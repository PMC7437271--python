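# brainaging

Analysis toolkit for cross-sectional brain-structure aging in elderly
cohorts: intracranial-volume (ICV) normalization, group-stratified aging
slopes (annual percent change) with percentile-bootstrap confidence
intervals, CI-non-overlap group comparisons, APOE-ε4 effect sizes as
bootstrapped slope differences, and normative volume tables stratified by
ethnicity × sex × 5-year age bin.

Because the source cohort data are not redistributable, the package ships a
first-class synthetic-cohort generator whose defaults encode the published
group demographics, APOE-ε4 carrier frequencies, and group-level aging
slopes, so every downstream stage is fully testable offline.

## Layout

| Module | Purpose |
| --- | --- |
| `brainaging.cohort` | Subject/cohort domain types, cognitively-normal screening, APOE genotype calls from rs429358/rs7412, CSV/TSV cohort I/O |
| `brainaging.regions` | The 15 composite regions and their parcel composition (editable YAML: `src/brainaging/data/regions.yaml`) |
| `brainaging.freesurfer` | Parsers for `aseg.stats` / `?h.aparc.DKTatlas.stats` and composite-region aggregation |
| `brainaging.simulate` | Group specs, defaults, and the seeded cohort generator |
| `brainaging.regression` | Pooled volume ~ age + sex + ethnicity + education + ICV regression, Bonferroni threshold, 2×2 ANOVA from cell summaries |
| `brainaging.slopes` | APC estimation, bootstrap CIs, CI-overlap comparisons, APOE effects |
| `brainaging.norms` | Normative tables and per-subject z-scoring |
| `brainaging.pipeline` / `brainaging.cli` | End-to-end runs, manifests, CLI |

## CLI

```bash
# simulate a cohort with the built-in four group specs
brainaging simulate --seed 1 --out cohort.csv

# aging slopes with 10,000-iteration bootstrap CIs + pairwise decisions
brainaging slopes cohort.csv --out slopes.csv --comparisons cmp.csv --seed 1

# APOE-e4 effects, normative tables, z-scores
brainaging apoe cohort.csv --out apoe.csv --seed 1
brainaging norms cohort.csv --out norms.csv
brainaging zscore cohort.csv norms.csv --out z.csv

# everything at once (regression, slopes, comparisons, APOE, norms, manifest)
brainaging run-all --cohort cohort.csv --out-dir out/ --seed 1

# aggregate FreeSurfer subject directories into volume rows
brainaging aggregate SUBJ_DIR [SUBJ_DIR ...] --out volumes.csv
```

Identical config + seed produces byte-identical outputs; one master seed
expands into per-(group, region) substreams so results do not depend on
processing order.

## Conventions

- **Relative volume** = 100 × volume / ICV (percent of ICV).
- **APC** = OLS slope of relative volume on age within a group, expressed
  as percent of the group-mean relative volume per year.
- **Bootstrap** = subject-level resampling with replacement, percentile
  CIs; degenerate resamples are redrawn so exactly B estimates enter each CI.
- **CI comparison**: two groups differ iff their CIs are disjoint
  (touching endpoints count as overlap).
- Binary codings in the pooled regression: female=0/male=1,
  korean=0/caucasian=1.
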