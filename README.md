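# augtrial

Analysis toolkit for multi-location **augmented block design** germplasm
trials: check-based adjustment of unreplicated test entries, augmented and
combined ANOVA, variance components with derived selection-genetics
statistics (GCV/PCV/ECV, broad-sense heritability, genetic advance),
Shannon–Weaver diversity for qualitative descriptors, multivariate structure
(Pearson correlation, PCA, UPGMA and K-means clustering), check-relative
selection and micronutrient screening, plus a synthetic trial generator with
known variance structure so every stage is testable without external data.

## Layout

| Module | Purpose |
| --- | --- |
| `augtrial.trial_data` | Long-format trial CSV + trait dictionary I/O, validation, sqrt transform of count traits |
| `augtrial.augmented_design` | Block adjustments, adjusted means, per-location augmented ANOVA, combined across-location ANOVA |
| `augtrial.genetic_parameters` | Variance components, CVs, heritability, genetic advance, classification scales |
| `augtrial.qualitative_diversity` | Category proportions, Shannon–Weaver H′, equitability, chi-square heterogeneity |
| `augtrial.multivariate` | Correlation matrix, PCA with loading-importance flags, UPGMA (Newick export), K-means, cluster summaries |
| `augtrial.selection_screening` | Percent gain over the best check, threshold screens for grain Fe/Zn |
| `augtrial.synthetic_data` | Simulation configs, trial generator, heritability parameter-recovery harness |
| `augtrial.pipeline` | One-config orchestration of all stages with a run manifest |

## CLI

All commands operate on a long-format trial CSV (`genotype, role, location,
block, trait, value`) plus a trait-dictionary CSV (`name, kind, units,
categories, transform`; categories pipe-separated).

```sh
augtrial simulate --seed 42 --out trial.csv          # synthetic trial + dictionary
augtrial validate trial.csv --dict trial_traits.csv
augtrial adjust   trial.csv --dict trial_traits.csv --out adjusted.csv
augtrial anova    trial.csv --dict trial_traits.csv --out anova.csv
augtrial genpar   trial.csv --dict trial_traits.csv --out genpar.csv
augtrial diversity trial.csv --dict trial_traits.csv --out diversity.csv
augtrial correlate trial.csv --dict trial_traits.csv --out corr.csv
augtrial pca      trial.csv --dict trial_traits.csv --out-prefix pca
augtrial cluster  trial.csv --dict trial_traits.csv --k 4 --seed 0 --out-prefix clust
augtrial select   trial.csv --dict trial_traits.csv --trait YLD --min-gain 12 --out sel.csv
augtrial screen   trial.csv --dict trial_traits.csv --fe-min 60 --zn-min 32 --out screen.csv
augtrial run      --config run.yaml                  # full pipeline + manifest.json
augtrial recover  --replicates 200 --seed 1          # heritability recovery study
```

A minimal `run.yaml`:

```yaml
out_dir: outputs
trial_csv: trial.csv
traits_csv: trial_traits.csv
kmeans_k: 4
k: 2.056
```

## Conventions worth knowing

- Adjustment rule: test value − (block check mean − grand check mean);
  check entries report raw means over blocks. On complete designs this
  equals the least-squares estimate of the genotype mean from
  `y = μ + block + genotype`.
- Combined ANOVA uses one adjusted mean per genotype × location cell
  (test entries present everywhere); G and E are tested against G×E, and
  G×E against the pooled intra-block (checks × blocks) error.
- Variance components: GV = (MS_G − MS_G×E)/n_env (truncated at 0),
  EV = MS_G×E, PV = GV + EV.
- Equitability defaults to H′/ln(number of accessions); pass
  `basis="categories"` for the textbook normalization.
- Classification scales use continuous boundaries
  (low ≤ 10 < moderate ≤ 20 < high; heritability low ≤ 30 < medium ≤ 60 < high).
- Nutrient screens are strict (`>`), gain selection is inclusive (`>=`).
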