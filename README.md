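# cryptax

An integrative cryptic-species delimitation toolkit.  It re-implements, as
a tested and reusable pipeline, the four quantitative strands commonly
combined when near-identical species must be told apart:

- **morphostats** — per-character boxplot summaries (95%-coverage whiskers)
  and Tukey–Kramer HSD comparisons between species, per character.
- **mra** — multivariate ratio analysis of 25 linear measurements:
  isometric size / zero-sum log-shape decomposition, shape PCA, PCA and
  allometry ratio spectra with bootstrap confidence intervals, and an
  exhaustive LDA ratio extractor (best and second-best discriminating body
  ratio, standard distances, and a size-vs-shape δ statistic).
- **gma** — landmark geometric morphometrics: TPS I/O for 7-landmark wing
  configurations, generalized Procrustes analysis (proper rotations only,
  canonical output orientation), tangent-space PCA, canonical variate
  analysis, and a landmark-permutation test for the correlation of group
  covariance matrices.
- **barcode** — DNA-barcode analysis: p and Kimura-2-parameter distances
  with pairwise deletion, within-species haplotype collapsing,
  intra/interspecific distance summaries, the barcode gap, canonical
  neighbour joining with column-bootstrap branch support (Newick output),
  and pure (species-fixed, exclusive) diagnostic characters.
- **datagen** — a synthetic three-species generator that plants known
  structure in all three data types (lognormal measurements with
  allometry, mean shapes under random similarity transforms, species-fixed
  diagnostic substitutions plus polymorphism at a chosen
  transition/transversion odds), so every downstream stage can be tested
  against ground truth.
- **pipeline** — YAML-configured orchestration of all stages with a
  deterministic, machine-readable `summary.json`.

## CLI

Runs are driven by a YAML config:

```yaml
# config.yaml
scenario:            # omit and set `inputs:` paths to use your own data
  seed: 11
  n_per_species: 12
seed: 11
params:
  alpha: 0.05
  n_boot: 200        # ratio-spectrum bootstrap resamples
  n_perm: 999        # covariance-matrix permutation test
  n_reps: 200        # NJ bootstrap replicates
  metric: k2p
```

```sh
cryptax all --config config.yaml --out results/run1
cryptax barcode --config config.yaml --out results/barcode-only --seed 3
```

User data goes through `inputs:` instead of `scenario:`:
`measurements` (CSV with `specimen_id`, `species` and the 25 character
columns), `landmarks` (TPS with `ID=specimen|species` records),
`sequences` (aligned FASTA, `id|species` headers supported) and
`partition` (two-column CSV).  Each stage writes tidy CSV/JSON/Newick
outputs plus a combined `summary.json`; identical configs produce
byte-identical summaries.

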