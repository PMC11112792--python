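# latdiv

Macroevolutionary analysis of latitudinal diversity gradients for a single
clade: why does species richness peak where it does? The package implements
the full desk-scale workflow used to dissect an *inverse* latitudinal
diversity gradient (richness peaking in the temperate zone rather than the
tropics) into the contributions of **evolutionary time**, **diversification
rate**, and **niche conservatism** — together with a seeded synthetic-data
generator that stands in for the sequence, occurrence and climate downloads
a real study would use.

## What it computes

Given an ultrametric chronogram (Newick, ages in Ma), occurrence records
(species, lon, lat), present-day temperature rasters (MAT, MTWM, MTDQ) and a
paleotemperature curve T(t):

- **Tree operations** (`latdiv.trees`) — validation of ultrametricity,
  random grafting of unsampled species into named clades (preserving all
  existing divergence times exactly), per-tip species ages, and the DR tip
  speciation rate: the inverse of the equal-splits measure
  ES_i = Σ_j l_j 2^−(j−1) along the root-to-tip path.
- **Occurrence QC** (`latdiv.qc`) — the five standard coordinate filters
  (missing, lat = lon, zero/integer coordinates, in sea, outside the native
  range), nearest-cell climate extraction, and climate-variable selection by
  greedy |r| ≥ 0.75 collinearity pruning followed by a PCA.
- **Ancestral niche** (`latdiv.niche`) — species climate means and
  maximum-likelihood Brownian-motion ancestral states via the two-pass
  peeling algorithm (equivalent to GLS with the BM covariance,
  â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x at the root), with exact finite-sample t intervals.
- **Paleoenvironment-dependent diversification** (`latdiv.divmodels`) —
  birth–death likelihoods with λ(t), μ(t) constant, linear or exponential in
  T(t), computed by propagating E′ = μ − (λ+μ)E + λE² from the present and
  telescoping the branch flow integrals; crown-conditioned on the survival
  of both crown lineages; a seven-model registry ranked by
  AICc = −2logL + 2k + 2k(k+1)/(n−k−1).
- **Spatial pattern** (`latdiv.spatial`) — a 100 km × 100 km cylindrical
  equal-area (Behrmann) grid; per-cell richness, evolutionary time (oldest
  species age), mean DR, and the deviation-from-ancestral-niche score
  Σ_v norm(|present_v − ancestral_v|) over v ∈ {MAT, MTWM, MTDQ}; LOESS
  (tricube, degree 2) latitudinal profiles.
- **Synthetic data** (`latdiv.simulate`) — seeded generators for
  temperature-forced birth–death chronograms (thinning simulation), BM
  thermal niches, a latitudinally structured climate field, and occurrence
  records with injected violations of each QC filter, all with recorded
  ground truth for recovery tests.

## Worked example

Run the bundled synthetic fixture end to end (simulate → clean → niche →
divrate → spatial → profile):

```bash
latdiv run --config examples/fixture.yaml --out demo_out
```

The manifest it prints (and writes to `demo_out/manifest.tsv`):

```
   stage                     key       value
     run          latdiv_version       0.1.0
     run             master_seed          11
simulate                  n_tips          48
simulate            crown_age_ma       37.44
simulate    n_occurrence_records         384
   clean              records_in         384
   clean         removed_missing           5
   clean    removed_equal_latlon           8
   clean removed_zero_or_integer           7
   clean          removed_in_sea           5
   clean    removed_out_of_range           6
   clean             records_out         353
   niche                root_mat     8.93115
 divrate              best_model lambda_expT
 divrate               best_aicc     292.931
 spatial                 n_cells         346
 profile       peak_lat_richness       43.89
```

Reading it: a 48-species chronogram with a 37.44 Ma crown was simulated
under cooling-forced speciation; 31 of 384 occurrence records were removed,
in the proportions injected by the generator (records in = records out +
Σ removed, an identity the pipeline asserts). The reconstructed root MAT is
8.9 °C, AICc selects a temperature-dependent speciation model, and the
LOESS richness profile peaks at 43.9 °N — a temperate, not tropical, peak:
the inverse-gradient signature the workflow is built to dissect.

Every product is tab-delimited text in the output directory
(`tree.nwk`, `occurrences_clean.tsv`, `ancestral_roots.tsv`,
`model_selection.tsv`, `cells.tsv`, `profiles.tsv`, …), and a rerun with the
same config and seed is byte-identical.

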