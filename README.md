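# phenokit

Image-based plant phenotyping, grain yield scoring, trait-model selection
and mixed-model GWAS — a desk-scale re-implementation of the software core
of a high-throughput rice phenotyping facility and its downstream
association analysis, fully testable on synthetic data.

## What it does

- **`phenokit.imaging`** — segments green plants from side-view images
  (excess-green index + Otsu), and extracts a frozen 33-descriptor
  catalogue per view: projected area, 25 morphological descriptors
  (plant height, plant compactness = area / convex-hull area, solidity,
  circularity, skeleton statistics, ...) and 7 GLCM texture descriptors
  (contrast, dissimilarity, homogeneity, energy, correlation, entropy,
  variance). Views are aggregated per plant (mean by default).
- **`phenokit.traits`** — predicts measured traits (shoot fresh/dry
  weight, green leaf area) from image features via feature-grouped
  all-subsets regression over four model families (A, AM, AT, ATM),
  scored with AIC, adjusted R² and the PRESS statistic; the final model
  must beat smaller families by configurable margins. Evaluation by
  test-set R² / MAPE and k-fold cross-validation.
- **`phenokit.grains`** — counts bright grains on a dark background
  (Otsu + debris filter + distance-transform watershed for touching
  pairs), measures per-grain length/width from the minimum-area rotated
  rectangle, and derives spikelet fertility, yield per plant and
  1,000-grain weight.
- **`phenokit.gwas`** — MAF/MAC SNP filtering, identity-proportion
  kinship, a spectrally transformed linear mixed model with
  likelihood-ratio tests, block-eigenvalue effective marker number N with
  1/N and 0.05/N thresholds, haplotype-frequency LD r², greedy clumping
  and an optional peak-support filter.
- **`phenokit.synth`** — procedural generators with exact ground truth:
  plant renders, grain scatter scenes, and genotype/phenotype simulations
  (Balding–Nichols structure, copying-chain LD, stated heritabilities).
- **`phenokit.io` / `phenokit.pipeline` / `phenokit.cli`** — minimal VCF
  and table IO, provenance-stamped outputs, and the umbrella CLI.

## CLI

```sh
phenokit simulate population --n 100 --m 2000 --seed 1 --out sim/
phenokit features --images imgs/ --views-per-plant 12 --out features.csv
phenokit train --features features.csv --trait fresh_weight --out model.json
phenokit predict --model model.json --features new.csv --out preds.csv
phenokit grains --total-image a.png --filled-image b.png --weight-g 21.4 \
    --calibration 0.1 --out batch.csv
phenokit gwas --vcf geno.vcf --pheno pheno.csv --trait plant_height --out results/
```

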