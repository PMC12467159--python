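# octatex

Texture-histogram classification for greyscale vascular-layer images
(e.g. en-face OCTA slabs). The package implements two pipelines:

1. **Whole local texture features** — dense local binary pattern coding
   (generic LBP or rotation-invariant-uniform *riu2*) or BRIEF coding with a
   noise-adaptive 3σ threshold, summarised as per-image histograms,
   concatenated across anatomical layers per eye, and classified with a
   KNN/SVM hyper-parameter grid under stratified 10-fold cross-validation.
2. **Reduced features** — the same histograms standardised (population σ)
   and projected by a PCA retaining 95% of the variance, fitted inside each
   training fold, before classification.

Because clinical datasets of this kind are private, the package ships a
seeded synthetic generator (`octatex.synthetic`) producing two-class
vascular-like textures (filamentous curves vs. added blob/dropout lesions)
with controllable separability, so every stage is testable end to end.

## Layout

| module | role |
|---|---|
| `octatex.io` | PNG/TIFF reading, manifest CSV (`eye_id,layer,label,path`) |
| `octatex.lbp` | circular-sampling LBP / riu2 codes + histograms |
| `octatex.brief` | BRIEF sampling patterns, noise estimate, dense coding |
| `octatex.features` | per-eye concatenated feature matrices, 15 layer combinations |
| `octatex.dimreduce` | standardisation, PCA, 95%-variance component selection |
| `octatex.evaluation` | stratified 10-fold CV, Mann-Whitney AUC, KNN/SVM grids |
| `octatex.synthetic` | seeded synthetic datasets and tiny hand-checkable fixtures |
| `octatex.cli` | `octatex` command: simulate / extract / reduce / evaluate / report |

## CLI quick start

```bash
# 1. simulate a seeded two-class dataset (PNGs + manifest.csv)
octatex simulate --n-eyes 30 --lesion-density 1.0 --seed 42 --out data/

# 2. evaluate: riu2 p=8 r=1, reduced features, KNN grid, one layer
octatex evaluate --manifest data/manifest.csv --task healthy_vs_wet \
    --descriptor lbp_riu2 --mode reduced --layers superficial \
    --grid knn --seed 42 --out report.json

# 3. summarise the top configurations
octatex report --report report.json
```

`--layers all_15` sweeps every one of the 15 layer combinations (4 singles,
6 pairs, 4 triples, all four). `--grid full` runs the complete KNN (k ∈
{1,3,5,7,9} × euclidean/manhattan/chebyshev) and SVM (C ∈ {0.1,…,100} ×
linear/rbf/poly with γ and degree grids) search.

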