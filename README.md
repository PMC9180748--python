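# lysoquant

Desk-scale analysis pipeline for lysosome-focused quantitative
proteomics and lipid-droplet imaging, built around the study designs
used in neuronal ceroid lipofuscinosis (NCL) disease models: knockout
cell lines and mouse brain compared against wild type through
lysosome-enriched, label-free protein quantitation, followed by
annotation-based curation of the lysosomal proteome and
fluorescence-image quantification of lipid storage.

## What it computes

**Differential expression.** From a proteins × samples intensity table
a protein is called differentially expressed (DEP) when it passes four
filters: ≥ 2 unique peptides used for quantitation, identification
FDR < 0.01, fold change |FC| ≥ 1.5 (cell lines; 1.3 for mouse-brain
datasets) computed from averaged, normalized intensities, and one-way
ANOVA p ≤ 0.05. FC magnitude is max(r, 1/r) of the ratio of group
means, so up- and down-regulation pass symmetrically.

**Lysosomal confidence scoring.** Each DEP is scored against three
layers of annotation evidence:

| layer | criterion | points |
|---|---|---|
| 1 | bovine lysosomal SWATH dataset | TrEMBL 1, SwissProt 2 |
| 1 | rat lysosomal proteome | Misc 1, endo-lysosome (EL) 2 |
| 2 | hLGDB / mLGDB (combined) | 2 |
| 2 | UniProtKB reviewed, keyword "lysosome" | 2 |
| 2 | Compartments confidence *c* (GO:0005764) | 2 < *c* < 4 → 1, 4 ≤ *c* ≤ 5 → 2 |
| 2 | Human Protein Atlas lysosomal localization | 2 |
| 3 | reported in another NCL-model lysosomal dataset | 2 |

Totals span 0–14 and map onto tiers: 6–14 very high (vHC), 3–5 high
(HC), 1–2 medium (MC); proteins scoring 0 are discarded.

**Cross-model overlap.** Set intersections of DEP lists across disease
models, and a presence matrix of high-confidence DEPs against external
NCL study gene lists (the data behind a cross-study heat map).

**Lipid-droplet quantification.** Local mean thresholding of the lipid
stain channel (BODIPY-type), connected-component particle analysis,
and the droplet gates circularity 4πA/P² > 0.6 and area > 3 µm²;
counts are normalized to the number of nuclei (Hoechst-type channel,
Otsu + minimum area).

Every stage runs on synthetic inputs produced by seeded generators in
`lysoquant.simulate`, so the full pipeline is testable without any
download.

## Worked example

```python
from lysoquant import (DEPParams, DifferentialExpression, gen_quant_dataset,
                       gen_annotation_catalogs, score_dataset)

matrix, meta, truth = gen_quant_dataset(n_proteins=1000, frac_dep=0.1, seed=42)
results = DifferentialExpression(matrix, meta, "case", "control",
                                 params=DEPParams(min_fc=1.5)).fit()
print(results.summary())

catalogs, _ = gen_annotation_catalogs(matrix.protein_ids, p_lyso=0.3, seed=43)
print(score_dataset(results.deps, catalogs).summary())
```

```
Differential expression (case vs control)
==============================================
proteins              1000
testable              1000
untestable (excluded) 0
fold-change gate      ≥ 1.5
p-value gate          ≤ 0.05
DEPs called           16

Lysosomal confidence scoring
==========================================
proteins scored       16
scheme maximum        14
tier vHC  count       6
tier HC   count       0
tier MC   count       3
tier LOW  count       7
retained (score ≥ 1)  9 (56.2%)
```

Of 1000 simulated proteins (10% carrying a planted 2-fold effect, but
most excluded by the identification filters), 16 pass all four DEP
filters; scoring them against synthetic annotation catalogs retains 9
at medium confidence or better, 6 of them very high.  The same
session's image quantification:

```python
from lysoquant import gen_ld_image, quantify
img, _ = gen_ld_image(droplets=[(10+8*i, 10+3*i, 1.5) for i in range(4)],
                      nuclei=[(15+10*i, 40, 4.0) for i in range(3)], seed=7)
print(quantify(img).summary())
```

```
Lipid-droplet quantification
==================================
objects segmented   4
droplets kept       4
nuclei counted      3
droplets per cell   1.333
```

All four planted 1.5 µm droplets survive the circularity/area gates
and are normalized to the three nuclei.

A command-line interface wraps the same stages:

```sh
lysoquant simulate --seed 3 --out demo/
lysoquant run-full demo/quant_table.tsv --config demo/config.yaml
lysoquant ld-quant demo/ld_image.tiff --pixel-size 0.1 --out demo/
```

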