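# ngi-contexture

Analysis toolkit for **sequential chromogenic multiplexed IHC** ("next-generation
IHC"): one FFPE tissue section is stained, scanned and destained six times —
Foxp3, CD3, CD8, CD4, Ki67 and cytokeratin (CK), each over a hematoxylin
counterstain — and the six single-stain scans are fused computationally into a
virtual multiplexed image. The package reconstructs that image, phenotypes
every cell, quantifies the tumour-immune contexture in space, and provides the
cohort-level statistics used to analyse such trials. Because per-cell data
from clinical trials of this kind are rarely public, the package ships a
ground-truthed synthetic slide and cohort generator, so every stage is
testable end to end.

Intended users: computational pathology and tumour-immunology groups working
with serial single-plex chromogenic stains rather than true multiplex
platforms.

## What it computes

**Image layer.** Each round's RGB scan is converted to optical density
(Beer–Lambert, `OD_c = -log10((I_c+1)/(I0_c+1))`) and unmixed into chromogen
and hematoxylin components by per-pixel least squares on the two stain OD
vectors. Rounds are co-registered on the repeated hematoxylin counterstain
with a similarity transform (phase correlation over a rotation search) and
fused into a `VirtualMultiplexImage`. Nuclei are detected on the counterstain
(watershed with diameter and circularity gates), each marker is called by the
mean chromogen OD over its subcellular compartment — nuclear disk for
Ki67/Foxp3, 1.5 µm perinuclear ring for CD3/CD4/CD8, 2 µm-dilated disk for CK
— and flag patterns map to exclusive phenotypes: CD8⁺CD4⁻Foxp3⁻ (cytotoxic T),
CD4⁺Foxp3⁻CD8⁻ (helper T), CD4⁺Foxp3⁺CD8⁻ (Treg), CD3⁺-only, tumour (CK⁺),
other.

**Spatial layer.** The CK image yields a tumour mask; the region of interest
is partitioned into zone **A** (intratumoural), zone **B** (peritumoural
stroma within 30 µm of the tumour, exact Euclidean distance, closed boundary)
and zone **C** (stroma beyond 30 µm). Per-sample metrics: marker densities in
cells/mm² overall and per zone, Ki67⁺ ("proliferating") fractions, CD3⁺ subset
proportions, the proliferating Foxp3⁺/CD8⁺ ratio, the immune share of
proliferating cells, and an ROI-area QC filter (< 100 000 µm² excluded).

**Statistics layer.** Spearman correlation, paired Wilcoxon, Mann–Whitney /
Kruskal–Wallis (exact enumeration p-values at small n), paired mean
differences with t confidence intervals, univariate logistic odds ratios for
pathological complete response (per 10 sTIL points or 1000 cells/mm²),
housekeeping-gene normalisation of expression counts, and quantitative SAM
(d = slope/(s + s0), permutation FDR) for gene–sTIL association.

## Worked example

```bash
ngi simulate slide --out demo/slide --seed 4       # six stain rounds + truth
ngi run --in demo/slide --out demo/out --pixel-size-um 0.5
ngi simulate cohort --n-patients 50 --out demo/cohort --seed 3
ngi stats cohort --cohort demo/cohort/cohort.csv --out demo/stats.csv
```

The `run` step prints, for the default synthetic slide,

```
analysed 843 cells (qc_pass=True); outputs in demo/out
```

and writes `cells.csv` (one row per cell: centroid, per-marker mean OD and
flag, phenotype, zone), `metrics.csv`/`metrics.json` (densities, Ki67⁺
fractions, subset proportions, QC), `zones.png` (0 = outside ROI, 1/2/3 =
zones A/B/C) and `transforms.json` (per-round alignment). On this slide the
CD3⁺ subset split comes out as 46.5 / 29.7 / 10.9 / 12.9 % (CD8_T / CD4_T /
Treg / CD3_only) — the inflamed-tumour regime the generator emulates — and
the CD3⁺ density is highest in the proximal stromal band (3805 cells/mm² in
zone B against 549 intratumoural and 1416 distal), the peritumoural
lymphocyte cuff the spatial analysis is designed to resolve. The `stats cohort` step emits a tidy table of paired sTIL
shifts per stratum (e.g. a day-15 rise concentrated in hormone-receptor-
negative patients), the day15→surgery dynamics split and pCR odds ratios.

Library use mirrors the CLI:

```python
from ngi import SlideConfig, generate_slide, run_sample

rounds, truth = generate_slide(SlideConfig(seed=4))
result = run_sample(rounds)
print(result.metrics.subset_proportions)
```

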