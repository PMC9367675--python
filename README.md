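# mifprox

Spatial proximity analysis of phenotyped cells in multiplex-immunofluorescence
(mIF) tissue sections, built around the question of whether two immune cell
types — here group 2 innate lymphoid cells (ILC2, gated CD4−CD8−CD127+GATA3+)
and regulatory T cells (Treg, gated CD4+Foxp3+) in liver allografts — sit
closer to each other than chance allows.

The package is for computational pathology / tissue-immunology analysts who
start from post-segmentation single-cell tables (one row per cell: sample and
region-of-interest identifiers, x/y centroids in µm, per-marker intensities or
binary calls) exported by image-analysis software, and want reproducible,
testable spatial statistics rather than one-off scripts.

## What it computes

For two phenotypes A and B within each region of interest (ROI):

- **Directed nearest-neighbor distances** — for every A cell, the Euclidean
  distance d(a, B) = min_b ‖a − b‖ to the closest B cell, and vice versa;
  reported with the nearest-partner identity and the medians
  median(d(A→B)), median(d(B→A)), and the pooled median over both directions
  (the headline "median ILC2–Treg distance").
- **Neighborhood counts** — for every center cell, the number of partner-type
  cells inside a circle of fixed size (15 µm and 25 µm *diameters* by
  default), for all four ordered (center, neighbor) phenotype pairs.
- **Pairwise distance matrices** — the dense A×B matrix behind
  distance/count heatmaps.
- **Null models** — closed-form complete-spatial-randomness (CSR) references
  (median NN distance √(ln 2/(πλ)), expected circle count λπr²) and a
  within-ROI label-permutation test that holds all cell positions fixed and
  returns an add-one p-value (1 + #extreme)/(1 + n_perm).
- **Synthetic tissue** — a generator of two-population point patterns with
  known ground truth: independent Poisson populations (CSR) or a
  Neyman–Scott process whose two offspring types share parent points, so a
  single dispersion parameter σ controls cross-type attraction. This makes
  every claim in the analysis path testable without any imaging data.

Distances never cross ROI boundaries; per-sample summaries pool ROI-level
distance vectors before taking medians. No edge correction is applied in the
analysis path (simulation checks use a toroidal metric instead).

## Worked example

Simulate one attractive ROI (shared-parent model, σ = 10 µm, 500×500 µm
window, with a background population of non-target cells), analyze it, and
test the proximity:

```
$ mifprox simulate --model shared_parent --sigma 10 \
    --lambda-a 5e-4 --lambda-b 5e-4 --lambda-other 1e-3 \
    --window 500x500 --seed 7 --out cells.csv
wrote 517 cells to cells.csv

$ mifprox analyze --cells cells.csv --out results/
analysis written to results
```

`results/summary.csv` then contains (columns abridged):

```
sample_id roi_id status  n_ILC2  n_Treg  median_pooled  mean_count_Treg_around_ILC2_15um  mean_count_Treg_around_ILC2_25um
synthetic   roi0     ok     112     144       3.528476                          3.928571                          9.142857
synthetic pooled     ok     112     144       3.528476                          3.928571                          9.142857
```

112 ILC2s and 144 Tregs were gated (matching the generator's ground truth
exactly); the pooled median nearest ILC2↔Treg distance is 3.5 µm — far below the
≈ 20 µm that CSR at the observed Treg density (λ = 144/500² µm⁻², median
√(ln 2/(πλ))) would give — and an
average ILC2 has 3.9 Tregs within a 15-µm-diameter circle and 9.1 within
25 µm. The permutation test (labels shuffled over all cells, positions
fixed):

```
$ mifprox test --cells cells.csv --n-perm 199 --seed 17 --pool all
observed median_pooled = 3.528 µm; p = 0.0050 (less, 199 permutations)
```

p = 1/200, the smallest value 199 permutations can produce: the two
phenotypes are significantly closer than a random relabeling of the tissue
allows.

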