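# Methods

## Setting and data model

The unit of analysis is a marked point pattern: the segmented cells of one
region of interest (ROI) of a stained tissue section, each with a micron
centroid (x, y) and marker values. Coordinates live in an arbitrary
Cartesian frame — only inter-point distances enter any statistic, so origin
and axis orientation are irrelevant and untested. Units are microns
throughout; no pixel convention exists anywhere in the package. Cells in
different ROIs are different pieces of tissue and are never treated as
neighbors.

Input tables are comma-delimited text with a header. A schema mapping binds
vendor column names to the required roles (`cell_id`, `sample_id`, `roi_id`,
`x`, `y`); `sample_id`/`roi_id` default to constants for single-ROI exports,
unknown columns ride along untouched, and validation is strict (duplicate
ids within an ROI, non-numeric coordinates and negative marker values are
errors, never silently dropped rows).

## Phenotyping

Cells are gated on binary marker positivity. The default panel encodes the
tissue definitions of the two phenotypes of interest:

- ILC2: CD4− ∧ CD8− ∧ CD127+ ∧ GATA3+
- Treg: CD4+ ∧ Foxp3+
- fallback: "other"

These two gates are mutually exclusive (CD4 appears with opposite sense),
but evaluation order is fixed anyway — first match wins — so user panels
with overlapping gates stay deterministic; the count of multi-matching
cells is reported. The Treg gate deliberately omits the CD25+/CD127-low
criteria of flow cytometry: they have no counterpart in a CD4/CD8/CD127/
GATA3/Foxp3 imaging panel, and the tissue definition used here is the
imaging one.

Positivity for continuous intensities is strict (`intensity > threshold`).
Thresholds are user-supplied per marker; an automatic helper proposes an
Otsu split, guarded by Otsu's separability measure η (fraction of variance
explained by the two-class split): a unimodal Gaussian cannot exceed
η ≈ 0.64 at any split, so below η = 0.8 the marker is declared to have no
positive population and the threshold is placed above the observed maximum.
Without this guard, a marker that is negative everywhere (CD8 in a section
with no cytotoxic T cells, say) would have its noise split in half and
silently destroy the CD8− gate. The helper assumes roughly two-component
intensity mixtures; heavily skewed or multi-modal real-world intensities
still call for manually reviewed thresholds.

## Spatial statistics

**Directed nearest-neighbor distance.** For phenotypes A and B,
d(a, B) = min_{b ∈ B} ‖a − b‖ for every a ∈ A, together with the argmin
cell id. The directions are not symmetric and both are always computed. The
headline summary is the pooled median — the median of the concatenated A→B
and B→A vectors — with both per-direction medians reported alongside; the
even-length median is the midpoint of the two central order statistics.
A cell present in both roles under one id is excluded from its own
candidates. Ties at the minimum are broken by the lexicographically
smallest partner id, making results independent of row order.

**Neighborhood counts.** For each center cell, the number of partner-type
cells with distance ≤ r (inclusive boundary by default; `< r` available).
Circle sizes are interpreted as diameters by default (r = size/2), i.e. the
default sizes 15 µm and 25 µm mean r = 7.5 µm and r = 12.5 µm; a
radius interpretation is a config flag. The per-center count vectors for
all four ordered phenotype pairs, and the dense pairwise distance matrix,
are exported as numeric tables ordered by cell id — heatmap rendering is a
thin optional matplotlib layer with no tested semantics.

**Implementation.** Neighbor queries run on `scipy.spatial.cKDTree`; every
candidate distance the tree proposes is recomputed in plain vectorised
arithmetic (`sqrt(dx² + dy²)`) and the boundary/tie rules are applied to
the recomputed values, so the output is exactly — not approximately — the
exhaustive-search answer (asserted against a brute-force oracle on random
and tie-rich integer-lattice instances). Count queries inflate the tree
radius by one part in 10⁹ before exact filtering so that boundary cells are
never lost to floating-point noise in the tree's internal metric.

**Edge effects and pooling.** The analysis path applies no edge correction,
matching how such measurements are made on scanned tissue; distances near
the ROI border are therefore biased slightly upward. Simulation-based
checks instead use a toroidal metric (`boxsize`), under which the CSR
closed forms below are exact. Per-sample summaries concatenate the
ROI-level distance and count vectors before taking medians/means; ROIs
missing either phenotype are flagged `insufficient` and excluded from
pooling rather than contributing zeros.

## Null models

For a homogeneous Poisson process of intensity λ (µm⁻²), the distance from
an independent point to the nearest process point satisfies
P(D > d) = exp(−λπd²), giving the median √(ln 2/(πλ)), and the expected
count in a circle of radius r is λπr². These anchor the Monte-Carlo checks
(λ = 0.01 µm⁻² → median 4.697 µm, r = 7.5 µm → count 1.767). λ ≤ 0 and
r < 0 are domain errors; r = 0 is accepted as the continuous limit (count
0) rather than rejected, since the formula is continuous there.

**Label-permutation test.** All positions stay fixed; phenotype labels are
shuffled within each ROI with every label's count preserved, and the
statistic (pooled median cross-distance, direction "less"; or mean
cross-type circle count, direction "greater") is recomputed through the
same spatial-module code path used for the observed value. The p-value is
add-one, (1 + #extreme)/(1 + n_perm), exactly valid under exchangeability
and never zero.

Two permutation pools are offered, and the choice is scientific, not
cosmetic:

- `pool="pair"` shuffles labels only among the union of the two tested
  phenotypes. It conditions on the joint infiltrate geometry and asks
  whether A–B pairing is tighter than A–A/B–B mixing predicts. It is blind
  — provably, by exchangeability — to the situation where both phenotypes
  are jointly clustered in the same niches: if every cell of the union is
  an exchangeable draw from the same clustered distribution (exactly what
  the shared-parent generator produces), every relabeling is equally
  likely and no statistic can detect anything.
- `pool="all"` shuffles the phenotype labels of all cells, including the
  background of non-target cells. It asks whether the two phenotypes sit
  closer to each other than a random relabeling of the whole cellular
  landscape allows, and has power against joint co-clustering whenever a
  reference population exists. This matches common practice in tissue
  neighborhood-enrichment analysis.

`pair` is the default (it is the stricter conditioning); power analyses and
the calibration runs use `pool="all"` on tables that include a background
population, which is also the realistic regime — in real sections the
overwhelming majority of segmented cells are neither ILC2 nor Treg. Both
pools are exactly level-α under their respective exchangeability nulls,
which the type-I calibration run verifies by simulation. The test is
single-sample; aggregation across samples (and any multiple-testing
control) is left to the user.

## Synthetic tissue generator

The generator emulates the statistical skeleton of a segmented mIF ROI and
defines the conditions under which everything here is tested:

- **Window**: 1000×1000 µm by default (about a 200× scanned field);
  calibration runs use 500×500 µm to keep Monte-Carlo loops tight.
- **Intensities**: rare-phenotype default λ = 10⁻⁴ µm⁻² (~100 cells per
  default window). These are conventions for sparse immune infiltrates —
  no measured tissue densities stand behind them — and are overridable.
- **CSR model**: per-type Poisson counts, uniform positions. Used as the
  no-interaction baseline and for type-I calibration.
- **Shared-parent model**: parents ~ Poisson(parent intensity, default
  2×10⁻⁵ µm⁻²); each type's count ~ Poisson(λ·area); each offspring picks a
  uniform parent and scatters with isotropic Gaussian dispersion σ.
  Sharing parents across types yields cross-type attraction with a single
  interpretable knob: the mean pooled median cross-distance rises strictly
  with σ and becomes indistinguishable from CSR once σ reaches the window
  scale. Chosen over a Gibbs attraction potential because simulation is
  exact (no MCMC) and ground truth is transparent.
- **Topology**: on the torus, offspring wrap, and CSR closed forms are
  exact. On the plane (the analysis-facing default), offspring falling
  outside the window are redrawn, which preserves edge intensity at the
  cost of slightly reweighting toward central parents. A Poisson draw of
  zero parents returns an empty pattern.
- **Markers**: intensity N(mean_pos = 10, mean_neg = 1, sd = 0.5), clipped
  at zero, per the cell's true phenotype (ILC2 ⇒ CD127, GATA3 high; Treg ⇒
  CD4, Foxp3 high; everything else low). The separation is deliberately
  generous — it tests the plumbing, not the hard problem of real
  intensity normalization. mean_pos = mean_neg is allowed as a degenerate
  smoke-test setting.
- **Cohorts**: groups "rejection" (σ = 5 µm), "nonrejection" (σ = 15 µm)
  and "control" (CSR) reproduce the qualitative ordering of median
  cross-distances expected when attraction weakens across clinical groups.

Ground truth travels in a `true_label` column that is never registered as a
marker, so the analysis path (coordinates + markers + assigned phenotype)
cannot read it; the CLI writes it to a separate sidecar file.

What passing these tests does **not** show about real tissue: the generator
has no lobular anatomy (portal-region clustering is not structurally
modeled), no segmentation errors or doublets, no staining batch effects or
spectral spillover, and its marker distributions are far cleaner than real
Opal intensities. Results on real exports depend on upstream segmentation
and thresholding quality in ways these simulations do not probe.

## Numerical and design choices

- Circle sizes are diameters by default because the operational description
  of the measurement counts partners "within a circle with a diameter of
  15 microns or 25 microns"; a radius flag covers the alternative reading.
- The pooled median is the default headline number, being the only single
  number consistent with measuring both directions first; per-direction
  medians are always attached.
- Boundary rule inclusive (≤ r) by default; configurable.
- Empty-side proximity results carry `status="undefined"` and `None`
  medians — degenerate inputs are flagged, never coerced to zero.
- Permutations, simulations and cohorts are driven by numpy `SeedSequence`
  derivations of a single user seed; identical seeds give bit-identical
  outputs.
- Monte-Carlo problem sizes in the test suite (50 replicates for CSR
  agreement and σ-recovery, 200/100 tables for type-I/power at
  n_perm = 199) were sized to keep the whole suite in the low minutes on a
  laptop while leaving comfortable margins against the asserted tolerances.

## Known limitations

- No edge-corrected estimators (Ripley K/L, pair correlation) — out of
  scope by design; the medians and counts here are the raw descriptive
  quantities, comparable across samples only when ROI geometry is similar.
- Single pair of phenotypes per analysis; multi-type interaction structure
  is not modeled.
- The automatic threshold helper assumes near-two-component intensity
  mixtures.
- The permutation test conditions on one section; it does not provide
  cohort-level inference.
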