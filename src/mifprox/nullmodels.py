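"""Null models for cross-type proximity: CSR theory and permutation tests.

Two closed forms for a homogeneous Poisson process (complete spatial
randomness, CSR) of intensity λ per µm²:

* the median distance from an independent point to the nearest process
  point, ``sqrt(ln 2 / (π λ))`` — from P(D > d) = exp(-λ π d²);
* the expected number of process points in a circle of radius r, ``λ π r²``.

These anchor simulation-based checks of the spatial statistics.

The label-permutation test turns "the two phenotypes look close together"
into a calibrated statement.  All cell positions stay fixed; phenotype
labels are shuffled among the union of the two tested phenotypes' cells,
within each ROI, keeping both phenotype counts fixed.  This conditions on
the observed abundances and on the full geometry of the section, isolating
relative spatial arrangement — the quantity of interest — from abundance
differences.  The p-value uses the add-one convention
``(1 + #extreme) / (1 + n_perm)`` so it is never zero and is exactly valid
under exchangeability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, DomainError
from .io_model import CellTable, PHENOTYPE_COLUMN
from . import spatial


def csr_expected_nn_median(intensity: float) -> float:
    """Median nearest-neighbor distance to a CSR process of intensity λ (µm⁻²)."""
    if intensity <= 0:
        raise DomainError("intensity must be > 0")
    return math.sqrt(math.log(2) / (math.pi * intensity))


def csr_expected_count(intensity: float, r: float) -> float:
    """Expected CSR point count in a circle of radius r: λ π r².

    ``r = 0`` is accepted as the continuous limit and returns 0.
    """
    if intensity <= 0:
        raise DomainError("intensity must be > 0")
    if r < 0:
        raise DomainError("radius must be >= 0")
    return intensity * math.pi * r * r


@dataclass
class PermutationTestResult:
    """Outcome of a within-ROI label-permutation test."""

    statistic: str
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    direction: str
    seed: int
    label_a: str
    label_b: str
    pool: str = "pair"

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "statistic": [self.statistic],
                "observed": [self.observed_stat],
                "p_value": [self.p_value],
                "n_perm": [self.n_perm],
                "direction": [self.direction],
                "seed": [self.seed],
            }
        )
        return head


def _stat_median_pooled(pairs) -> float:
    """Pooled median cross-distance over per-ROI (A, B) point sets."""
    pooled = []
    for A, B in pairs:
        if len(A) == 0 or len(B) == 0:
            continue
        pooled.append(spatial.nn_distance_vector(A, B))
        pooled.append(spatial.nn_distance_vector(B, A))
    if not pooled:
        raise DegenerateInputError("no ROI with both phenotypes present")
    return float(np.median(np.concatenate(pooled)))


def _stat_mean_count(pairs, radius: float) -> float:
    """Mean cross-type circle count over centers of both phenotypes."""
    counts = []
    for A, B in pairs:
        if len(A) == 0 or len(B) == 0:
            continue
        for centers, nbrs in ((A, B), (B, A)):
            cm = spatial.neighborhood_counts(
                centers, nbrs, radius, size_is_diameter=False
            )
            counts.append(cm.counts)
    if not counts:
        raise DegenerateInputError("no ROI with both phenotypes present")
    return float(np.concatenate(counts).mean())


def label_permutation_test(
    table: CellTable,
    stat: str = "median_pooled",
    labels: tuple[str, str] = ("ILC2", "Treg"),
    n_perm: int = 999,
    seed: int = 0,
    direction: str | None = None,
    radius: float = 7.5,
    pool: str = "pair",
) -> PermutationTestResult:
    """Permutation test for cross-type proximity with positions held fixed.

    Parameters
    ----------
    stat
        ``"median_pooled"`` (pooled median cross-distance, µm) or
        ``"mean_count"`` (mean cross-type neighborhood count at ``radius``).
    labels
        The two phenotype labels entering the statistic.
    direction
        ``"less"`` rejects for small statistics (attraction shrinks the
        median distance), ``"greater"`` for large ones (attraction raises
        counts).  Defaults to ``"less"`` for ``median_pooled`` and
        ``"greater"`` for ``mean_count``.
    pool
        Which cells the labels are shuffled over, within each ROI, always
        keeping every label's count fixed.  ``"pair"`` permutes only among
        the two tested phenotypes' cells: it conditions on the joint
        infiltrate geometry and asks whether A–B pairing is tighter than
        A–A/B–B mixing would predict — it is blind to the two types being
        *jointly* clustered.  ``"all"`` permutes the phenotype labels of all
        cells (including non-target cells): it asks whether the two types
        sit closer to each other than a random relabeling of the whole
        cellular landscape allows, and is the choice with power against
        joint co-clustering, provided the table contains a reference
        population of other cells.

    The statistic is recomputed through the spatial module on every
    permutation; the observed value uses the identical code path with the
    identity assignment.
    """
    if stat not in ("median_pooled", "mean_count"):
        raise ConfigurationError(f"unknown statistic {stat!r}")
    if pool not in ("pair", "all"):
        raise ConfigurationError(f"unknown pool {pool!r}")
    if direction is None:
        direction = "less" if stat == "median_pooled" else "greater"
    if direction not in ("less", "greater"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if n_perm < 99:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse p-value grid; >= 99 recommended",
            stacklevel=2,
        )
    if PHENOTYPE_COLUMN not in table.data.columns:
        raise ConfigurationError("table is not labeled; run phenotyping first")
    la, lb = labels
    df = table.data
    n_a_total = int((df[PHENOTYPE_COLUMN] == la).sum())
    n_b_total = int((df[PHENOTYPE_COLUMN] == lb).sum())
    if n_a_total < 2 or n_b_total < 2:
        raise DegenerateInputError(
            f"need >= 2 cells of each phenotype; got {n_a_total} {la!r}, "
            f"{n_b_total} {lb!r}"
        )

    # per-ROI: positions and labels of the permutation pool
    roi_data = []
    for sample, roi, sub in table.iter_rois():
        sel = sub if pool == "all" else sub[sub[PHENOTYPE_COLUMN].isin([la, lb])]
        if len(sel) == 0:
            continue
        pts = sel[["x", "y"]].to_numpy(dtype=float)
        labs = sel[PHENOTYPE_COLUMN].to_numpy(dtype=object)
        roi_data.append((pts, labs))

    def compute(label_lists):
        pairs = [
            (pts[labs == la], pts[labs == lb])
            for (pts, _), labs in zip(roi_data, label_lists)
        ]
        if stat == "median_pooled":
            return _stat_median_pooled(pairs)
        return _stat_mean_count(pairs, radius)

    observed = compute([labs for _, labs in roi_data])
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_perm, dtype=float)
    for p in range(n_perm):
        shuffled = [labs[rng.permutation(len(labs))] for _, labs in roi_data]
        null_stats[p] = compute(shuffled)

    if direction == "less":
        extreme = int((null_stats <= observed).sum())
    else:
        extreme = int((null_stats >= observed).sum())
    p_value = (1 + extreme) / (1 + n_perm)
    return PermutationTestResult(
        statistic=stat, observed_stat=observed, null_stats=null_stats,
        p_value=p_value, n_perm=n_perm, direction=direction, seed=seed,
        label_a=la, label_b=lb, pool=pool,
    )
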