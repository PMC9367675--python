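"""Synthetic two-population marked point patterns with known ground truth.

Emulates the statistical structure of a segmented multiplex-IF region of
interest: two rare phenotypes (ILC2 and Treg) scattered in a rectangular
window at tissue-realistic intensities, with optional cross-type attraction
and Gaussian marker-intensity noise.

Two interaction models are available:

* ``csr`` — both populations are independent homogeneous Poisson processes
  (complete spatial randomness): the no-interaction baseline.
* ``shared_parent`` — a Neyman–Scott cluster process in which both
  populations scatter around the *same* latent parent points with Gaussian
  dispersion σ.  Sharing parents induces cross-type attraction whose
  strength is set by a single interpretable parameter: small σ means tight
  co-location, σ much larger than the window is indistinguishable from CSR.
  Marginal intensities match ``lambda_a``/``lambda_b`` in expectation.

Ground-truth phenotypes are carried in a ``true_label`` column that is never
listed among the marker columns, so the analysis path (coordinates +
markers only) cannot see it.  Marker intensities consistent with each
ground-truth phenotype (ILC2: CD127/GATA3 high, CD4/CD8/Foxp3 low; Treg:
CD4/Foxp3 high, rest low) are drawn as truncated Gaussians via
:func:`attach_marker_intensities`.

Default window and intensities (1000×1000 µm, λ = 1e-4 µm⁻², i.e. ~100
cells of each rare phenotype per ROI) are conventions chosen to resemble a
scanned 200× field with sparse infiltrates; they are not measured tissue
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .io_model import CellTable, GROUND_TRUTH_COLUMN

#: Marker panel emitted by the generator, in file order.
MARKERS = ("CD4", "CD8", "CD127", "GATA3", "Foxp3")

#: Which markers are truly positive for each ground-truth phenotype.
POSITIVE_MARKERS = {
    "ILC2": {"CD127", "GATA3"},
    "Treg": {"CD4", "Foxp3"},
    "other": set(),
}


@dataclass(frozen=True)
class MarkerNoise:
    """Truncated-Gaussian intensity model: N(mean, sd²) clipped at 0."""

    mean_pos: float = 10.0
    mean_neg: float = 1.0
    sd: float = 0.5

    def __post_init__(self) -> None:
        # equality is allowed as a degenerate (uninformative) setting
        if self.mean_pos < self.mean_neg:
            raise DomainError("mean_pos must not be below mean_neg")
        if self.sd < 0:
            raise DomainError("sd must be >= 0")


@dataclass
class SyntheticTissueConfig:
    """Full recipe for one simulated ROI.

    ``window`` is (width, height) in µm; ``lambda_a``/``lambda_b`` are the
    ILC2/Treg intensities per µm²; ``lambda_other`` adds an optional CSR
    background of non-target cells.  ``parent_intensity`` and ``sigma``
    (µm) apply to the shared-parent model only.  ``topology = "torus"``
    wraps coordinates periodically so closed-form CSR checks are exact;
    ``"plane"`` is the analysis-facing default.
    """

    window: tuple[float, float] = (1000.0, 1000.0)
    lambda_a: float = 1e-4
    lambda_b: float = 1e-4
    lambda_other: float = 0.0
    model: str = "csr"  # or "shared_parent"
    parent_intensity: float = 2e-5
    sigma: float = 10.0
    marker_noise: MarkerNoise = field(default_factory=MarkerNoise)
    topology: str = "plane"  # or "torus"
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window
        if w <= 0 or h <= 0:
            raise DomainError("window must have positive area")
        if min(self.lambda_a, self.lambda_b, self.lambda_other) < 0:
            raise DomainError("intensities must be >= 0")
        if self.model not in ("csr", "shared_parent"):
            raise DomainError(f"unknown model {self.model!r}")
        if self.model == "shared_parent":
            if self.sigma <= 0:
                raise DomainError("sigma must be > 0 for shared_parent")
            if self.parent_intensity <= 0 and (self.lambda_a > 0 or self.lambda_b > 0):
                raise DomainError(
                    "parent_intensity must be > 0 when offspring intensities are"
                )
        if self.topology not in ("plane", "torus"):
            raise DomainError(f"unknown topology {self.topology!r}")

    @property
    def area(self) -> float:
        return self.window[0] * self.window[1]


def _assemble(points: dict[str, np.ndarray], sample_id: str, roi_id: str,
              window: tuple[float, float]) -> CellTable:
    frames = []
    for label, xy in points.items():
        n = len(xy)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{label}_{i:05d}" for i in range(n)],
                    "sample_id": sample_id,
                    "roi_id": roi_id,
                    "x": xy[:, 0] if n else np.empty(0),
                    "y": xy[:, 1] if n else np.empty(0),
                    GROUND_TRUTH_COLUMN: label,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    w, h = window
    return CellTable(
        data=data, markers=(),
        windows={(sample_id, roi_id): (0.0, 0.0, float(w), float(h))},
    )


def _uniform(rng: np.random.Generator, n: int, window) -> np.ndarray:
    w, h = window
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def simulate_csr(
    config: SyntheticTissueConfig,
    sample_id: str = "synthetic",
    roi_id: str = "roi0",
    rng: np.random.Generator | None = None,
) -> CellTable:
    """Two independent Poisson populations, uniform in the window.

    Counts are Poisson(λ · area) per type; a fixed seed reproduces the table
    exactly.
    """
    if config.model != "csr":
        raise DomainError("config.model must be 'csr'")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    points = {}
    for label, lam in (
        ("ILC2", config.lambda_a),
        ("Treg", config.lambda_b),
        ("other", config.lambda_other),
    ):
        if label == "other" and lam == 0:
            continue
        n = rng.poisson(lam * config.area)
        points[label] = _uniform(rng, n, config.window)
    return _assemble(points, sample_id, roi_id, config.window)


def _offspring(
    rng: np.random.Generator,
    parents: np.ndarray,
    n: int,
    sigma: float,
    window,
    topology: str,
) -> np.ndarray:
    """Scatter n offspring around uniformly chosen parents.

    Torus: displacements wrap.  Plane: points falling outside the window are
    redrawn (parent choice and displacement together), i.e. the pattern is
    the cluster process conditioned on the window — intensity near edges is
    preserved at the cost of a slight reweighting toward central parents.
    """
    w, h = window
    out = np.empty((n, 2))
    remaining = np.arange(n)
    guard = 0
    while remaining.size:
        idx = rng.integers(0, len(parents), size=remaining.size)
        pts = parents[idx] + rng.normal(0.0, sigma, size=(remaining.size, 2))
        if topology == "torus":
            pts[:, 0] %= w
            pts[:, 1] %= h
            out[remaining] = pts
            break
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        )
        out[remaining[inside]] = pts[inside]
        remaining = remaining[~inside]
        guard += 1
        if guard > 10_000:
            raise RuntimeError("rejection sampling failed to converge")
    return out


def simulate_shared_parent(
    config: SyntheticTissueConfig,
    sample_id: str = "synthetic",
    roi_id: str = "roi0",
    rng: np.random.Generator | None = None,
) -> CellTable:
    """Neyman–Scott pattern with parents shared by both phenotypes."""
    if config.model != "shared_parent":
        raise DomainError("config.model must be 'shared_parent'")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_parents = rng.poisson(config.parent_intensity * config.area)
    points: dict[str, np.ndarray] = {}
    if n_parents == 0:
        # a Poisson draw of zero parents leaves nothing to scatter around
        points = {"ILC2": np.empty((0, 2)), "Treg": np.empty((0, 2))}
    else:
        parents = _uniform(rng, n_parents, config.window)
        for label, lam in (("ILC2", config.lambda_a), ("Treg", config.lambda_b)):
            n = rng.poisson(lam * config.area)
            points[label] = _offspring(
                rng, parents, n, config.sigma, config.window, config.topology
            )
    if config.lambda_other > 0:
        n = rng.poisson(config.lambda_other * config.area)
        points["other"] = _uniform(rng, n, config.window)
    return _assemble(points, sample_id, roi_id, config.window)


def simulate(config: SyntheticTissueConfig, **kwargs) -> CellTable:
    """Dispatch on ``config.model``."""
    if config.model == "csr":
        return simulate_csr(config, **kwargs)
    return simulate_shared_parent(config, **kwargs)


def attach_marker_intensities(
    table: CellTable,
    config: SyntheticTissueConfig,
    rng: np.random.Generator | None = None,
) -> CellTable:
    """Draw continuous marker intensities consistent with ground truth.

    Each marker is N(mean_pos, sd²) if the cell's true phenotype is positive
    for it, N(mean_neg, sd²) otherwise, truncated at zero by clipping.
    """
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        if rng is None
        else rng
    )
    noise = config.marker_noise
    df = table.data.copy()
    truth = df[GROUND_TRUTH_COLUMN].to_numpy()
    n = len(df)
    for marker in MARKERS:
        pos = np.array([marker in POSITIVE_MARKERS.get(t, set()) for t in truth])
        means = np.where(pos, noise.mean_pos, noise.mean_neg)
        vals = means + (rng.normal(0.0, noise.sd, n) if noise.sd > 0 else 0.0)
        df[marker] = np.clip(vals, 0.0, None)
    return CellTable(data=df, markers=MARKERS, windows=dict(table.windows))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Default per-group interaction settings: attraction strongest in the
#: rejection-like group, intermediate in non-rejection, absent in controls.
DEFAULT_GROUP_MODELS = {
    "rejection": {"model": "shared_parent", "sigma": 5.0},
    "nonrejection": {"model": "shared_parent", "sigma": 15.0},
    "control": {"model": "csr"},
}


def make_cohort(
    n_rejection: int,
    n_nonrejection: int,
    n_control: int,
    base_config: SyntheticTissueConfig | None = None,
    group_models: dict[str, dict] | None = None,
    seed: int = 0,
    with_markers: bool = True,
) -> list[tuple[str, CellTable]]:
    """Simulate a cohort of samples in three clinical-like groups.

    Returns ``(group, table)`` pairs, one per sample; sample ids encode the
    group.  Group interaction settings default to
    :data:`DEFAULT_GROUP_MODELS` (σ = 5 µm for "rejection", σ = 15 µm for
    "nonrejection", CSR for "control"), so downstream medians reproduce the
    expected ordering rejection < non-rejection < control.
    """
    sizes = {"rejection": n_rejection, "nonrejection": n_nonrejection,
             "control": n_control}
    if sum(sizes.values()) == 0:
        raise DomainError("cohort must contain at least one sample")
    base = base_config if base_config is not None else SyntheticTissueConfig()
    models = dict(DEFAULT_GROUP_MODELS)
    if group_models:
        models.update(group_models)
    ss = np.random.SeedSequence(seed)
    out: list[tuple[str, CellTable]] = []
    for group, n in sizes.items():
        for i in range(n):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            cfg = replace(base, **models[group])
            sample_id = f"{group}_{i:02d}"
            table = simulate(cfg, sample_id=sample_id, rng=rng)
            if with_markers:
                table = attach_marker_intensities(table, cfg, rng=rng)
            # carry group metadata on every row
            table.data["group"] = group
            out.append((group, table))
    return out


def concat_tables(tables: Sequence[CellTable]) -> CellTable:
    """Stack tables that share a marker panel into one multi-sample table."""
    markers = tables[0].markers
    data = pd.concat([t.data for t in tables], ignore_index=True)
    windows: dict = {}
    for t in tables:
        windows.update(t.windows)
    return CellTable(data=data, markers=markers, windows=windows)
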