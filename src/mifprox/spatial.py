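"""Cross-type spatial statistics for phenotyped cell tables.

Implements the proximity readouts used to quantify co-location of two cell
phenotypes in a tissue section:

* directed nearest-neighbor distances (for each A cell, the distance to the
  closest B cell, and vice versa) and their medians — pooled over both
  directions and per direction;
* neighborhood counts: for each center cell, the number of partner-type
  cells inside a circle of fixed size (15 µm and 25 µm diameters by
  default);
* full pairwise distance matrices, the numeric content behind
  distance/count heatmaps.

Distances are Euclidean in the micron coordinate plane.  Neighbor queries
run on a k-d tree and are exactly equivalent to exhaustive search: candidate
distances are recomputed in plain floating point and nearest-neighbor ties
are broken by the lexicographically smallest partner ``cell_id``.  No edge
correction is applied in the analysis path; an optional toroidal metric
(``boxsize``) is available so simulation-based checks against closed-form
theory are free of edge effects.

Distances never cross ROI boundaries: cells in different tissue regions are
never considered neighbors, and per-sample summaries pool ROI-level distance
vectors before taking medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DegenerateInputError, DomainError
from .io_model import AnalysisConfig, CellTable, PHENOTYPE_COLUMN

__all__ = [
    "DistancePairMatrix",
    "ProximityResult",
    "NeighborhoodCountMatrix",
    "pairwise_distances",
    "directed_nn",
    "nn_distance_vector",
    "median_cross_distance",
    "neighborhood_counts",
    "summarize_sample",
]


def _points(xy) -> np.ndarray:
    pts = np.asarray(xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        pts = pts.reshape(-1, 2)
    return pts


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def _dists_from(point: np.ndarray, pts: np.ndarray, boxsize) -> np.ndarray:
    """Distances from one point to many, plane or torus."""
    delta = np.abs(pts - point)
    if boxsize is not None:
        delta = np.minimum(delta, np.asarray(boxsize, dtype=float) - delta)
    return np.sqrt((delta * delta).sum(axis=1))


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------


@dataclass
class DistancePairMatrix:
    """All-pairs Euclidean distances between two labeled point sets (µm)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.col_ids)
        df.insert(0, "cell_id", self.row_ids)
        return df


def pairwise_distances(
    a_xy, b_xy, a_ids: Sequence[str] | None = None, b_ids: Sequence[str] | None = None,
    boxsize=None,
) -> DistancePairMatrix:
    """Dense A×B Euclidean distance matrix.

    Raises :class:`DegenerateInputError` naming the empty set when either
    input has no points.
    """
    A, B = _points(a_xy), _points(b_xy)
    if len(A) == 0:
        raise DegenerateInputError("point set A is empty")
    if len(B) == 0:
        raise DegenerateInputError("point set B is empty")
    if boxsize is None:
        values = cdist(A, B)
    else:
        box = np.asarray(boxsize, dtype=float)
        delta = np.abs(A[:, None, :] - B[None, :, :])
        delta = np.minimum(delta, box - delta)
        values = np.sqrt((delta * delta).sum(axis=2))
    a_ids = list(a_ids) if a_ids is not None else _default_ids("A", len(A))
    b_ids = list(b_ids) if b_ids is not None else _default_ids("B", len(B))
    return DistancePairMatrix(a_ids, b_ids, values)


# ---------------------------------------------------------------------------
# Directed nearest neighbors
# ---------------------------------------------------------------------------


def nn_distance_vector(a_xy, b_xy, boxsize=None) -> np.ndarray:
    """Fast path: distance from each A point to its nearest B point.

    No identity bookkeeping (the two sets are assumed disjoint); used in the
    permutation loop where only the distances feed the statistic.
    """
    A, B = _points(a_xy), _points(b_xy)
    if len(B) == 0:
        raise DegenerateInputError("point set B is empty")
    tree = cKDTree(B, boxsize=boxsize)
    d, _ = tree.query(A, k=1)
    return np.atleast_1d(d)


def directed_nn(
    a_xy, b_xy,
    a_ids: Sequence[str] | None = None,
    b_ids: Sequence[str] | None = None,
    boxsize=None,
) -> tuple[np.ndarray, list[str]]:
    """Nearest B neighbor for each A point: distances and partner ids.

    A cell present in both sets under the same ``cell_id`` is excluded from
    its own candidates (needed when A and B are the same phenotype).  Ties at
    the minimum distance are broken by the lexicographically smallest partner
    ``cell_id``, which makes results independent of input row order.

    Distances are recomputed outside the tree in plain vectorised arithmetic,
    so the output matches an exhaustive double-loop search exactly.
    """
    A, B = _points(a_xy), _points(b_xy)
    n_a, n_b = len(A), len(B)
    if n_b == 0:
        raise DegenerateInputError("point set B is empty")
    a_ids = list(a_ids) if a_ids is not None else _default_ids("A", n_a)
    b_ids = list(b_ids) if b_ids is not None else _default_ids("B", n_b)
    b_ids_arr = np.asarray(b_ids, dtype=object)

    tree = cKDTree(B, boxsize=boxsize)
    k = min(2, n_b)
    d, _ = tree.query(A, k=k)
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if d.shape[0] != n_a:  # k == 1 returns shape (n_a,)
        d = d.reshape(n_a, -1)

    dists = np.empty(n_a, dtype=float)
    partners: list[str] = []
    for i in range(n_a):
        radius = d[i, -1]
        cand = tree.query_ball_point(A[i], radius * (1 + 1e-12) + 1e-300)
        cand = np.asarray(cand, dtype=int)
        cand = cand[b_ids_arr[cand] != a_ids[i]]  # never one's own neighbor
        if cand.size == 0:
            # the only candidates within the k-NN radius were the cell itself
            mask = b_ids_arr != a_ids[i]
            if not mask.any():
                raise DegenerateInputError(
                    "point set B contains no candidate other than the query cell"
                )
            cand = np.flatnonzero(mask)
        cd = _dists_from(A[i], B[cand], boxsize)
        dmin = cd.min()
        ties = cand[cd == dmin]
        partners.append(min(b_ids_arr[ties]))
        dists[i] = dmin
    return dists, partners


# ---------------------------------------------------------------------------
# Median cross-distance
# ---------------------------------------------------------------------------


@dataclass
class ProximityResult:
    """Directed nearest-neighbor distances between two phenotypes (µm).

    ``status`` is ``"ok"`` when both sets are non-empty and ``"undefined"``
    otherwise — an empty side yields no medians, never a silent zero.  The
    median of an even-length vector is the midpoint of the two central order
    statistics (numpy convention).
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    dists_a_to_b: np.ndarray
    dists_b_to_a: np.ndarray
    nearest_partner: dict[str, str]
    median_pooled: float | None
    median_a_to_b: float | None
    median_b_to_a: float | None
    status: str = "ok"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, ids, dists in (
            (f"{self.label_a}->{self.label_b}", self._a_ids, self.dists_a_to_b),
            (f"{self.label_b}->{self.label_a}", self._b_ids, self.dists_b_to_a),
        ):
            for cid, dist in zip(ids, dists):
                rows.append(
                    {
                        "direction": direction,
                        "cell_id": cid,
                        "partner_id": self.nearest_partner.get((direction, cid)),
                        "distance_um": dist,
                        "status": self.status,
                    }
                )
        if not rows:  # degenerate: header plus a single flagged row
            rows.append(
                {
                    "direction": f"{self.label_a}->{self.label_b}",
                    "cell_id": None,
                    "partner_id": None,
                    "distance_um": None,
                    "status": self.status,
                }
            )
        return pd.DataFrame(rows)

    # ids kept for serialisation; set by median_cross_distance
    _a_ids: list[str] = field(default_factory=list, repr=False)
    _b_ids: list[str] = field(default_factory=list, repr=False)

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.dists_a_to_b, self.dists_b_to_a])


def median_cross_distance(
    a_xy, b_xy,
    a_ids: Sequence[str] | None = None,
    b_ids: Sequence[str] | None = None,
    mode: str = "pooled",
    boxsize=None,
    label_a: str = "A",
    label_b: str = "B",
) -> ProximityResult:
    """Directed NN distances in both directions plus all three medians.

    ``mode`` records which median is the headline number (``pooled``: median
    of the concatenated A→B and B→A vectors; ``per_direction``: the two
    directional medians); all three are always populated.
    """
    if mode not in ("pooled", "per_direction"):
        raise ConfigurationError(f"unknown median mode {mode!r}")
    A, B = _points(a_xy), _points(b_xy)
    a_ids = list(a_ids) if a_ids is not None else _default_ids("A", len(A))
    b_ids = list(b_ids) if b_ids is not None else _default_ids("B", len(B))
    if len(A) == 0 or len(B) == 0:
        return ProximityResult(
            label_a=label_a, label_b=label_b, n_a=len(A), n_b=len(B),
            dists_a_to_b=np.empty(0), dists_b_to_a=np.empty(0),
            nearest_partner={}, median_pooled=None, median_a_to_b=None,
            median_b_to_a=None, status="undefined",
            _a_ids=a_ids, _b_ids=b_ids,
        )
    d_ab, part_ab = directed_nn(A, B, a_ids, b_ids, boxsize=boxsize)
    d_ba, part_ba = directed_nn(B, A, b_ids, a_ids, boxsize=boxsize)
    partner = {(f"{label_a}->{label_b}", i): p for i, p in zip(a_ids, part_ab)}
    partner.update({(f"{label_b}->{label_a}", i): p for i, p in zip(b_ids, part_ba)})
    pooled = np.concatenate([d_ab, d_ba])
    return ProximityResult(
        label_a=label_a, label_b=label_b, n_a=len(A), n_b=len(B),
        dists_a_to_b=d_ab, dists_b_to_a=d_ba, nearest_partner=partner,
        median_pooled=float(np.median(pooled)),
        median_a_to_b=float(np.median(d_ab)),
        median_b_to_a=float(np.median(d_ba)),
        status="ok", _a_ids=a_ids, _b_ids=b_ids,
    )


# ---------------------------------------------------------------------------
# Neighborhood counts
# ---------------------------------------------------------------------------


@dataclass
class NeighborhoodCountMatrix:
    """Per-center counts of partner-type cells inside a fixed circle."""

    center_type: str
    neighbor_type: str
    circle_size: float
    size_is_diameter: bool
    boundary: str
    center_ids: list[str]
    counts: np.ndarray
    status: str = "ok"

    @property
    def radius(self) -> float:
        return self.circle_size / 2 if self.size_is_diameter else self.circle_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_type": self.center_type,
                "neighbor_type": self.neighbor_type,
                "circle_size_um": self.circle_size,
                "size_is_diameter": self.size_is_diameter,
                "boundary": self.boundary,
                "cell_id": self.center_ids,
                "count": self.counts.astype(int),
                "status": self.status,
            }
        )


def neighborhood_counts(
    centers_xy, neighbors_xy,
    size: float,
    size_is_diameter: bool = True,
    boundary: str = "inclusive",
    center_ids: Sequence[str] | None = None,
    neighbor_ids: Sequence[str] | None = None,
    boxsize=None,
    center_type: str = "A",
    neighbor_type: str = "B",
) -> NeighborhoodCountMatrix:
    """Count partner cells within a circle around each center cell.

    ``size`` is interpreted as a diameter by default (radius = size/2).  The
    boundary rule is inclusive (distance <= r) unless ``boundary`` is
    ``"exclusive"``.  A cell appearing in both roles under the same id never
    counts itself.  Empty neighbor set is valid and yields all-zero counts
    with ``status = "no_neighbors"``.
    """
    if size <= 0:
        raise DomainError("circle size must be > 0")
    if boundary not in ("inclusive", "exclusive"):
        raise ConfigurationError(f"unknown boundary rule {boundary!r}")
    C, N = _points(centers_xy), _points(neighbors_xy)
    if len(C) == 0:
        raise DegenerateInputError("center set is empty")
    center_ids = (
        list(center_ids) if center_ids is not None else _default_ids("C", len(C))
    )
    if len(N) == 0:
        return NeighborhoodCountMatrix(
            center_type, neighbor_type, float(size), size_is_diameter, boundary,
            center_ids, np.zeros(len(C), dtype=int), status="no_neighbors",
        )
    neighbor_ids = (
        list(neighbor_ids) if neighbor_ids is not None else _default_ids("N", len(N))
    )
    nid = np.asarray(neighbor_ids, dtype=object)
    r = size / 2 if size_is_diameter else float(size)
    tree = cKDTree(N, boxsize=boxsize)
    # query slightly beyond r, then apply the exact boundary rule on
    # recomputed distances so inclusive/exclusive semantics are bit-exact
    balls = tree.query_ball_point(C, r * (1 + 1e-9) + 1e-12)
    counts = np.zeros(len(C), dtype=int)
    for i, cand in enumerate(balls):
        if not cand:
            continue
        cand = np.asarray(cand, dtype=int)
        cd = _dists_from(C[i], N[cand], boxsize)
        keep = cd <= r if boundary == "inclusive" else cd < r
        keep &= nid[cand] != center_ids[i]
        counts[i] = int(keep.sum())
    return NeighborhoodCountMatrix(
        center_type, neighbor_type, float(size), size_is_diameter, boundary,
        center_ids, counts,
    )


# ---------------------------------------------------------------------------
# Per-sample summaries
# ---------------------------------------------------------------------------


def _roi_points(sub: pd.DataFrame, label: str):
    rows = sub[sub[PHENOTYPE_COLUMN] == label]
    return rows[["x", "y"]].to_numpy(dtype=float), rows["cell_id"].tolist()


def summarize_sample(table: CellTable, config: AnalysisConfig) -> pd.DataFrame:
    """Per-ROI and pooled per-sample proximity summary for two phenotypes.

    For each (sample, ROI): phenotype counts, the three cross-distance
    medians, and mean/median neighborhood counts for the four ordered
    (center, neighbor) phenotype pairs at every configured circle size.
    ROIs with no cell of either phenotype are flagged ``insufficient`` and
    excluded from pooling.  Pooled rows (``roi_id = "pooled"``) concatenate
    the ROI-level distance and count vectors of a sample before taking
    medians, so a single-ROI sample pools to its own ROI summary.
    """
    if PHENOTYPE_COLUMN not in table.data.columns:
        raise ConfigurationError("table is not labeled; run phenotyping first")
    la, lb = config.label_a, config.label_b
    combos = [(la, lb), (lb, la), (la, la), (lb, lb)]
    rows = []
    pools: dict[str, dict] = {}
    for sample, roi, sub in table.iter_rois():
        A, a_ids = _roi_points(sub, la)
        B, b_ids = _roi_points(sub, lb)
        row: dict = {
            "sample_id": sample, "roi_id": roi,
            f"n_{la}": len(A), f"n_{lb}": len(B),
        }
        pool = pools.setdefault(
            sample,
            {"n_a": 0, "n_b": 0, "ab": [], "ba": [],
             "counts": {(c, n, s): [] for c, n in combos for s in config.circle_sizes},
             "n_rois": 0, "n_insufficient": 0},
        )
        pool["n_a"] += len(A)
        pool["n_b"] += len(B)
        pool["n_rois"] += 1
        if len(A) == 0 or len(B) == 0:
            row["status"] = "insufficient"
            row.update({
                "median_pooled": np.nan,
                f"median_{la}_to_{lb}": np.nan,
                f"median_{lb}_to_{la}": np.nan,
            })
            pool["n_insufficient"] += 1
            rows.append(row)
            continue
        prox = median_cross_distance(
            A, B, a_ids, b_ids, mode=config.median_mode, label_a=la, label_b=lb
        )
        row["status"] = "ok"
        row["median_pooled"] = prox.median_pooled
        row[f"median_{la}_to_{lb}"] = prox.median_a_to_b
        row[f"median_{lb}_to_{la}"] = prox.median_b_to_a
        pool["ab"].append(prox.dists_a_to_b)
        pool["ba"].append(prox.dists_b_to_a)
        pts = {la: (A, a_ids), lb: (B, b_ids)}
        for c, nb in combos:
            for size in config.circle_sizes:
                cm = neighborhood_counts(
                    pts[c][0], pts[nb][0], size,
                    size_is_diameter=config.size_is_diameter,
                    boundary=config.boundary_rule,
                    center_ids=pts[c][1], neighbor_ids=pts[nb][1],
                    center_type=c, neighbor_type=nb,
                )
                col = f"count_{nb}_around_{c}_{size:g}um"
                row[f"mean_{col}"] = float(cm.counts.mean())
                row[f"median_{col}"] = float(np.median(cm.counts))
                pool["counts"][(c, nb, size)].append(cm.counts)
        rows.append(row)

    # pooled per-sample rows
    if config.pooling == "per_sample":
        for sample, pool in pools.items():
            row = {
                "sample_id": sample, "roi_id": "pooled",
                f"n_{la}": pool["n_a"], f"n_{lb}": pool["n_b"],
            }
            if pool["ab"]:
                ab = np.concatenate(pool["ab"])
                ba = np.concatenate(pool["ba"])
                row["status"] = "ok"
                row["median_pooled"] = float(np.median(np.concatenate([ab, ba])))
                row[f"median_{la}_to_{lb}"] = float(np.median(ab))
                row[f"median_{lb}_to_{la}"] = float(np.median(ba))
                for (c, nb, size), vecs in pool["counts"].items():
                    col = f"count_{nb}_around_{c}_{size:g}um"
                    allc = np.concatenate(vecs)
                    row[f"mean_{col}"] = float(allc.mean())
                    row[f"median_{col}"] = float(np.median(allc))
            else:
                row["status"] = "insufficient"
                row["median_pooled"] = np.nan
                row[f"median_{la}_to_{lb}"] = np.nan
                row[f"median_{lb}_to_{la}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
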