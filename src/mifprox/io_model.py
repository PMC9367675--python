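"""Single-cell table container, readers/writers and analysis configuration.

The pipeline starts from post-segmentation single-cell tables: one row per
cell with sample/ROI identifiers, x/y centroid coordinates in microns and one
column per marker (either a continuous intensity >= 0 or a binary 0/1
positivity call).  Coordinates are real-valued micron centroids in an
arbitrary Cartesian frame; only inter-point distances matter, so origin and
axis orientation are irrelevant.

Input dialect is comma-delimited text with a header row.  A ``schema``
mapping binds arbitrary vendor column names to the required roles
(``cell_id``, ``sample_id``, ``roi_id``, ``x``, ``y``); unknown extra columns
are preserved and ignored so that exports from commercial image-analysis
software pass through unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    RowParseError,
    SchemaError,
    TableValidationError,
)

#: Reserved column names of the internal table layout.
ROLE_COLUMNS = ("cell_id", "sample_id", "roi_id", "x", "y")

#: Accepted header aliases for each role when no explicit schema is given.
_ROLE_ALIASES = {
    "cell_id": ("cell_id", "Cell ID", "cell"),
    "sample_id": ("sample_id", "Sample Name", "sample"),
    "roi_id": ("roi_id", "Annotation ID", "roi"),
    "x": ("x", "x_um", "Cell X Position"),
    "y": ("y", "y_um", "Cell Y Position"),
}

#: Column used by the synthetic generator for ground truth; never a marker.
GROUND_TRUTH_COLUMN = "true_label"

#: Column written by the phenotyping step.
PHENOTYPE_COLUMN = "phenotype"

Window = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


@dataclass
class CellTable:
    """Validated container for segmented single-cell records.

    Parameters
    ----------
    data
        One row per cell with at least the columns in :data:`ROLE_COLUMNS`
        plus one numeric column per marker.  Extra columns (e.g. vendor
        metadata or the generator's ground-truth label) ride along untouched.
    markers
        Names of the marker columns, in panel order.  May be empty for
        coordinate-only tables (e.g. a freshly simulated point pattern before
        marker intensities are attached).
    windows
        Optional per-ROI rectangles ``(xmin, ymin, xmax, ymax)`` in microns,
        keyed by ``(sample_id, roi_id)``.  When present, every cell of that
        ROI must lie inside its rectangle.
    """

    data: pd.DataFrame
    markers: tuple[str, ...] = ()
    windows: dict[tuple[str, str], Window] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        df = self.data
        missing = [c for c in ROLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table is missing required column(s): {missing}")
        for col in ("cell_id", "sample_id", "roi_id"):
            df[col] = df[col].astype(str)
        for axis in ("x", "y"):
            vals = df[axis].to_numpy()
            if not np.issubdtype(vals.dtype, np.number):
                raise TableValidationError(f"coordinate column '{axis}' is not numeric")
            if not np.all(np.isfinite(vals)):
                bad = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise TableValidationError(
                    f"non-finite {axis} coordinate at row {bad}"
                )
        dup = df.duplicated(subset=["sample_id", "roi_id", "cell_id"])
        if dup.any():
            first = df.loc[dup, ["sample_id", "roi_id", "cell_id"]].iloc[0]
            raise TableValidationError(
                "duplicate cell_id within ROI: "
                f"cell_id={first['cell_id']!r} in sample={first['sample_id']!r}, "
                f"roi={first['roi_id']!r}"
            )
        for m in self.markers:
            if m not in df.columns:
                raise SchemaError(f"declared marker column '{m}' not in table")
            vals = pd.to_numeric(df[m], errors="coerce")
            if vals.isna().any():
                bad = int(vals.isna().idxmax())
                raise RowParseError(
                    f"non-numeric value for marker '{m}' at row {bad}"
                )
            if (vals < 0).any():
                raise TableValidationError(f"marker '{m}' has negative values")
            df[m] = vals.astype(float)
        for (sample, roi), (xmin, ymin, xmax, ymax) in self.windows.items():
            sub = df[(df["sample_id"] == sample) & (df["roi_id"] == roi)]
            inside = (
                (sub["x"] >= xmin)
                & (sub["x"] <= xmax)
                & (sub["y"] >= ymin)
                & (sub["y"] <= ymax)
            )
            if not inside.all():
                raise TableValidationError(
                    f"cells outside declared window for ROI ({sample}, {roi})"
                )

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def marker_is_binary(self, marker: str) -> bool:
        """True if every value of *marker* is 0 or 1."""
        vals = self.data[marker].to_numpy()
        return bool(np.isin(vals, (0.0, 1.0)).all())

    def iter_rois(self) -> Iterator[tuple[str, str, pd.DataFrame]]:
        """Yield ``(sample_id, roi_id, sub-frame)`` in first-appearance order."""
        for (sample, roi), sub in self.data.groupby(
            ["sample_id", "roi_id"], sort=False
        ):
            yield str(sample), str(roi), sub

    def with_data(self, data: pd.DataFrame, markers: Sequence[str] | None = None) -> "CellTable":
        return CellTable(
            data=data.reset_index(drop=True),
            markers=self.markers if markers is None else tuple(markers),
            windows=dict(self.windows),
        )


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    markers: Sequence[str] | None = None,
) -> CellTable:
    """Read and validate a delimited-text cell table.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from role name (``cell_id``, ``sample_id``,
        ``roi_id``, ``x``, ``y``) to the column name carrying it.  Roles not
        mapped are resolved through the default aliases; ``sample_id`` and
        ``roi_id`` default to constants when absent, so single-ROI exports
        with only ``cell_id,x,y`` plus markers are accepted.
    markers
        Marker column names.  When omitted, every unclaimed fully-numeric
        column except the ground-truth/phenotype columns is taken as a
        marker, in file order.

    Units are assumed to be microns throughout; no rescaling is applied.
    Row order is preserved.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})

    colmap: dict[str, str] = {}
    for role, aliases in _ROLE_ALIASES.items():
        if role in schema:
            col = schema[role]
            if col not in raw.columns:
                raise SchemaError(
                    f"schema maps role '{role}' to column '{col}', "
                    "which is not present in the file"
                )
            colmap[role] = col
        else:
            for alias in aliases:
                if alias in raw.columns:
                    colmap[role] = alias
                    break
    for role in ("cell_id", "x", "y"):
        if role not in colmap:
            raise SchemaError(f"no column found for required role '{role}'")

    out = pd.DataFrame(index=raw.index)
    out["cell_id"] = raw[colmap["cell_id"]].astype(str)
    out["sample_id"] = (
        raw[colmap["sample_id"]].astype(str) if "sample_id" in colmap else "sample0"
    )
    out["roi_id"] = raw[colmap["roi_id"]].astype(str) if "roi_id" in colmap else "roi0"
    for axis in ("x", "y"):
        vals = pd.to_numeric(raw[colmap[axis]], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise RowParseError(
                f"non-numeric value {raw[colmap[axis]].iloc[row]!r} in coordinate "
                f"column '{colmap[axis]}' at row {row}"
            )
        out[axis] = vals.astype(float)

    claimed = set(colmap.values())
    special = {GROUND_TRUTH_COLUMN, PHENOTYPE_COLUMN}
    if markers is None:
        inferred = []
        for col in raw.columns:
            if col in claimed or col in special:
                continue
            vals = pd.to_numeric(raw[col], errors="coerce")
            if not vals.isna().any():
                inferred.append(col)
        markers = inferred
    marker_list = list(markers)
    for m in marker_list:
        if m not in raw.columns:
            raise SchemaError(f"declared marker column '{m}' not in file")
        vals = pd.to_numeric(raw[m], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise RowParseError(
                f"non-numeric value for marker '{m}' at row {row}"
            )
        out[m] = vals.astype(float)
    # preserve everything else verbatim (vendor metadata, ground truth, ...)
    for col in raw.columns:
        if col not in claimed and col not in marker_list:
            out[col] = raw[col]
    return CellTable(data=out.reset_index(drop=True), markers=tuple(marker_list))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table back to CSV with the internal column layout."""
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Settings for the spatial analysis of a labeled cell table.

    ``circle_sizes`` are the neighborhood sizes in microns; whether a size is
    a diameter or a radius is controlled by ``size_is_diameter`` (diameters
    by default, matching the operational description of counting partners
    "within a circle with a diameter of 15 microns or 25 microns").
    """

    circle_sizes: tuple[float, ...] = (15.0, 25.0)
    size_is_diameter: bool = True
    median_mode: str = "pooled"  # or "per_direction"
    boundary_rule: str = "inclusive"  # or "exclusive"
    pooling: str = "per_sample"  # or "per_roi"
    label_a: str = "ILC2"
    label_b: str = "Treg"
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.circle_sizes)
        if any(s <= 0 for s in sizes):
            raise ConfigurationError("circle_sizes must be strictly positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ConfigurationError("circle_sizes must be strictly increasing")
        self.circle_sizes = sizes
        if self.median_mode not in ("pooled", "per_direction"):
            raise ConfigurationError(f"unknown median_mode {self.median_mode!r}")
        if self.boundary_rule not in ("inclusive", "exclusive"):
            raise ConfigurationError(f"unknown boundary_rule {self.boundary_rule!r}")
        if self.pooling not in ("per_sample", "per_roi"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "circle_sizes" in payload:
            payload["circle_sizes"] = tuple(payload["circle_sizes"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# Result serialisation (round-trip safe)
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result frame as CSV; floats use Python repr so they round-trip."""
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results(result, path: str | Path) -> None:
    """Serialise a result object (or plain DataFrame) to delimited text.

    Dispatches on type: :class:`~mifprox.spatial.ProximityResult`,
    :class:`~mifprox.spatial.NeighborhoodCountMatrix`,
    :class:`~mifprox.spatial.DistancePairMatrix` and ``pandas.DataFrame``
    are supported.  Each result type defines ``to_frame`` producing a flat
    table with a ``status`` column where degenerate inputs need flagging;
    re-reading reproduces integer values exactly and floats to full repr
    precision.
    """
    if isinstance(result, pd.DataFrame):
        write_table(result, path)
        return
    to_frame = getattr(result, "to_frame", None)
    if to_frame is None:
        raise TypeError(f"cannot serialise object of type {type(result).__name__}")
    write_table(to_frame(), path)
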