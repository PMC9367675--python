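"""Thin optional rendering of distance/count matrices as heatmaps.

Purely presentational: the tested semantics live in the exported numeric
tables.  Matplotlib is imported lazily so headless pipelines that never
plot pay nothing.
"""

from __future__ import annotations

import numpy as np


def plot_distance_heatmap(matrix, ax=None, cmap: str = "RdBu"):
    """Render a :class:`~mifprox.spatial.DistancePairMatrix`.

    Red = close, blue = far (reversed colormap), matching the usual
    convention for proximity heatmaps.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(np.asarray(matrix.values), cmap=cmap, aspect="auto")
    ax.set_xlabel("cells (columns)")
    ax.set_ylabel("cells (rows)")
    ax.figure.colorbar(im, ax=ax, label="distance (µm)")
    return ax


def plot_count_heatmap(count_matrix, ax=None, cmap: str = "RdBu_r"):
    """Render per-center neighborhood counts as a single-row heatmap."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = np.asarray(count_matrix.counts, dtype=float)[None, :]
    im = ax.imshow(vals, cmap=cmap, aspect="auto")
    ax.set_yticks([])
    ax.set_xlabel(f"{count_matrix.center_type} cells")
    ax.figure.colorbar(
        im, ax=ax,
        label=f"{count_matrix.neighbor_type} within {count_matrix.circle_size:g} µm",
    )
    return ax
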