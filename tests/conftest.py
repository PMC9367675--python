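import numpy as np
import pandas as pd
import pytest

from mifprox import CellTable, SyntheticTissueConfig, simulate, attach_marker_intensities
from mifprox.io_model import GROUND_TRUTH_COLUMN, PHENOTYPE_COLUMN

MARKER_COLS = ["CD4", "CD8", "CD127", "GATA3", "Foxp3"]


def make_table(rows, markers=MARKER_COLS, windows=None):
    """Build a CellTable from a list of dicts; missing markers default to 0."""
    df = pd.DataFrame(rows)
    for col, default in (("sample_id", "s1"), ("roi_id", "r1")):
        if col not in df.columns:
            df[col] = default
    for m in markers:
        if m not in df.columns:
            df[m] = 0.0
        else:
            df[m] = df[m].fillna(0.0)
    return CellTable(data=df, markers=tuple(markers), windows=windows or {})


@pytest.fixture
def small_binary_table():
    """Three cells: one ILC2 pattern, one Treg pattern, one blank."""
    return make_table(
        [
            {"cell_id": "c1", "x": 0.0, "y": 0.0, "CD127": 1.0, "GATA3": 1.0},
            {"cell_id": "c2", "x": 3.0, "y": 4.0, "CD4": 1.0, "Foxp3": 1.0},
            {"cell_id": "c3", "x": 10.0, "y": 0.0},
        ]
    )


def labeled_from_truth(table):
    """Use the generator's ground truth directly as the phenotype label."""
    df = table.data.copy()
    df[PHENOTYPE_COLUMN] = df[GROUND_TRUTH_COLUMN]
    return table.with_data(df)


@pytest.fixture
def attractive_table():
    """Strongly co-clustered ILC2/Treg pattern with a CSR background."""
    cfg = SyntheticTissueConfig(
        window=(500.0, 500.0), lambda_a=0.002, lambda_b=0.002, lambda_other=0.002,
        model="shared_parent", parent_intensity=2e-4, sigma=5.0, seed=42,
    )
    return labeled_from_truth(simulate(cfg))
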