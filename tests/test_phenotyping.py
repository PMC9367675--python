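import itertools

import numpy as np
import pandas as pd
import pytest

from mifprox import phenotyping
from mifprox.errors import ConfigurationError
from mifprox.io_model import PHENOTYPE_COLUMN
from mifprox.phenotyping import (
    MarkerRule,
    PhenotypePanel,
    binarize_markers,
    classify_cell,
    classify_table,
    default_panel,
    parse_panel,
    panel_to_text,
)

from conftest import make_table

MARKERS = ("CD4", "CD8", "CD127", "GATA3", "Foxp3")


def test_binarize_is_strictly_greater_than(small_binary_table):
    table = make_table(
        [
            {"cell_id": "c1", "x": 0, "y": 0, "CD4": 5.0},
            {"cell_id": "c2", "x": 1, "y": 0, "CD4": 3.0},
            {"cell_id": "c3", "x": 2, "y": 0, "CD4": 0.0},
        ],
        markers=["CD4"],
    )
    out = binarize_markers(table, {"CD4": 3.0})
    assert list(out.data["CD4"]) == [1.0, 0.0, 0.0]
    # original intensities retained alongside
    assert list(out.data["CD4_intensity"]) == [5.0, 3.0, 0.0]


def test_binarize_requires_threshold_for_continuous_marker():
    table = make_table([{"cell_id": "c", "x": 0, "y": 0, "CD4": 2.5}], markers=["CD4"])
    with pytest.raises(ConfigurationError, match="CD4"):
        binarize_markers(table, {})


@pytest.mark.parametrize(
    "pattern,expected",
    [
        ({"CD4": 0, "CD8": 0, "CD127": 1, "GATA3": 1, "Foxp3": 0}, "ILC2"),
        ({"CD4": 1, "CD8": 0, "CD127": 0, "GATA3": 0, "Foxp3": 1}, "Treg"),
        ({"CD4": 0, "CD8": 0, "CD127": 0, "GATA3": 0, "Foxp3": 0}, "other"),
        # CD8+ blocks the ILC2 gate even with CD127+GATA3+
        ({"CD4": 0, "CD8": 1, "CD127": 1, "GATA3": 1, "Foxp3": 0}, "other"),
        # Treg needs both CD4 and Foxp3
        ({"CD4": 1, "CD8": 0, "CD127": 0, "GATA3": 0, "Foxp3": 0}, "other"),
    ],
)
def test_default_gates(pattern, expected):
    assert classify_cell(pattern, default_panel()) == expected


def test_default_panel_gates_are_mutually_exclusive():
    """Exhaustive over all 2^5 binary patterns: no cell can satisfy both the
    ILC2 gate (requires CD4-) and the Treg gate (requires CD4+)."""
    panel = default_panel()
    for bits in itertools.product((0, 1), repeat=5):
        cell = dict(zip(MARKERS, map(float, bits)))
        ilc2 = cell["CD4"] == 0 and cell["CD8"] == 0 and cell["CD127"] == 1 and cell["GATA3"] == 1
        treg = cell["CD4"] == 1 and cell["Foxp3"] == 1
        assert not (ilc2 and treg)
        expected = "ILC2" if ilc2 else ("Treg" if treg else "other")
        assert classify_cell(cell, panel) == expected


def test_classify_cell_missing_marker_names_it():
    with pytest.raises(ConfigurationError, match="Foxp3"):
        classify_cell({"CD4": 1, "CD8": 0, "CD127": 0, "GATA3": 0}, default_panel())


def test_classify_table_counts_partition(small_binary_table):
    labeled, counts, n_multi = classify_table(small_binary_table, default_panel())
    assert list(labeled.data[PHENOTYPE_COLUMN]) == ["ILC2", "Treg", "other"]
    by_label = counts.groupby("label")["n"].sum().to_dict()
    assert by_label == {"ILC2": 1, "Treg": 1, "other": 1}
    assert counts["n"].sum() == len(small_binary_table)
    assert n_multi == 0


def test_classify_table_empty():
    base = make_table([{"cell_id": "c", "x": 0.0, "y": 0.0}])
    table = base.with_data(base.data.iloc[:0])
    labeled, counts, n_multi = classify_table(table, default_panel())
    assert len(labeled) == 0
    assert counts.empty
    assert n_multi == 0


def test_labels_independent_of_row_order(small_binary_table):
    panel = default_panel()
    labeled, _, _ = classify_table(small_binary_table, panel)
    shuffled = small_binary_table.with_data(
        small_binary_table.data.sample(frac=1.0, random_state=7)
    )
    labeled2, _, _ = classify_table(shuffled, panel)
    m1 = labeled.data.set_index("cell_id")[PHENOTYPE_COLUMN]
    m2 = labeled2.data.set_index("cell_id")[PHENOTYPE_COLUMN]
    assert m1.sort_index().equals(m2.sort_index())


def test_first_match_wins_and_multi_match_counted():
    panel = PhenotypePanel(
        phenotypes=[
            ("broad", [MarkerRule("CD4", "positive")]),
            ("narrow", [MarkerRule("CD4", "positive"), MarkerRule("Foxp3", "positive")]),
        ]
    )
    table = make_table(
        [{"cell_id": "c", "x": 0, "y": 0, "CD4": 1.0, "Foxp3": 1.0}],
        markers=["CD4", "Foxp3"],
    )
    labeled, _, n_multi = classify_table(table, panel)
    assert labeled.data[PHENOTYPE_COLUMN].iloc[0] == "broad"
    assert n_multi == 1


def test_panel_text_round_trip():
    text = """
phenotypes:
  ILC2: [CD4:-, CD8:-, CD127:+, GATA3:+]
  Treg: [CD4:+, Foxp3:+]
fallback: other
thresholds: {CD127: 2.0}
"""
    panel = parse_panel(text)
    assert panel.labels == ["ILC2", "Treg"]
    assert panel.phenotypes[0][1][2].threshold == 2.0
    again = parse_panel(panel_to_text(panel))
    assert again == panel


def test_suggest_threshold_separates_bimodal():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(1, 0.5, 200), rng.normal(10, 0.5, 200)])
    thr = phenotyping.suggest_threshold(np.clip(vals, 0, None))
    assert 2.0 < thr < 9.0
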