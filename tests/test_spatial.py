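import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mifprox import spatial
from mifprox.errors import ConfigurationError, DegenerateInputError, DomainError
from mifprox.io_model import AnalysisConfig, PHENOTYPE_COLUMN
from mifprox.spatial import (
    directed_nn,
    median_cross_distance,
    neighborhood_counts,
    pairwise_distances,
    summarize_sample,
)

from conftest import labeled_from_truth, make_table


def brute_nn(A, B, a_ids, b_ids):
    """Independent exhaustive nearest-neighbor search with the same tie rule
    (smallest partner id at equal distance)."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    dists, partners = [], []
    for i in range(len(A)):
        d = np.sqrt(((B - A[i]) ** 2).sum(axis=1))
        keep = np.array([b_ids[j] != a_ids[i] for j in range(len(B))])
        dmin = d[keep].min()
        ties = [b_ids[j] for j in range(len(B)) if keep[j] and d[j] == dmin]
        dists.append(dmin)
        partners.append(min(ties))
    return np.array(dists), partners


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


def test_pairwise_3_4_5():
    m = pairwise_distances([(0.0, 0.0)], [(3.0, 4.0)])
    assert m.values.tolist() == [[5.0]]


def test_pairwise_symmetric_zero_diagonal():
    pts = [(0.0, 0.0), (1.0, 0.0)]
    m = pairwise_distances(pts, pts)
    assert np.allclose(m.values, [[0, 1], [1, 0]])
    assert np.allclose(m.values, m.values.T)


def test_pairwise_matches_double_loop():
    rng = np.random.default_rng(5)
    A, B = rng.uniform(0, 100, (20, 2)), rng.uniform(0, 100, (30, 2))
    m = pairwise_distances(A, B)
    oracle = np.array(
        [[np.sqrt(((a - b) ** 2).sum()) for b in B] for a in A]
    )
    assert np.allclose(m.values, oracle, rtol=1e-9, atol=0)


def test_pairwise_empty_set_names_the_culprit():
    with pytest.raises(DegenerateInputError, match="B"):
        pairwise_distances([(0.0, 0.0)], np.empty((0, 2)))
    with pytest.raises(DegenerateInputError, match="A"):
        pairwise_distances(np.empty((0, 2)), [(0.0, 0.0)])


# ---------------------------------------------------------------------------
# directed nearest neighbors
# ---------------------------------------------------------------------------


def test_directed_nn_unique_minimum():
    d, partners = directed_nn(
        [(0.0, 0.0)], [(3.0, 4.0), (10.0, 0.0)], ["a"], ["near", "far"]
    )
    assert d.tolist() == [5.0]
    assert partners == ["near"]


def test_directed_nn_coincident_points_give_zero():
    d, partners = directed_nn([(2.0, 2.0)], [(2.0, 2.0)], ["a"], ["b"])
    assert d.tolist() == [0.0]
    assert partners == ["b"]


def test_directed_nn_tie_broken_by_smallest_id():
    d, partners = directed_nn(
        [(0.0, 0.0)], [(1.0, 0.0), (0.0, 1.0)], ["q"], ["zz", "aa"]
    )
    assert d.tolist() == [1.0]
    assert partners == ["aa"]


def test_directed_nn_excludes_self_by_id():
    pts = [(0.0, 0.0), (5.0, 0.0)]
    ids = ["c1", "c2"]
    d, partners = directed_nn(pts, pts, ids, ids)
    assert d.tolist() == [5.0, 5.0]
    assert partners == ["c2", "c1"]
    # sole candidate being the cell itself means no valid neighbor exists
    with pytest.raises(DegenerateInputError):
        directed_nn([(0.0, 0.0)], [(0.0, 0.0)], ["c1"], ["c1"])


def test_directed_nn_row_order_invariance():
    rng = np.random.default_rng(11)
    A, B = rng.uniform(0, 50, (25, 2)), rng.uniform(0, 50, (40, 2))
    a_ids = [f"a{i}" for i in range(25)]
    b_ids = [f"b{i:02d}" for i in range(40)]
    d1, p1 = directed_nn(A, B, a_ids, b_ids)
    perm = rng.permutation(40)
    d2, p2 = directed_nn(A, B[perm], a_ids, [b_ids[j] for j in perm])
    assert (d1 == d2).all()
    assert p1 == p2


# ---------------------------------------------------------------------------
# median cross-distance
# ---------------------------------------------------------------------------


def test_median_singletons():
    r = median_cross_distance([(0.0, 0.0)], [(3.0, 4.0)])
    assert r.median_pooled == r.median_a_to_b == r.median_b_to_a == 5.0


def test_median_hand_computed_order_statistics():
    r = median_cross_distance([(0.0, 0.0), (100.0, 0.0)], [(1.0, 0.0)])
    assert sorted(r.dists_a_to_b.tolist()) == [1.0, 99.0]
    assert r.dists_b_to_a.tolist() == [1.0]
    assert r.median_pooled == 1.0  # median of pooled {1, 99, 1}
    assert r.median_a_to_b == 50.0  # even-length midpoint convention


def test_median_undefined_on_empty_side_never_silent_zero():
    r = median_cross_distance(np.empty((0, 2)), [(0.0, 0.0)])
    assert r.status == "undefined"
    assert r.median_pooled is None and r.median_a_to_b is None
    assert len(r.pooled) == 0


def test_median_non_increasing_when_b_points_added():
    rng = np.random.default_rng(3)
    A = rng.uniform(0, 100, (30, 2))
    B = rng.uniform(0, 100, (10, 2))
    extra = rng.uniform(0, 100, (15, 2))
    m_small = median_cross_distance(A, B).median_a_to_b
    m_large = median_cross_distance(A, np.vstack([B, extra])).median_a_to_b
    assert m_large <= m_small


# ---------------------------------------------------------------------------
# neighborhood counts
# ---------------------------------------------------------------------------


def test_count_15um_diameter_reaches_only_the_near_cell():
    cm = neighborhood_counts([(0.0, 0.0)], [(3.0, 0.0), (8.0, 0.0)], 15.0)
    assert cm.counts.tolist() == [1]  # r = 7.5; 3 <= 7.5 < 8


def test_count_25um_diameter_reaches_both():
    cm = neighborhood_counts([(0.0, 0.0)], [(3.0, 0.0), (8.0, 0.0)], 25.0)
    assert cm.counts.tolist() == [2]


def test_boundary_rule_inclusive_vs_exclusive():
    args = ([(0.0, 0.0)], [(7.5, 0.0)], 15.0)
    assert neighborhood_counts(*args, boundary="inclusive").counts.tolist() == [1]
    assert neighborhood_counts(*args, boundary="exclusive").counts.tolist() == [0]


def test_size_as_radius():
    cm = neighborhood_counts(
        [(0.0, 0.0)], [(3.0, 0.0), (8.0, 0.0)], 7.5, size_is_diameter=False
    )
    assert cm.counts.tolist() == [1]


def test_counts_never_include_self_and_empty_neighbors_flagged():
    pts = [(0.0, 0.0), (1.0, 0.0)]
    ids = ["c1", "c2"]
    cm = neighborhood_counts(pts, pts, 25.0, center_ids=ids, neighbor_ids=ids)
    assert cm.counts.tolist() == [1, 1]
    empty = neighborhood_counts(pts, np.empty((0, 2)), 25.0, center_ids=ids)
    assert empty.counts.tolist() == [0, 0]
    assert empty.status == "no_neighbors"


def test_counts_monotone_in_circle_size():
    rng = np.random.default_rng(9)
    C, N = rng.uniform(0, 200, (50, 2)), rng.uniform(0, 200, (200, 2))
    c15 = neighborhood_counts(C, N, 15.0).counts
    c25 = neighborhood_counts(C, N, 25.0).counts
    assert (c25 >= c15).all()
    assert (c25 <= len(N)).all()


def test_invalid_inputs():
    with pytest.raises(DomainError):
        neighborhood_counts([(0.0, 0.0)], [(1.0, 0.0)], 0.0)
    with pytest.raises(DegenerateInputError):
        neighborhood_counts(np.empty((0, 2)), [(1.0, 0.0)], 15.0)
    with pytest.raises(ConfigurationError):
        neighborhood_counts([(0.0, 0.0)], [(1.0, 0.0)], 15.0, boundary="sometimes")


# ---------------------------------------------------------------------------
# scale equivariance (property)
# ---------------------------------------------------------------------------


@settings(derandomize=True, max_examples=25, deadline=None)
@given(scale=st.floats(min_value=0.01, max_value=1000.0, allow_nan=False))
def test_scale_equivariance(scale):
    rng = np.random.default_rng(21)
    A, B = rng.uniform(0, 100, (15, 2)), rng.uniform(0, 100, (20, 2))
    base = median_cross_distance(A, B)
    scaled = median_cross_distance(A * scale, B * scale)
    assert np.allclose(scaled.pooled, base.pooled * scale, rtol=1e-9)
    assert np.isclose(scaled.median_pooled, base.median_pooled * scale, rtol=1e-9)
    c = neighborhood_counts(A, B, 15.0).counts
    c_scaled = neighborhood_counts(A * scale, B * scale, 15.0 * scale).counts
    assert (c == c_scaled).all()


# ---------------------------------------------------------------------------
# per-sample summaries
# ---------------------------------------------------------------------------


def _two_type_table(rows):
    table = make_table(rows)
    df = table.data
    df[PHENOTYPE_COLUMN] = df.pop("label")
    return table.with_data(df)


def test_single_roi_sample_pools_to_itself():
    table = _two_type_table(
        [
            {"cell_id": "i1", "x": 0.0, "y": 0.0, "label": "ILC2"},
            {"cell_id": "i2", "x": 20.0, "y": 0.0, "label": "ILC2"},
            {"cell_id": "t1", "x": 3.0, "y": 4.0, "label": "Treg"},
        ]
    )
    s = summarize_sample(table, AnalysisConfig())
    roi = s[s["roi_id"] != "pooled"].iloc[0]
    pooled = s[s["roi_id"] == "pooled"].iloc[0]
    for col in ("median_pooled", "median_ILC2_to_Treg", "n_ILC2", "n_Treg"):
        assert roi[col] == pooled[col]


def test_sample_with_zero_tregs_is_flagged_not_zeroed():
    table = _two_type_table(
        [
            {"cell_id": "i1", "x": 0.0, "y": 0.0, "label": "ILC2"},
            {"cell_id": "i2", "x": 5.0, "y": 0.0, "label": "ILC2"},
        ]
    )
    s = summarize_sample(table, AnalysisConfig())
    assert set(s["status"]) == {"insufficient"}
    assert s["median_pooled"].isna().all()


def test_distances_never_cross_roi_boundaries():
    # the only Treg in roi r2 is far; the near ILC2 lives in roi r1
    table = _two_type_table(
        [
            {"cell_id": "i1", "roi_id": "r1", "x": 0.0, "y": 0.0, "label": "ILC2"},
            {"cell_id": "t1", "roi_id": "r1", "x": 1.0, "y": 0.0, "label": "Treg"},
            {"cell_id": "i2", "roi_id": "r2", "x": 0.0, "y": 0.0, "label": "ILC2"},
            {"cell_id": "t2", "roi_id": "r2", "x": 60.0, "y": 0.0, "label": "Treg"},
        ]
    )
    s = summarize_sample(table, AnalysisConfig())
    r2 = s[s["roi_id"] == "r2"].iloc[0]
    assert r2["median_pooled"] == 60.0  # not 1.0 from the other section
    pooled = s[s["roi_id"] == "pooled"].iloc[0]
    assert pooled["median_pooled"] == np.median([1.0, 1.0, 60.0, 60.0])


def test_attractive_sample_has_smaller_median_than_csr(attractive_table):
    from mifprox import SyntheticTissueConfig, simulate_csr
    from conftest import labeled_from_truth

    csr = labeled_from_truth(
        simulate_csr(
            SyntheticTissueConfig(
                window=(500.0, 500.0), lambda_a=0.002, lambda_b=0.002, seed=7
            )
        )
    )
    cfg = AnalysisConfig()
    med_attr = summarize_sample(attractive_table, cfg)
    med_csr = summarize_sample(csr, cfg)
    m_attr = med_attr[med_attr["roi_id"] == "pooled"]["median_pooled"].iloc[0]
    m_csr = med_csr[med_csr["roi_id"] == "pooled"]["median_pooled"].iloc[0]
    assert m_attr < m_csr
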