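"""Repertoire matrices: set partitions, truth recovery, marginals."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from tickpi import (
    ConditionAxis,
    Library,
    ProteinRecord,
    build_repertoire_matrix,
    cluster_presence,
    marginal_total,
    partition_two_way,
    share_percent,
)
from tickpi.cluster import RedundancyCluster
from tickpi.datasets import published_axis_matrix
from tickpi.pipeline import dedup_all, repertoire_all
from tickpi.repertoire import timepoint_table


# --------------------------------------------------------- partitioning ----


def test_partition_matches_published_kazal_row():
    # 13 female-present and 19 male-present inhibitors with 11 shared
    female = set(range(13))
    male = set(range(2, 21))
    assert partition_two_way(female, male) == (2, 8, 11)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(0, 30)),
    st.sets(st.integers(0, 30)),
)
def test_partition_two_way_properties(left, right):
    lx, rx, sh = partition_two_way(left, right)
    assert lx + sh == len(left)
    assert rx + sh == len(right)
    assert lx + rx + sh == len(left | right)
    # axis symmetry: swapping sides swaps exclusives, fixes shared
    assert partition_two_way(right, left) == (rx, lx, sh)


def test_cluster_presence_is_union_of_member_memberships():
    records = {
        "a": ProteinRecord("a", "aam", "MKT", library_ids={"L1"}),
        "b": ProteinRecord("b", "aam", "MKT", library_ids={"L2"}),
    }
    cluster = RedundancyCluster("I2", "aam", "a", ["a", "b"], {"a": 100.0, "b": 100.0})
    assert cluster_presence(cluster, records) == {"L1", "L2"}


# ---------------------------------------------------------- matrix build ----


def _libs():
    return [
        Library("WF", "aam", sex="F", feeding_state="fed", tissue="whole"),
        Library("WM", "aam", sex="M", feeding_state="unfed", tissue="whole"),
        Library("SG48", "aam", sex="F", feeding_state="fed", tissue="SG", timepoint_h=48),
        Library("MG48", "aam", sex="F", feeding_state="fed", tissue="MG", timepoint_h=48),
    ]


def _singleton(rid, libs):
    return (
        RedundancyCluster("I2", "aam", rid, [rid], {rid: 100.0}),
        ProteinRecord(rid, "aam", "MKTAYIAALL", library_ids=libs),
    )


def test_sg_only_cluster_counts_left_exclusive_on_tissue_axis():
    cluster, record = _singleton("a", {"SG48"})
    axis = ConditionAxis.from_libraries(_libs(), "tissue")
    matrix = build_repertoire_matrix([cluster], {"a": record}, axis)
    assert tuple(matrix.data.loc["I2", ["left_exclusive", "right_exclusive", "shared"]]) == (1, 0, 0)


def test_whole_body_only_cluster_is_neither_tissue():
    cluster, record = _singleton("a", {"WF"})
    axis = ConditionAxis.from_libraries(_libs(), "tissue")
    matrix = build_repertoire_matrix([cluster], {"a": record}, axis)
    assert matrix.data.loc["I2", "neither"] == 1
    assert matrix.data.loc["I2", "detected"] == 0


def test_axis_sides_must_be_disjoint():
    with pytest.raises(ValueError, match="share"):
        ConditionAxis("sex", "F", "M", frozenset({"L1"}), frozenset({"L1"}))


def test_unknown_axis_rejected():
    with pytest.raises(ValueError, match="unknown axis"):
        ConditionAxis.from_libraries(_libs(), "altitude")


def test_matrix_equals_planted_truth_on_all_axes(scenario):
    """End-to-end: matrices built from recovered clusters equal the
    generator's expected matrices cell-for-cell on every axis."""
    clusters = dedup_all(scenario.records, scenario.truth.family_of)
    matrices = repertoire_all(
        clusters,
        scenario.records,
        scenario.libraries,
        "aam",
        families=scenario.config.families,
    )
    for axis_name, matrix in matrices.items():
        assert matrix.data.equals(scenario.truth.expected_matrices[axis_name])


def test_row_conservation_and_detected_bound(scenario):
    clusters = dedup_all(scenario.records, scenario.truth.family_of)
    matrices = repertoire_all(
        clusters, scenario.records, scenario.libraries, "aam",
        families=scenario.config.families,
    )
    for matrix in matrices.values():
        d = matrix.data
        assert (
            d["left_exclusive"] + d["right_exclusive"] + d["shared"]
            == d["detected"]
        ).all()
        assert (d["detected"] + d["neither"] == d["row_total"]).all()


# ----------------------------------------------------------- marginals -----


def test_published_totals_row_marginals():
    feeding = published_axis_matrix("feeding", totals_only=True)
    assert marginal_total(feeding, "left") == 442  # fed
    assert marginal_total(feeding, "right") == 231  # unfed
    tissue = published_axis_matrix("tissue", totals_only=True)
    assert marginal_total(tissue, "left") == 206  # SG
    assert marginal_total(tissue, "right") == 164  # MG


def test_published_family_rows_kunitz_and_kazal():
    tissue = published_axis_matrix("tissue")
    assert tissue.data.loc["I2", "left_exclusive"] + tissue.data.loc["I2", "shared"] == 87
    sex = published_axis_matrix("sex")
    assert sex.data.loc["I1", "left_exclusive"] + sex.data.loc["I1", "shared"] == 13
    assert sex.data.loc["I1", "right_exclusive"] + sex.data.loc["I1", "shared"] == 19


def test_share_percent_rounds_half_up():
    assert share_percent(164, 515) == 32
    assert share_percent(202, 515) == 39
    assert share_percent(0, 10) == 0
    assert share_percent(1, 8) == 13  # 12.5 rounds up
    with pytest.raises(ValueError):
        share_percent(1, 0)


def test_empty_matrix_marginal_is_zero():
    axis = ConditionAxis.from_libraries(_libs(), "sex")
    matrix = build_repertoire_matrix([], {}, axis)
    assert marginal_total(matrix, "left") == 0


# ----------------------------------------------------------- timepoints ----


def test_timepoint_table_marks_conditions():
    libs = _libs()
    cluster, record = _singleton("a", {"SG48"})
    table = timepoint_table([cluster], {"a": record}, libs)
    row = table.set_index("representative").loc["a"]
    assert row["SG48"] == 1 and row["MG48"] == 0
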