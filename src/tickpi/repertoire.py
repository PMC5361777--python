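"""Presence/absence repertoire matrices across condition axes.

After redundancy collapse, each non-redundant inhibitor (cluster) is marked
present in every library any of its member sequences was observed in.  For a
two-sided condition axis — female vs male, fed vs unfed, salivary gland vs
midgut — the family repertoire splits into counts exclusive to one side,
exclusive to the other, and shared, the structure of a comparative
repertoire table.

A cluster detected in no library of either axis side (possible on the tissue
axis, whose libraries do not cover whole-body data) is surfaced in a
``neither`` column rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster import RedundancyCluster
from .families import FAMILY_IDS, family_sort_key
from .records import Library, ProteinRecord, round_half_up

#: axis name -> (library attribute, left token, right token, left/right labels)
AXES = {
    "sex": ("sex", "F", "M", ("F", "M")),
    "feeding": ("feeding_state", "fed", "unfed", ("FD", "UF")),
    "tissue": ("tissue", "SG", "MG", ("SG", "MG")),
}

MATRIX_COLUMNS = [
    "left_exclusive", "right_exclusive", "shared",
    "detected", "neither", "row_total",
]


@dataclass(frozen=True)
class ConditionAxis:
    """A two-sided comparison axis defined by disjoint library sets."""

    axis_name: str
    left_label: str
    right_label: str
    left_library_ids: frozenset[str]
    right_library_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.left_library_ids & self.right_library_ids:
            raise ValueError(
                f"axis {self.axis_name}: sides share libraries "
                f"{sorted(self.left_library_ids & self.right_library_ids)}"
            )

    @classmethod
    def from_libraries(
        cls, libraries: Sequence[Library], axis_name: str
    ) -> "ConditionAxis":
        if axis_name not in AXES:
            raise ValueError(
                f"unknown axis {axis_name!r}; known: {sorted(AXES)}"
            )
        attr, left_tok, right_tok, (llab, rlab) = AXES[axis_name]
        left = frozenset(
            lib.library_id for lib in libraries if getattr(lib, attr) == left_tok
        )
        right = frozenset(
            lib.library_id for lib in libraries if getattr(lib, attr) == right_tok
        )
        return cls(axis_name, llab, rlab, left, right)


@dataclass
class RepertoireMatrix:
    """Per-family exclusive/shared counts along one condition axis.

    ``data`` is indexed by family with columns left_exclusive,
    right_exclusive, shared, detected (= sum of the three), neither
    (clusters in no axis library) and row_total (non-redundant count).
    """

    axis: ConditionAxis
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != MATRIX_COLUMNS:
            raise ValueError(f"matrix columns must be {MATRIX_COLUMNS}")
        bad = self.data[
            self.data["detected"]
            != self.data[["left_exclusive", "right_exclusive", "shared"]].sum(axis=1)
        ]
        if len(bad):
            raise ValueError(f"detected != L+R+shared for families {list(bad.index)}")
        if (self.data["detected"] > self.data["row_total"]).any():
            raise ValueError("detected count exceeds non-redundant total")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    def totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def with_totals_row(self) -> pd.DataFrame:
        out = self.data.copy()
        out.loc["total"] = self.totals()
        return out


def cluster_presence(
    cluster: RedundancyCluster, records_by_id: Mapping[str, ProteinRecord]
) -> frozenset[str]:
    """Libraries a cluster is present in: the union of member memberships."""
    libs: set[str] = set()
    for member in cluster.member_ids:
        libs |= records_by_id[member].library_ids
    return frozenset(libs)


def partition_two_way(
    left_present: Iterable, right_present: Iterable
) -> tuple[int, int, int]:
    """(left-exclusive, right-exclusive, shared) counts of two presence sets."""
    left, right = set(left_present), set(right_present)
    return len(left - right), len(right - left), len(left & right)


def build_repertoire_matrix(
    clusters: Sequence[RedundancyCluster],
    records_by_id: Mapping[str, ProteinRecord],
    axis: ConditionAxis,
    *,
    families: Sequence[str] = FAMILY_IDS,
) -> RepertoireMatrix:
    """Build the per-family exclusive/shared matrix for one species.

    Families with no detected cluster are retained as zero rows.
    """
    species = {c.species_code for c in clusters}
    if len(species) > 1:
        raise ValueError(
            f"repertoire matrix is per-species; got {sorted(species)}"
        )
    fams = sorted(set(families), key=family_sort_key)
    unknown = {c.family_id for c in clusters} - set(fams)
    if unknown:
        raise ValueError(f"clusters carry families outside the set: {sorted(unknown)}")

    rows = {}
    for fam in fams:
        fam_clusters = [c for c in clusters if c.family_id == fam]
        left_present, right_present, neither = set(), set(), 0
        for k, c in enumerate(fam_clusters):
            libs = cluster_presence(c, records_by_id)
            on_left = bool(libs & axis.left_library_ids)
            on_right = bool(libs & axis.right_library_ids)
            if on_left:
                left_present.add(k)
            if on_right:
                right_present.add(k)
            if not (on_left or on_right):
                neither += 1
        lx, rx, sh = partition_two_way(left_present, right_present)
        rows[fam] = {
            "left_exclusive": lx,
            "right_exclusive": rx,
            "shared": sh,
            "detected": lx + rx + sh,
            "neither": neither,
            "row_total": len(fam_clusters),
        }
    data = pd.DataFrame.from_dict(rows, orient="index", dtype=int)[MATRIX_COLUMNS]
    return RepertoireMatrix(axis=axis, data=data)


def marginal_total(matrix: RepertoireMatrix, side: str) -> int:
    """Total clusters present on one axis side: exclusive + shared, summed
    over families (e.g. the "found in fed ticks" headline count)."""
    if side == "left":
        col = "left_exclusive"
    elif side == "right":
        col = "right_exclusive"
    else:
        raise ValueError("side must be 'left' or 'right'")
    return int((matrix.data[col] + matrix.data["shared"]).sum())


def share_percent(count: int, total: int) -> int:
    """100*count/total rounded half-up to the nearest integer."""
    if total < 1:
        raise ValueError("total must be >= 1")
    return int(round_half_up(100.0 * count / total, 0))


def timepoint_table(
    clusters: Sequence[RedundancyCluster],
    records_by_id: Mapping[str, ProteinRecord],
    libraries: Sequence[Library],
) -> pd.DataFrame:
    """Supplementary per-cluster presence across tissue x time point.

    One row per cluster (labelled by representative), one 0/1 column per
    dissected-tissue library condition (e.g. SG48, MG120), ordered by tissue
    then time.
    """
    conds = sorted(
        {
            (lib.tissue, lib.timepoint_h)
            for lib in libraries
            if lib.tissue in ("SG", "MG")
        },
        key=lambda t: (t[0], t[1]),
    )
    cond_libs = {
        cond: {
            lib.library_id
            for lib in libraries
            if (lib.tissue, lib.timepoint_h) == cond
        }
        for cond in conds
    }
    rows = []
    for c in clusters:
        libs = cluster_presence(c, records_by_id)
        row = {"representative": c.representative_id, "family": c.family_id}
        for tissue, tp in conds:
            row[f"{tissue}{tp}"] = int(bool(libs & cond_libs[(tissue, tp)]))
        rows.append(row)
    return pd.DataFrame(rows)
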