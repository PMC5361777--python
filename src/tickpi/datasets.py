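"""Published repertoire counts for ixodid tick protease inhibitors.

These are the printed summary numbers of a comparative survey of tick
protease-inhibitor (PI) repertoires: per-family non-redundant counts across
26 ixodid species, and the *Amblyomma americanum* presence/absence table
(per family: counts exclusive to females/males, fed/unfed, salivary gland/
midgut, and shared).  They serve as worked-example inputs for the repertoire
arithmetic (marginal totals, catalytic-type rollups, share percentages) and
as cross-checks in the test suite; they are transcribed data, not outputs of
this package.

Notes on internal consistency of the source table: the per-family rows for
the footnoted families I4 and I68 do not sum to their printed totals (they
were imported from earlier studies), so the printed column-totals row is
kept separately and is the authoritative input for marginal arithmetic.
The survey's printed cysteine/metallo aggregate counts (164/134) likewise
disagree with its own per-family component counts, which sum to 206 and 167
and do reproduce the printed percentages; this module carries the component
counts.
"""

from __future__ import annotations

import pandas as pd

from .repertoire import ConditionAxis, RepertoireMatrix, MATRIX_COLUMNS

#: Non-redundant PI counts per MEROPS family across 26 ixodid tick species.
#: Serine-inhibitor families: I1, I2, I4, I8, I21, I51, I53, I72, I74
#: (sum 1,159 of the 1,595 total).
TICK_PI_FAMILY_COUNTS: dict[str, int] = {
    "I1": 61,
    "I2": 527,
    "I4": 287,
    "I8": 237,
    "I21": 3,
    "I25": 102,
    "I29": 39,
    "I31": 53,
    "I32": 12,
    "I35": 6,
    "I39": 63,
    "I43": 75,
    "I51": 31,
    "I53": 10,
    "I63": 62,
    "I68": 24,
    "I72": 2,
    "I74": 1,
}

#: A. americanum per-family presence/absence counts.  Columns: exclusive to
#: female (F) / male (M) and shared (FM); fed (FD) / unfed (UF) and shared
#: (FDUF); salivary gland (SG) / midgut (MG) and shared (SGMG); and the
#: family's non-redundant total.  ``None`` marks cells the source left blank
#: (family I68, imported from a salivary-gland-only study).
AMBLYOMMA_TABLE: dict[str, dict[str, int | None]] = {
    "I1": dict(F=2, M=8, FM=11, FD=8, UF=1, FDUF=12, SG=3, MG=2, SGMG=6, total=21),
    "I2": dict(F=69, M=35, FM=73, FD=102, UF=30, FDUF=45, SG=60, MG=14, SGMG=27, total=177),
    "I4": dict(F=33, M=57, FM=31, FD=87, UF=12, FDUF=21, SG=12, MG=10, SGMG=26, total=122),
    "I8": dict(F=6, M=2, FM=9, FD=6, UF=2, FDUF=9, SG=5, MG=0, SGMG=5, total=17),
    "I21": dict(F=0, M=0, FM=1, FD=0, UF=0, FDUF=1, SG=0, MG=0, SGMG=1, total=1),
    "I25": dict(F=6, M=10, FM=12, FD=17, UF=0, FDUF=11, SG=3, MG=3, SGMG=9, total=28),
    "I29": dict(F=7, M=7, FM=1, FD=12, UF=1, FDUF=2, SG=1, MG=4, SGMG=1, total=15),
    "I31": dict(F=2, M=0, FM=4, FD=3, UF=1, FDUF=2, SG=0, MG=1, SGMG=4, total=6),
    "I32": dict(F=0, M=0, FM=2, FD=0, UF=0, FDUF=2, SG=0, MG=0, SGMG=2, total=2),
    "I35": dict(F=1, M=0, FM=0, FD=0, UF=0, FDUF=1, SG=0, MG=0, SGMG=1, total=1),
    "I39": dict(F=13, M=2, FM=13, FD=14, UF=4, FDUF=10, SG=8, MG=5, SGMG=9, total=28),
    "I43": dict(F=17, M=10, FM=7, FD=14, UF=11, FDUF=9, SG=8, MG=7, SGMG=3, total=34),
    "I51": dict(F=0, M=9, FM=5, FD=9, UF=0, FDUF=5, SG=1, MG=0, SGMG=4, total=14),
    "I63": dict(F=8, M=8, FM=32, FD=9, UF=9, FDUF=30, SG=0, MG=12, SGMG=7, total=48),
    "I68": dict(F=1, M=None, FM=None, FD=None, UF=None, FDUF=None, SG=1, MG=None, SGMG=None, total=1),
}

#: The survey's printed column-totals row for the table above (kept verbatim;
#: see module docstring on why it is not recomputed from the family rows).
AMBLYOMMA_TOTALS: dict[str, int] = dict(
    F=164, M=148, FM=202, FD=282, UF=71, FDUF=160, SG=101, MG=59, SGMG=105,
    total=515,
)

_AXIS_KEYS = {
    "sex": ("F", "M", "FM"),
    "feeding": ("FD", "UF", "FDUF"),
    "tissue": ("SG", "MG", "SGMG"),
}

_AXIS_LABELS = {
    "sex": ("F", "M"),
    "feeding": ("FD", "UF"),
    "tissue": ("SG", "MG"),
}


def published_axis_matrix(
    axis_name: str, *, totals_only: bool = False
) -> RepertoireMatrix:
    """Build a :class:`RepertoireMatrix` from the published table.

    With ``totals_only`` the matrix has the single printed totals row (the
    authoritative input for marginal arithmetic); otherwise one row per
    family, blank source cells read as zero.
    """
    lkey, rkey, skey = _AXIS_KEYS[axis_name]
    llab, rlab = _AXIS_LABELS[axis_name]
    source: dict[str, dict] = (
        {"all": AMBLYOMMA_TOTALS} if totals_only else AMBLYOMMA_TABLE
    )
    rows = {}
    for fam, row in source.items():
        lx = row[lkey] or 0
        rx = row[rkey] or 0
        sh = row[skey] or 0
        total = row["total"] or 0
        detected = lx + rx + sh
        rows[fam] = {
            "left_exclusive": lx,
            "right_exclusive": rx,
            "shared": sh,
            "detected": detected,
            "neither": max(total - detected, 0),
            "row_total": max(total, detected),
        }
    data = pd.DataFrame.from_dict(rows, orient="index", dtype=int)[MATRIX_COLUMNS]
    axis = ConditionAxis(
        axis_name=axis_name,
        left_label=llab,
        right_label=rlab,
        left_library_ids=frozenset({f"{axis_name}_left"}),
        right_library_ids=frozenset({f"{axis_name}_right"}),
    )
    return RepertoireMatrix(axis=axis, data=data)
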