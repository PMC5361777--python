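"""Protease-inhibitor family models, motif scanning and family assignment.

Ixodid ticks express protease inhibitors (PIs) from 18 MEROPS inhibitor
families.  Each family here is a :class:`FamilyModel`: a set of diagnostic
motifs (a lightweight, fully overridable stand-in for a conserved-domain
search), a catalytic type (which protease class the family inhibits), and
optionally annotated reference members.

Assignment follows a two-rule procedure: a record is assigned to the unique
family whose diagnostic motifs it carries; failing that, to a family one of
whose annotated reference members it matches at strictly more than 95%
global identity (shorter-sequence denominator).  Records that neither rule
can verify are left UNASSIGNED and excluded downstream.

The shipped default motifs are heuristic consensus 10-mers, not curated
domain definitions; real analyses should supply their own family config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .align import AlignParams, GLOBAL, align, percent_identity
from .records import CANONICAL_AA, ProteinRecord, round_half_up

UNASSIGNED = "UNASSIGNED"

#: The 18 MEROPS inhibitor families found in ixodid ticks.
FAMILY_IDS = (
    "I1", "I2", "I4", "I8", "I21", "I25", "I29", "I31", "I32",
    "I35", "I39", "I43", "I51", "I53", "I63", "I68", "I72", "I74",
)

#: Fixed family -> protease catalytic type mapping.
CATALYTIC_TYPE = {
    **{f: "serine" for f in ("I1", "I2", "I4", "I8", "I21", "I51", "I53", "I72", "I74")},
    **{f: "cysteine" for f in ("I25", "I29", "I31", "I32")},
    **{f: "metallo" for f in ("I35", "I43", "I63", "I68")},
    "I39": "nonspecific",
}

CATALYTIC_TYPES = ("serine", "cysteine", "metallo", "nonspecific")

FAMILY_NAMES = {
    "I1": "Kazal",
    "I2": "Kunitz",
    "I4": "serpin",
    "I8": "TIL-domain elastase inhibitor",
    "I21": "secretogranin V",
    "I25": "cystatin",
    "I29": "CTLA/peptidase propeptide",
    "I31": "thyropin",
    "I32": "survivin/IAP",
    "I35": "TIMP",
    "I39": "alpha-2-macroglobulin",
    "I43": "oprin",
    "I51": "PEBP/serine carboxypeptidase inhibitor",
    "I53": "madanin",
    "I63": "pro-eosinophil major basic protein",
    "I68": "tick carboxypeptidase inhibitor",
    "I72": "chimadanin",
    "I74": "variegin",
}

_LITERAL_RE = re.compile(f"^[{CANONICAL_AA}]+$")


def family_sort_key(family_id: str) -> int:
    return int(family_id.lstrip("I"))


@dataclass(frozen=True)
class Motif:
    """One diagnostic pattern.

    Literal residue strings are matched as sliding windows allowing up to
    ``max_mismatches`` substitutions; anything containing regex metacharacters
    is matched with :mod:`re` (exact, ``max_mismatches`` must be 0).
    """

    pattern: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        if self.max_mismatches and not _LITERAL_RE.match(self.pattern):
            raise ValueError(
                "mismatch tolerance is only supported for literal motifs"
            )

    @property
    def is_literal(self) -> bool:
        return bool(_LITERAL_RE.match(self.pattern))

    def matches(self, seq: str) -> bool:
        if self.is_literal:
            k, n = len(self.pattern), len(seq)
            budget = self.max_mismatches
            for start in range(n - k + 1):
                mism = 0
                for p_ch, s_ch in zip(self.pattern, seq[start : start + k]):
                    if p_ch != s_ch:
                        mism += 1
                        if mism > budget:
                            break
                else:
                    return True
            return False
        return re.search(self.pattern, seq) is not None


@dataclass
class FamilyModel:
    """One MEROPS-style inhibitor family."""

    family_id: str
    family_name: str = ""
    motifs: Sequence[Motif] = field(default_factory=tuple)
    min_motif_hits: int = 1
    reference_members: Sequence[ProteinRecord] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.family_id not in FAMILY_IDS:
            raise ValueError(
                f"unknown family {self.family_id!r}; accepted: {FAMILY_IDS}"
            )
        if not self.family_name:
            self.family_name = FAMILY_NAMES[self.family_id]
        self.motifs = tuple(self.motifs)
        if self.min_motif_hits < 1:
            raise ValueError("min_motif_hits must be >= 1")

    @property
    def catalytic_type(self) -> str:
        return CATALYTIC_TYPE[self.family_id]


@dataclass(frozen=True)
class FamilyAssignment:
    """Outcome of assigning one record to a family."""

    record_id: str
    family_id: str  # a family id or UNASSIGNED
    method: Optional[str] = None  # motif | identity | hint
    evidence: Optional[str] = None
    ambiguous: bool = False


def scan_motifs(seq: str, model: FamilyModel) -> int:
    """Number of the model's distinct motifs with at least one match in *seq*
    (overlapping matches of one motif count once)."""
    if not model.motifs:
        raise ValueError(
            f"family {model.family_id} has no motifs; identity-only family"
        )
    return sum(1 for motif in model.motifs if motif.matches(seq))


def assign_family(
    rec: ProteinRecord,
    models: Sequence[FamilyModel],
    *,
    annotation_identity: float = 95.0,
    params: AlignParams | None = None,
    use_hints: bool = False,
) -> FamilyAssignment:
    """Assign *rec* to a family by motif, then by reference identity.

    Rule 1 (motif): the model whose motif hit count reaches its
    ``min_motif_hits``; with several qualifying models the one with the most
    hits wins, and a tie yields UNASSIGNED with the ambiguity flag (a record
    whose family cannot be verified uniquely is eliminated rather than
    guessed).

    Rule 2 (identity): best global identity (shorter denominator) to any
    annotated reference member, accepted iff strictly greater than
    ``annotation_identity``.

    Rule 3 (hint, optional): trust ``rec.annotation_hint`` when it names a
    known family and nothing better decided.
    """
    if params is None:
        params = GLOBAL
    hits = {}
    for model in models:
        if not model.motifs:
            continue
        count = scan_motifs(rec.sequence, model)
        if count >= model.min_motif_hits:
            hits[model.family_id] = count
    if hits:
        best = max(hits.values())
        winners = sorted(
            (f for f, c in hits.items() if c == best), key=family_sort_key
        )
        if len(winners) == 1:
            return FamilyAssignment(
                rec.record_id,
                winners[0],
                method="motif",
                evidence=f"{best} motif hit(s)",
            )
        return FamilyAssignment(
            rec.record_id,
            UNASSIGNED,
            evidence=f"ambiguous motif hits: {','.join(winners)}",
            ambiguous=True,
        )

    best_identity = -1.0
    best_family = None
    best_ref = None
    for model in models:
        for ref in model.reference_members:
            ident = percent_identity(
                align(rec.sequence, ref.sequence, params), "shorter"
            )
            if ident > best_identity:
                best_identity, best_family, best_ref = ident, model.family_id, ref
    if best_family is not None and best_identity > annotation_identity:
        return FamilyAssignment(
            rec.record_id,
            best_family,
            method="identity",
            evidence=f"{best_identity:.1f}% to {best_ref.record_id}",
        )

    if use_hints and rec.annotation_hint in FAMILY_IDS:
        return FamilyAssignment(
            rec.record_id,
            rec.annotation_hint,
            method="hint",
            evidence="annotation hint",
        )
    return FamilyAssignment(rec.record_id, UNASSIGNED)


def catalytic_rollup(counts: Mapping[str, int]) -> pd.DataFrame:
    """Roll non-redundant per-family counts up to protease catalytic types.

    Returns a DataFrame indexed by catalytic type (plus a ``total`` row) with
    ``count`` and ``percent`` (one decimal, half-up) columns.
    """
    unknown = sorted(set(counts) - set(FAMILY_IDS))
    if unknown:
        raise ValueError(f"unknown families in counts: {unknown}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all-zero family counts")
    rows = {}
    for ctype in CATALYTIC_TYPES:
        csum = sum(
            v for f, v in counts.items() if CATALYTIC_TYPE[f] == ctype
        )
        rows[ctype] = {
            "count": csum,
            "percent": round_half_up(100.0 * csum / total, 1),
        }
    rows["total"] = {"count": total, "percent": 100.0}
    return pd.DataFrame.from_dict(rows, orient="index")


def default_models() -> list[FamilyModel]:
    """Heuristic default family models: two literal consensus motifs per
    family, scanned with a 2-mismatch tolerance, any one sufficing."""
    return [
        FamilyModel(
            family_id=fid,
            motifs=tuple(Motif(p, max_mismatches=2) for p in patterns),
            min_motif_hits=1,
        )
        for fid, patterns in DEFAULT_MOTIFS.items()
    ]


#: Heuristic diagnostic 10-mers per family (cysteine-spacing flavoured
#: consensus peptides; explicitly NOT curated domain definitions).
DEFAULT_MOTIFS: dict[str, tuple[str, str]] = {
    "I1": ("CPRIYNPVCG", "TYSNECLLCA"),
    "I2": ("GPCRAAIPRW", "YGGCEGNANN"),
    "I4": ("DVNEEGTEAA", "FKGKWKTPFD"),
    "I8": ("CPANEVWKEC", "GCEGDNAETC"),
    "I21": ("GERDPHWLQQ", "YSPRTPDRVS"),
    "I25": ("QVVAGTNYFI", "LGRTTCPKSS"),
    "I29": ("ERWNAQYGVT", "NKFADLTPEE"),
    "I31": ("CQLPKEVGPC", "YNPHTGQCEM"),
    "I32": ("GCAFLSVKKQ", "EEAGFVHCPT"),
    "I35": ("CTCVPPHPQT", "FIYTAPSSAV"),
    "I39": ("GCGEQNMIGM", "VAYKHQSPLS"),
    "I43": ("HDCDFEENQC", "PKTVRGAECG"),
    "I51": ("HRYVWLVYEQ", "GGNDISSGTV"),
    "I53": ("EPGHHDHDKS", "APQFPELAGE"),
    "I63": ("CRGDTFKDHD", "SYGLPWEARQ"),
    "I68": ("QHADPICNKP", "CDSGWEKDNE"),
    "I72": ("NDTGAFDGLP", "TEEPQHNATG"),
    "I74": ("SDQGDVAEPK", "HTSKGPIRLQ"),
}


def load_family_models(path: str | Path) -> list[FamilyModel]:
    """Load family models from a YAML config.

    Schema::

        families:
          - family_id: I2
            motifs: ["GPCRAAIPRW", {pattern: "C..GC", max_mismatches: 0}]
            min_motif_hits: 1
            reference_fasta: path/to/refs.fasta   # optional, ids become
                                                  # reference members
            reference_species: merops             # species code for refs
    """
    from .io import read_fasta  # local import to avoid a cycle

    path = Path(path)
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    models = []
    for entry in cfg["families"]:
        motifs = []
        for m in entry.get("motifs", []):
            if isinstance(m, str):
                motifs.append(Motif(m, max_mismatches=2 if _LITERAL_RE.match(m) else 0))
            else:
                motifs.append(
                    Motif(m["pattern"], max_mismatches=int(m.get("max_mismatches", 0)))
                )
        refs = []
        if entry.get("reference_fasta"):
            ref_path = path.parent / entry["reference_fasta"]
            sp = entry.get("reference_species", "ref")
            refs = [
                ProteinRecord(record_id=rid, species_code=sp, sequence=seq)
                for rid, seq in read_fasta(ref_path)
            ]
        models.append(
            FamilyModel(
                family_id=entry["family_id"],
                family_name=entry.get("family_name", ""),
                motifs=tuple(motifs),
                min_motif_hits=int(entry.get("min_motif_hits", 1)),
                reference_members=tuple(refs),
            )
        )
    return models


def assignments_table(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": a.record_id,
                "family": a.family_id,
                "method": a.method or "",
                "evidence": a.evidence or "",
                "ambiguous": a.ambiguous,
            }
            for a in assignments
        ]
    )
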