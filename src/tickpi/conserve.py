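"""Cross-species homolog screening within inhibitor families.

The focal species' non-redundant inhibitors are screened against same-family
sequences of other tick species; for each (query, subject species) pair the
single best local-alignment hit by score is kept, and retained iff its
percent identity over alignment columns is at least the threshold (default
50%, inclusive).  Identity over columns approximates what a translated
database search reports.

Because family members share short diagnostic motifs even when otherwise
unrelated, a local alignment covering just a motif window can reach 100%
identity over a handful of columns.  A minimum query-coverage filter
(default: the alignment must span half the query) plays the role that
length-dependent significance statistics play in a database search and keeps
such spurious micro-alignments out of the hit list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import AlignParams, LOCAL, align, percent_identity
from .records import ProteinRecord
from .translate import longest_orf_protein

#: Conservation bands used when summarising per-query best identities.
BANDS = ((80.0, ">=80"), (65.0, "65-80"), (50.0, "50-65"))


@dataclass(frozen=True)
class ConservationHit:
    """Best same-family hit of a focal query in one other species."""

    query_id: str
    subject_id: str
    subject_species: str
    family_id: str
    identity_percent: float
    aligned_columns: int
    score: int


def screen_conservation(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    family_id: str,
    *,
    min_identity: float = 50.0,
    min_query_coverage: float = 0.5,
    params: AlignParams | None = None,
    translate_queries: bool = False,
) -> list[ConservationHit]:
    """Best-hit cross-species screen within one family.

    *queries* are the focal species' cluster representatives (nucleotide
    contigs if ``translate_queries``, in which case the longest stop-free
    translated stretch is used); *subjects* are same-family proteins of other
    species.  Candidate alignments must span at least
    ``min_query_coverage * len(query)`` columns (0 disables the filter).
    Hits are sorted by descending identity, then ids.
    """
    if params is None:
        params = LOCAL
    hits: list[ConservationHit] = []
    focal_species = {q.species_code for q in queries}
    for query in queries:
        qseq = (
            longest_orf_protein(query.sequence)
            if translate_queries
            else query.sequence
        )
        if not qseq:
            continue
        min_columns = min_query_coverage * len(qseq)
        best_by_species: dict[str, tuple] = {}
        for subj in sorted(subjects, key=lambda s: s.record_id):
            if subj.species_code in focal_species:
                continue
            result = align(qseq, subj.sequence, params)
            if result.aligned_columns == 0 or result.aligned_columns < min_columns:
                continue
            ident = percent_identity(result, "columns")
            key = subj.species_code
            cand = (result.score, ident, subj, result)
            if key not in best_by_species or (
                cand[0], cand[1]
            ) > (best_by_species[key][0], best_by_species[key][1]):
                best_by_species[key] = cand
        for species in sorted(best_by_species):
            score, ident, subj, result = best_by_species[species]
            if ident >= min_identity:
                hits.append(
                    ConservationHit(
                        query_id=query.record_id,
                        subject_id=subj.record_id,
                        subject_species=species,
                        family_id=family_id,
                        identity_percent=ident,
                        aligned_columns=result.aligned_columns,
                        score=score,
                    )
                )
    hits.sort(key=lambda h: (-h.identity_percent, h.query_id, h.subject_id))
    return hits


def band_of(identity: float) -> Optional[str]:
    for floor, label in BANDS:
        if identity >= floor:
            return label
    return None


def conservation_summary(
    hits: Sequence[ConservationHit], queries: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Per-query conservation summary.

    Columns: best identity per subject species (semicolon-joined
    ``species:identity`` pairs), number of species with a retained hit, and
    the identity band of the best hit (>=80, 65-80 or 50-65).
    """
    by_query: dict[str, dict[str, float]] = {}
    for h in hits:
        best = by_query.setdefault(h.query_id, {})
        if h.identity_percent > best.get(h.subject_species, -1.0):
            best[h.subject_species] = h.identity_percent
    rows = []
    for q in queries:
        best = by_query.get(q.record_id, {})
        best_ident = max(best.values()) if best else None
        rows.append(
            {
                "query_id": q.record_id,
                "species_hits": ";".join(
                    f"{sp}:{best[sp]:.1f}" for sp in sorted(best)
                ),
                "n_species": len(best),
                "band": band_of(best_ident) if best_ident is not None else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["query_id", "species_hits", "n_species", "band"]
    )


def hits_table(hits: Sequence[ConservationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "subject_species": h.subject_species,
                "family": h.family_id,
                "identity_percent": h.identity_percent,
                "aligned_columns": h.aligned_columns,
                "score": h.score,
            }
            for h in hits
        ],
        columns=[
            "query_id", "subject_id", "subject_species", "family",
            "identity_percent", "aligned_columns", "score",
        ],
    )
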