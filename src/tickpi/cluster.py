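"""Greedy 95%-identity redundancy collapse and non-redundant counting.

Within one species and one inhibitor family, sequences sharing at least 95%
identity are treated as redundant variants of the same inhibitor, and only
one representative is retained.  Clustering is greedy longest-first (the
CD-HIT convention): records are visited in order of decreasing length (ties
by ascending id), each joining the first existing cluster whose
representative it matches at or above the threshold — global alignment,
shorter-sequence denominator, so a fragment collapses onto its full-length
transcript — otherwise seeding a new cluster.  The seed (longest member) is
the cluster's representative.

When planted (or real) data are well separated — intra-cluster identity above
the threshold, inter-cluster identity below it — this greedy result coincides
with single-linkage clustering regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignParams, GLOBAL, align, percent_identity
from .families import FAMILY_IDS, family_sort_key
from .records import ProteinRecord


@dataclass
class RedundancyCluster:
    """A set of >= threshold-identical same-species, same-family records."""

    family_id: str
    species_code: str
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    member_identities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def dedup(
    records: Sequence[ProteinRecord],
    family_id: str,
    *,
    threshold: float = 95.0,
    params: AlignParams | None = None,
) -> list[RedundancyCluster]:
    """Collapse same-species, same-family records at >= *threshold* identity.

    All records must share one species (the family is supplied by the caller,
    since family membership is an assignment output, not a record field).
    """
    if params is None:
        params = GLOBAL
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if not records:
        return []
    species = {r.species_code for r in records}
    if len(species) > 1:
        raise ValueError(
            f"dedup input mixes species {sorted(species)}; cluster per species"
        )
    species_code = species.pop()

    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.record_id))
    clusters: list[RedundancyCluster] = []
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            ident = percent_identity(
                align(rec.sequence, rep.sequence, params), "shorter"
            )
            if ident >= threshold:
                cluster.member_ids.append(rec.record_id)
                cluster.member_identities[rec.record_id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                RedundancyCluster(
                    family_id=family_id,
                    species_code=species_code,
                    representative_id=rec.record_id,
                    member_ids=[rec.record_id],
                    member_identities={rec.record_id: 100.0},
                )
            )
            reps.append(rec)
    return clusters


def nonredundant_counts(
    clusters: Iterable[RedundancyCluster],
    *,
    families: Sequence[str] = FAMILY_IDS,
) -> pd.DataFrame:
    """Per species x family count of non-redundant clusters.

    Returns a DataFrame indexed by species (plus a ``total`` row) with one
    column per family (ordered numerically) and a ``total`` column.
    """
    clusters = list(clusters)
    fams = sorted(set(families), key=family_sort_key)
    species = sorted({c.species_code for c in clusters})
    table = pd.DataFrame(0, index=species, columns=fams, dtype=int)
    for c in clusters:
        if c.family_id not in table.columns:
            raise ValueError(f"cluster family {c.family_id} not in family set")
        table.loc[c.species_code, c.family_id] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def clusters_table(clusters: Sequence[RedundancyCluster]) -> pd.DataFrame:
    rows = []
    for k, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": f"{c.species_code}.{c.family_id}.{k}",
                "family": c.family_id,
                "species": c.species_code,
                "representative": c.representative_id,
                "members": ",".join(c.member_ids),
                "identities": ",".join(
                    f"{c.member_identities[m]:.1f}" for m in c.member_ids
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "family", "species", "representative",
            "members", "identities",
        ],
    )
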