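"""Redundancy collapse: greedy clustering vs single-linkage oracle."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from tickpi import (
    ProteinRecord,
    dedup,
    identity_between,
    mutate_to_identity,
    nonredundant_counts,
)
from tickpi.cluster import RedundancyCluster

from conftest import random_protein


def _planted_records(rng, n_clusters=6, size=3, length=150, intra=98.0):
    """Well-separated planted clusters: unrelated ancestors, members mutated
    within a shared small window so intra-pairwise identity stays high."""
    records, truth = [], []
    k = 0
    window_size = round(length * (100 - intra) / 100)
    for c in range(n_clusters):
        ancestor = random_protein(rng, length)
        window = rng.choice(length, window_size, replace=False).tolist()
        members = []
        for m in range(size):
            seq = (
                ancestor
                if m == 0
                else mutate_to_identity(
                    ancestor, float(rng.uniform(intra, 100.0)), rng,
                    allowed=window,
                )
            )
            rid = f"r{k:03d}"
            records.append(ProteinRecord(rid, "aam", seq))
            members.append(rid)
            k += 1
        truth.append(frozenset(members))
    return records, set(truth)


def _single_linkage_oracle(records, threshold):
    """Independent oracle: connected components of the >=threshold identity
    graph (single linkage)."""
    g = nx.Graph()
    g.add_nodes_from(r.record_id for r in records)
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            if identity_between(a.sequence, b.sequence) >= threshold:
                g.add_edge(a.record_id, b.record_id)
    return {frozenset(c) for c in nx.connected_components(g)}


def _partition(clusters):
    return {frozenset(c.member_ids) for c in clusters}


# -------------------------------------------------------------- basics ----


def test_identical_pair_plus_unrelated_gives_two_clusters(rng):
    seq = random_protein(rng, 80)
    other = random_protein(rng, 80)
    records = [
        ProteinRecord("a", "aam", seq),
        ProteinRecord("b", "aam", seq),
        ProteinRecord("c", "aam", other),
    ]
    clusters = dedup(records, "I2")
    assert len(clusters) == 2
    assert _partition(clusters) == {frozenset({"a", "b"}), frozenset({"c"})}


def test_empty_input_gives_empty_list():
    assert dedup([], "I2") == []


def test_mixed_species_rejected(rng):
    records = [
        ProteinRecord("a", "aam", random_protein(rng, 50)),
        ProteinRecord("b", "isca", random_protein(rng, 50)),
    ]
    with pytest.raises(ValueError, match="species"):
        dedup(records, "I2")


def test_fragment_collapses_onto_full_length(rng):
    """The shorter-denominator convention merges a fragment with its
    transcript, and the longest member is the representative."""
    full = random_protein(rng, 120)
    records = [
        ProteinRecord("frag", "aam", full[:60]),
        ProteinRecord("full", "aam", full),
    ]
    (cluster,) = dedup(records, "I4")
    assert cluster.representative_id == "full"
    assert cluster.member_identities["frag"] == 100.0


# ----------------------------------------------------- oracle agreement ----


def test_planted_clusters_match_single_linkage_oracle(rng):
    records, truth = _planted_records(rng)
    clusters = dedup(records, "I2")
    assert _partition(clusters) == truth
    assert _partition(clusters) == _single_linkage_oracle(records, 95.0)


def test_order_robustness_under_separation(rng):
    """With intra identity above and inter identity below the threshold, the
    greedy result equals single linkage for any input permutation."""
    records, truth = _planted_records(rng, n_clusters=5, size=3)
    oracle = _single_linkage_oracle(records, 95.0)
    assert oracle == truth
    shuffled = list(records)
    for _ in range(50):
        rng.shuffle(shuffled)
        assert _partition(dedup(shuffled, "I2")) == oracle


# ------------------------------------------------------------ properties ----


def test_every_record_in_exactly_one_cluster(scenario):
    focal = [r for r in scenario.records if r.species_code == "aam"]
    by_family = {}
    for r in focal:
        by_family.setdefault(scenario.truth.family_of[r.record_id], []).append(r)
    for fam, records in by_family.items():
        clusters = dedup(records, fam)
        member_ids = [m for c in clusters for m in c.member_ids]
        assert sorted(member_ids) == sorted(r.record_id for r in records)


def test_cluster_count_monotone_in_threshold(rng):
    records, _ = _planted_records(rng, n_clusters=4, size=4)
    counts = [
        len(dedup(records, "I2", threshold=t))
        for t in (50, 70, 80, 90, 95, 99, 100)
    ]
    assert counts == sorted(counts)


def test_member_identities_meet_threshold(rng):
    records, _ = _planted_records(rng)
    for cluster in dedup(records, "I2", threshold=95.0):
        for member, ident in cluster.member_identities.items():
            assert ident >= 95.0
        assert cluster.member_identities[cluster.representative_id] == 100.0


# ---------------------------------------------------------------- counts ----


def test_nonredundant_counts_table():
    def mk(fam, sp, n):
        return [
            RedundancyCluster(fam, sp, f"{sp}{fam}{i}", [f"{sp}{fam}{i}"],
                              {f"{sp}{fam}{i}": 100.0})
            for i in range(n)
        ]

    clusters = mk("I1", "aam", 6) + mk("I25", "aam", 3) + mk("I1", "isca", 2)
    table = nonredundant_counts(clusters)
    assert table.loc["aam", "I1"] == 6
    assert table.loc["aam", "total"] == 9
    assert table.loc["total", "total"] == 11


def test_nonredundant_counts_empty():
    table = nonredundant_counts([])
    assert table.loc["total", "total"] == 0
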