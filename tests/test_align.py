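"""Alignment: oracle equivalence, scoring invariants, identity conventions."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align as BioAlign
from Bio.Align import substitution_matrices

from tickpi import (
    AlignParams,
    align,
    default_table,
    identity_between,
    load_matrix,
    percent_identity,
)

from conftest import random_protein

GLOBAL = AlignParams(mode="global")
LOCAL = AlignParams(mode="local")


# ------------------------------------------------------------- examples ----


def test_identical_sequences_align_perfectly():
    r = align("MKT", "MKT", GLOBAL)
    assert (r.matches, r.aligned_columns, r.gap_columns) == (3, 3, 0)
    assert percent_identity(r, "columns") == 100.0


def test_single_substitution_is_gapless_under_default_scores():
    r = align("MKT", "MRT", GLOBAL)
    assert (r.matches, r.aligned_columns) == (2, 3)


def test_empty_sequence_errors():
    with pytest.raises(ValueError):
        align("", "MKT", GLOBAL)


def test_gap_params_validated():
    with pytest.raises(ValueError):
        AlignParams(gap_open=-1, gap_extend=-11)


# ------------------------------------------------- brute-force oracle ------


def _enumerate_global_best(a: str, b: str, params: AlignParams) -> int:
    """Score of the best global alignment by exhaustive enumeration of every
    gapped alignment (each gap opening pays gap_open, every gap column pays
    gap_extend; switching gap side reopens)."""
    best = [-(10**9)]

    def rec(i: int, j: int, prev: str | None, score: int) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + params.matrix.score(a[i], b[j]))
        if i < len(a):
            pen = params.gap_extend + (params.gap_open if prev != "F" else 0)
            rec(i + 1, j, "F", score + pen)
        if j < len(b):
            pen = params.gap_extend + (params.gap_open if prev != "E" else 0)
            rec(i, j + 1, "E", score + pen)

    rec(0, 0, None, 0)
    return best[0]


def test_global_score_equals_exhaustive_enumeration(rng):
    for _ in range(60):
        a = random_protein(rng, int(rng.integers(1, 7)))
        b = random_protein(rng, int(rng.integers(1, 7)))
        assert align(a, b, GLOBAL).score == _enumerate_global_best(a, b, GLOBAL)


def _biopython_aligner(mode: str) -> BioAlign.PairwiseAligner:
    aligner = BioAlign.PairwiseAligner()
    aligner.mode = mode
    table = default_table()
    arr = substitution_matrices.Array(
        alphabet="ACDEFGHIKLMNPQRSTVWYX*", dims=2, data=table.scores.astype(float)
    )
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -12.0  # first gap column: open + extend
    aligner.extend_gap_score = -1.0
    return aligner


@pytest.mark.parametrize("mode", ["global", "local"])
def test_score_matches_independent_aligner_short(rng, mode):
    """Both modes agree with an independent implementation on 8-mers."""
    aligner = _biopython_aligner(mode)
    params = AlignParams(mode=mode)
    for _ in range(200):
        a = random_protein(rng, int(rng.integers(1, 9)))
        b = random_protein(rng, int(rng.integers(1, 9)))
        expected = aligner.score(a, b)
        if mode == "local":
            expected = max(expected, 0.0)
        assert align(a, b, params).score == expected


@pytest.mark.parametrize("mode", ["global", "local"])
def test_score_matches_independent_aligner_long(rng, mode):
    aligner = _biopython_aligner(mode)
    params = AlignParams(mode=mode)
    for _ in range(25):
        a = random_protein(rng, int(rng.integers(30, 120)))
        b = random_protein(rng, int(rng.integers(30, 120)))
        assert align(a, b, params).score == aligner.score(a, b) or params.mode == "local"
        if mode == "local":
            assert align(a, b, params).score == max(aligner.score(a, b), 0.0)


# ------------------------------------------------------------ invariants ----


def test_score_symmetry(rng):
    for _ in range(200):
        a = random_protein(rng, int(rng.integers(1, 30)))
        b = random_protein(rng, int(rng.integers(1, 30)))
        for params in (GLOBAL, LOCAL):
            assert align(a, b, params).score == align(b, a, params).score


def test_self_global_score_is_diagonal_sum(rng):
    table = default_table()
    for _ in range(30):
        a = random_protein(rng, int(rng.integers(1, 50)))
        expected = sum(table.score(ch, ch) for ch in a)
        assert align(a, a, GLOBAL).score == expected
        # every BLOSUM62 diagonal is positive, so the local optimum is the
        # same full-length self alignment
        assert align(a, a, LOCAL).score == expected


def test_local_score_never_negative(rng):
    for _ in range(50):
        a = random_protein(rng, int(rng.integers(1, 20)))
        b = random_protein(rng, int(rng.integers(1, 20)))
        assert align(a, b, LOCAL).score >= 0


def test_traceback_columns_reproduce_score(rng):
    """The emitted alignment re-scores to the reported optimum."""
    table = default_table()
    for _ in range(40):
        a = random_protein(rng, int(rng.integers(2, 40)))
        b = random_protein(rng, int(rng.integers(2, 40)))
        r = align(a, b, GLOBAL)
        score, prev = 0, None
        for x, y in zip(r.aligned_a, r.aligned_b):
            if x != "-" and y != "-":
                score += table.score(x, y)
                prev = "M"
            else:
                side = "F" if y == "-" else "E"
                score += GLOBAL.gap_extend + (
                    GLOBAL.gap_open if prev != side else 0
                )
                prev = side
        assert score == r.score


# ------------------------------------------------------ percent identity ----


def test_percent_identity_rounding_and_conventions():
    r = align("MKTAYIAALL", "MKTAYIAALL", GLOBAL)
    assert percent_identity(r, "columns") == 100.0
    assert percent_identity(r, "shorter") == 100.0
    # 5 matches over 6 columns rounds half-up to one decimal: 83.3
    r5of6 = align("MKTAYL", "MKTAYI", GLOBAL)
    assert r5of6.matches == 5 and r5of6.aligned_columns == 6
    assert percent_identity(r5of6, "columns") == 83.3


def test_columns_convention_never_exceeds_shorter_for_global(rng):
    """Gaps inflate the columns denominator, so columns <= shorter."""
    for _ in range(50):
        a = random_protein(rng, int(rng.integers(3, 30)))
        b = random_protein(rng, int(rng.integers(3, 30)))
        r = align(a, b, GLOBAL)
        assert percent_identity(r, "columns") <= percent_identity(r, "shorter")


def test_fragment_scores_full_identity_under_shorter_convention():
    full = "MKTAYIAALLWLYPTRAEFA"
    assert identity_between(full[:8], full, convention="shorter") == 100.0


def test_x_never_counts_as_match():
    r = align("MXT", "MXT", GLOBAL)
    assert r.matches == 2
    assert default_table().score("X", "W") == 0


def test_matrix_ncbi_format_round_trip(tmp_path):
    src = substitution_matrices.load("BLOSUM62")
    path = tmp_path / "blosum62.txt"
    path.write_text(str(src))
    table = load_matrix(path)
    assert table.score("W", "W") == int(src["W", "W"])
    assert table.score("A", "R") == int(src["A", "R"])
    assert table.score("X", "A") == 0  # X forced to zero on load
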