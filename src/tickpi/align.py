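"""Pairwise protein alignment with affine gap penalties.

This module is the in-house replacement for the similarity searches that a
repertoire study would normally delegate to BLAST or a commercial workbench:
optimal global (Needleman-Wunsch) and local (Smith-Waterman) alignment under
an affine gap model (Gotoh's algorithm), with percent identity computed under
two explicit denominator conventions.

Conventions
-----------
* A gap of length ``L`` costs ``gap_open + L * gap_extend`` (so with the
  defaults -11/-1 a length-1 gap costs -12, the BLASTP "existence 11,
  extension 1" convention).
* ``X`` (unknown residue) scores 0 against everything and never counts as a
  match, so unknown residues cannot inflate identity.
* Traceback is deterministic: ties resolve diagonal, then up (gap in the
  subject), then left (gap in the query); a gap closes rather than extends on
  a tie; the local alignment ends at the first maximal cell in row-major
  order.
* Percent identity: ``columns`` divides matches by all alignment columns
  (gaps included), the convention of translated-search identity reports;
  ``shorter`` divides by the shorter sequence length, the convention used for
  redundancy removal so that a fragment collapses onto its full-length
  transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .records import CANONICAL_AA, round_half_up

MATRIX_ALPHABET = CANONICAL_AA + "X*"
_NEG = np.int64(-(2**40))


class SubstitutionTable:
    """A symmetric residue substitution score table over the 22-letter
    alphabet (20 canonical residues, X, *)."""

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores, dtype=np.int64)
        n = len(MATRIX_ALPHABET)
        if scores.shape != (n, n):
            raise ValueError(f"substitution table must be {n}x{n}")
        if not np.array_equal(scores, scores.T):
            raise ValueError("substitution table must be symmetric")
        self.scores = scores
        self.name = name
        self._index = {ch: i for i, ch in enumerate(MATRIX_ALPHABET)}

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._index[a], self._index[b]])

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter(
                (self._index[ch] for ch in seq), dtype=np.intp, count=len(seq)
            )
        except KeyError as exc:
            raise ValueError(f"residue {exc} not in alignment alphabet") from None

    @classmethod
    def from_biopython(cls, arr, name: str = "custom") -> "SubstitutionTable":
        """Build from a ``Bio.Align.substitution_matrices.Array``; X (and any
        residue the source matrix lacks) is forced to score 0 everywhere."""
        src_alpha = str(arr.alphabet)
        n = len(MATRIX_ALPHABET)
        scores = np.zeros((n, n), dtype=np.int64)
        for i, a in enumerate(MATRIX_ALPHABET):
            for j, b in enumerate(MATRIX_ALPHABET):
                if a == "X" or b == "X":
                    continue
                if a in src_alpha and b in src_alpha:
                    scores[i, j] = int(arr[a, b])
        return cls(scores, name=name)


_DEFAULT_TABLE: SubstitutionTable | None = None


def default_table() -> SubstitutionTable:
    """BLOSUM62 with the X-scores-zero convention (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = SubstitutionTable.from_biopython(
            substitution_matrices.load("BLOSUM62"), name="BLOSUM62"
        )
    return _DEFAULT_TABLE


def load_matrix(path: str | Path) -> SubstitutionTable:
    """Load a substitution matrix from NCBI matrix text format."""
    with open(path) as handle:
        arr = substitution_matrices.read(handle)
    return SubstitutionTable.from_biopython(arr, name=Path(path).stem)


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring parameters (defaults mirror BLASTP)."""

    matrix: SubstitutionTable = field(default_factory=default_table)
    gap_open: int = -11
    gap_extend: int = -1
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"mode must be global or local, got {self.mode!r}")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")


GLOBAL = AlignParams(mode="global")
LOCAL = AlignParams(mode="local")


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal pairwise alignment and its column statistics."""

    mode: str
    score: int
    aligned_a: str
    aligned_b: str
    aligned_columns: int
    matches: int
    gap_columns: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_len: int
    subject_len: int


def percent_identity(result: AlignmentResult, convention: str = "columns") -> float:
    """Percent identity of an alignment, one decimal, ties rounded up.

    ``columns``: 100 * matches / aligned_columns.
    ``shorter``: 100 * matches / min(query length, subject length).
    """
    if convention == "columns":
        if result.aligned_columns < 1:
            raise ValueError("alignment has zero columns")
        denom = result.aligned_columns
    elif convention == "shorter":
        denom = min(result.query_len, result.subject_len)
    else:
        raise ValueError(f"unknown identity convention {convention!r}")
    return round_half_up(100.0 * result.matches / denom, 1)


def _fill(a_idx, b_idx, params):
    """Gotoh forward pass; returns the H, E, F score matrices.

    E holds alignments ending in a gap in the query (left move), F in a gap
    in the subject (up move).  The same-row E recurrence is solved per row
    with a prefix-maximum: opening a gap out of a cell whose own best path
    ends in a left-gap is never strictly better than extending that gap
    (gap_open <= 0), so E can be computed from the non-E cell candidates.
    """
    m, n = len(a_idx), len(b_idx)
    open_, ext = np.int64(params.gap_open), np.int64(params.gap_extend)
    local = params.mode == "local"
    scores = params.matrix.scores

    H = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)

    js = np.arange(n + 1, dtype=np.int64)
    H[0, 0] = 0
    if local:
        H[0, :] = 0
        H[:, 0] = 0
    else:
        E[0, 1:] = open_ + ext * js[1:]
        H[0, 1:] = E[0, 1:]
        F[1:, 0] = open_ + ext * np.arange(1, m + 1, dtype=np.int64)
        H[1:, 0] = F[1:, 0]

    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(H[i - 1, 1:] + open_ + ext, F[i - 1, 1:] + ext)
        diag = H[i - 1, :-1] + scores[a_idx[i - 1], b_idx]
        cand = np.maximum(diag, F[i, 1:])
        if local:
            cand = np.maximum(cand, 0)
        # base[k]: best same-row cell value at column k not ending in a left-gap
        base = np.concatenate(([H[i, 0]], cand))
        prefmax = np.maximum.accumulate(base - ext * js)
        E[i, 1:] = open_ + ext * js[1:] + prefmax[:-1]
        H[i, 1:] = np.maximum(cand, E[i, 1:])
    return H, E, F


def _traceback(a, b, a_idx, b_idx, H, E, F, params, end_i, end_j):
    open_, ext = params.gap_open, params.gap_extend
    local = params.mode == "local"
    scores = params.matrix.scores
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = end_i, end_j
    state = "H"
    while True:
        if state == "H":
            if i == 0 and j == 0:
                break
            if local and H[i, j] == 0:
                break
            if (
                i > 0
                and j > 0
                and H[i, j] == H[i - 1, j - 1] + scores[a_idx[i - 1], b_idx[j - 1]]
            ):
                cols_a.append(a[i - 1])
                cols_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - would indicate a fill bug
                raise AssertionError("traceback dead end")
        elif state == "F":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            if F[i, j] == H[i - 1, j] + open_ + ext:
                state = "H"
            i -= 1
        else:  # state == "E"
            cols_a.append("-")
            cols_b.append(b[j - 1])
            if E[i, j] == H[i, j - 1] + open_ + ext:
                state = "H"
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    return "".join(cols_a), "".join(cols_b), i, j


def align(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal pairwise alignment of proteins *a* and *b*.

    Returns the dynamic-programming optimum for the chosen mode with affine
    gaps and a deterministic traceback.  An all-negative local comparison
    yields an empty alignment with score 0.
    """
    if params is None:
        params = GLOBAL
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    table = params.matrix
    a_idx, b_idx = table.encode(a), table.encode(b)
    H, E, F = _fill(a_idx, b_idx, params)

    if params.mode == "global":
        end_i, end_j = len(a), len(b)
        score = int(H[end_i, end_j])
    else:
        flat = int(np.argmax(H))
        end_i, end_j = divmod(flat, H.shape[1])
        score = int(H[end_i, end_j])
        if score == 0:
            return AlignmentResult(
                mode=params.mode,
                score=0,
                aligned_a="",
                aligned_b="",
                aligned_columns=0,
                matches=0,
                gap_columns=0,
                query_span=(0, 0),
                subject_span=(0, 0),
                query_len=len(a),
                subject_len=len(b),
            )

    aligned_a, aligned_b, start_i, start_j = _traceback(
        a, b, a_idx, b_idx, H, E, F, params, end_i, end_j
    )
    matches = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x not in ("X", "-")
    )
    gap_columns = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == "-" or y == "-"
    )
    return AlignmentResult(
        mode=params.mode,
        score=score,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        aligned_columns=len(aligned_a),
        matches=matches,
        gap_columns=gap_columns,
        query_span=(start_i, end_i),
        subject_span=(start_j, end_j),
        query_len=len(a),
        subject_len=len(b),
    )


def identity_between(
    a: str,
    b: str,
    *,
    mode: str = "global",
    convention: str = "shorter",
    params: AlignParams | None = None,
) -> float:
    """Convenience: align and return percent identity in one call."""
    if params is None:
        params = GLOBAL if mode == "global" else LOCAL
    return percent_identity(align(a, b, params), convention)
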