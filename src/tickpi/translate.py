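"""Six-frame translation and longest-ORF protein extraction.

Assembled transcriptome contigs are nucleotide sequences; every similarity
step downstream works on proteins.  Translated screening of nucleotide
queries is emulated by translating all six reading frames and, where a single
protein per contig is needed, taking the longest stop-free stretch across the
frames (the stretch a translated-search tool would effectively score).
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTN")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

FRAME_ORDER = ("+1", "+2", "+3", "-1", "-2", "-3")


def _translate_frame(nt: str) -> str:
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        # codons containing N translate to X (unknown residue)
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def six_frame_translate(nt: str) -> tuple[str, str, str, str, str, str]:
    """Translate *nt* in frames +1, +2, +3, -1, -2, -3 (standard code).

    Stop codons are rendered as ``*``; codons containing N translate to X;
    trailing partial codons are dropped.
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError(f"nucleotide sequence too short ({len(nt)} < 3)")
    bad = [(i, b) for i, b in enumerate(nt) if b not in NT_ALPHABET]
    if bad:
        i, b = bad[0]
        raise ValueError(f"invalid base {b!r} at position {i}")
    rc = str(Seq(nt).reverse_complement())
    return (
        _translate_frame(nt),
        _translate_frame(nt[1:]),
        _translate_frame(nt[2:]),
        _translate_frame(rc),
        _translate_frame(rc[1:]),
        _translate_frame(rc[2:]),
    )


def longest_orf_protein(nt: str) -> str:
    """Longest stop-free translated stretch across all six frames.

    Ties are broken by frame order +1, +2, +3, -1, -2, -3, then by the
    leftmost start within the frame.  Returns ``""`` when every frame is all
    stops.
    """
    best = ""
    for frame_aa in six_frame_translate(nt):
        for piece in frame_aa.split("*"):
            if len(piece) > len(best):
                best = piece
    return best
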