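"""FASTA and library-manifest readers/writers, and dataset assembly.

The pipeline's input contract is a set of per-library protein FASTA files
plus a tab-separated manifest describing each library.  A record observed in
several libraries simply appears in each of those libraries' FASTA files
under the same id; :func:`load_dataset` merges them into
:class:`~tickpi.records.ProteinRecord` objects whose ``library_ids`` record
where each sequence was seen.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .records import Library, ProteinRecord, check_unique_ids, validate_sequence

MANIFEST_COLUMNS = [
    "library_id",
    "species_code",
    "sex",
    "feeding_state",
    "tissue",
    "timepoint_h",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA file into ``(id, sequence)`` pairs in file order.

    Sequences are uppercased; the header token before the first whitespace is
    the id.  Duplicate ids and non-alphabet characters are errors; an empty
    file returns an empty list with a warning.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        validate_sequence(seq, where=f"{path}:{rec.id}")
        out.append((rec.id, seq))
    if not out:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (60-column wrapping)."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def parse_library_manifest(path: str | Path) -> list[Library]:
    """Parse the tab-separated library manifest into validated libraries.

    Expected columns: library_id, species_code, sex, feeding_state, tissue,
    timepoint_h.  ``NA`` tokens are accepted case-insensitively.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    libraries: list[Library] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        tok = {c: str(getattr(row, c)).strip() for c in MANIFEST_COLUMNS}
        for col in ("sex", "feeding_state", "timepoint_h"):
            if tok[col].upper() == "NA":
                tok[col] = "NA"
        timepoint = None
        if tok["timepoint_h"] != "NA":
            try:
                timepoint = int(tok["timepoint_h"])
            except ValueError:
                raise ValueError(
                    f"{path} row {row_no}, column timepoint_h: "
                    f"bad token {tok['timepoint_h']!r}"
                ) from None
        try:
            libraries.append(
                Library(
                    library_id=tok["library_id"],
                    species_code=tok["species_code"],
                    sex=tok["sex"],
                    feeding_state=tok["feeding_state"],
                    tissue=tok["tissue"],
                    timepoint_h=timepoint,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {row_no}: {exc}") from None
    check_unique_ids((lib.library_id for lib in libraries), what="library_id")
    return libraries


def write_library_manifest(
    libraries: Sequence[Library], path: str | Path
) -> None:
    rows = [
        {
            "library_id": lib.library_id,
            "species_code": lib.species_code,
            "sex": lib.sex,
            "feeding_state": lib.feeding_state,
            "tissue": lib.tissue,
            "timepoint_h": "NA" if lib.timepoint_h is None else lib.timepoint_h,
        }
        for lib in libraries
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_dataset(
    fasta_by_library: Mapping[str, str | Path],
    libraries: Sequence[Library],
    extra_fasta_by_species: Mapping[str, str | Path] | None = None,
) -> list[ProteinRecord]:
    """Assemble ProteinRecords from per-library FASTA files.

    Parameters
    ----------
    fasta_by_library
        Map from library_id (must appear in *libraries*) to a FASTA path.
        A record present in several libraries appears in each file under the
        same id with the same sequence.
    libraries
        Validated manifest entries.
    extra_fasta_by_species
        Optional map from species_code to FASTA paths of reference sequences
        with no library membership (e.g. sequence-database downloads for
        other species).
    """
    lib_index = {lib.library_id: lib for lib in libraries}
    unknown = sorted(set(fasta_by_library) - set(lib_index))
    if unknown:
        raise ValueError(f"FASTA given for undeclared libraries: {unknown}")

    seqs: dict[str, str] = {}
    species: dict[str, str] = {}
    memberships: dict[str, set[str]] = {}
    for lib_id in sorted(fasta_by_library):
        lib = lib_index[lib_id]
        for rid, seq in read_fasta(fasta_by_library[lib_id]):
            if rid in seqs:
                if seqs[rid] != seq:
                    raise ValueError(
                        f"record {rid!r}: conflicting sequences across libraries"
                    )
                if species[rid] != lib.species_code:
                    raise ValueError(
                        f"record {rid!r}: appears in libraries of different "
                        f"species"
                    )
            else:
                seqs[rid] = seq
                species[rid] = lib.species_code
                memberships[rid] = set()
            memberships[rid].add(lib_id)

    records = [
        ProteinRecord(
            record_id=rid,
            species_code=species[rid],
            sequence=seqs[rid],
            library_ids=frozenset(memberships[rid]),
        )
        for rid in sorted(seqs)
    ]

    if extra_fasta_by_species:
        for sp in sorted(extra_fasta_by_species):
            for rid, seq in read_fasta(extra_fasta_by_species[sp]):
                if rid in seqs:
                    raise ValueError(
                        f"record {rid!r}: duplicated between library and "
                        f"species FASTA"
                    )
                seqs[rid] = seq
                records.append(
                    ProteinRecord(record_id=rid, species_code=sp, sequence=seq)
                )
    return records


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = True) -> None:
    """Write a result table as TSV with a JSON mirror alongside it."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    json_path = path.with_suffix(".json")
    df.to_json(json_path, orient="split", indent=2)
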