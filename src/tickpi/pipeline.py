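"""End-to-end orchestration: classify -> dedup -> repertoire -> conserve -> report.

The pipeline consumes per-library protein FASTA files (named
``lib_<library_id>.fasta``), optional per-species reference FASTA
(``species_<code>.fasta``) and a manifest TSV, and writes every stage's
table as TSV with a JSON mirror, plus a run log recording package versions,
thresholds and input digests.  All analysis stages are deterministic;
reruns on identical inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .align import AlignParams, GLOBAL, LOCAL
from .cluster import (
    RedundancyCluster,
    clusters_table,
    dedup,
    nonredundant_counts,
)
from .conserve import (
    ConservationHit,
    conservation_summary,
    hits_table,
    screen_conservation,
)
from .families import (
    FAMILY_IDS,
    FamilyModel,
    UNASSIGNED,
    assign_family,
    assignments_table,
    catalytic_rollup,
    default_models,
    family_sort_key,
    load_family_models,
)
from .io import load_dataset, parse_library_manifest, write_table
from .records import Library, ProteinRecord
from .repertoire import (
    ConditionAxis,
    RepertoireMatrix,
    build_repertoire_matrix,
    timepoint_table,
)

logger = logging.getLogger("tickpi")

AXIS_NAMES = ("sex", "feeding", "tissue")

#: Table-1-style column layout: three axis triples, then totals.
TABLE1_COLUMNS = [
    "F", "M", "F&M", "FD", "UF", "FD&UF", "SG", "MG", "SG&MG",
    "Total", "Detected", "NeitherTissue",
]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for actionable messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    input_dir: str | Path
    manifest: str | Path
    out_dir: str | Path
    family_config: Optional[str | Path] = None
    focal_species: Optional[str] = None
    redundancy_identity: float = 95.0
    annotation_identity: float = 95.0  # strict: evidence must exceed this
    conservation_identity: float = 50.0
    min_query_coverage: float = 0.5
    families: Sequence[str] = FAMILY_IDS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "redundancy_identity",
            "annotation_identity",
            "conservation_identity",
        ):
            value = getattr(self, name)
            if not 0 < value <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(**raw)


@dataclass
class PipelineResult:
    records: list[ProteinRecord]
    libraries: list[Library]
    assignments: pd.DataFrame
    clusters: list[RedundancyCluster]
    counts: pd.DataFrame
    matrices: dict[str, RepertoireMatrix]
    table1: pd.DataFrame
    rollup: pd.DataFrame
    hits: list[ConservationHit]
    summary: pd.DataFrame
    out_dir: Path = field(default=Path("."))


def discover_inputs(
    input_dir: str | Path,
) -> tuple[dict[str, Path], dict[str, Path]]:
    """Find ``lib_*.fasta`` and ``species_*.fasta`` files in a directory."""
    input_dir = Path(input_dir)
    by_library = {
        p.name[len("lib_") : -len(".fasta")]: p
        for p in sorted(input_dir.glob("lib_*.fasta"))
    }
    by_species = {
        p.name[len("species_") : -len(".fasta")]: p
        for p in sorted(input_dir.glob("species_*.fasta"))
    }
    return by_library, by_species


def load_inputs(
    input_dir: str | Path, manifest: str | Path
) -> tuple[list[ProteinRecord], list[Library]]:
    libraries = parse_library_manifest(manifest)
    by_library, by_species = discover_inputs(input_dir)
    if not by_library:
        raise PipelineError("core_io", f"no lib_*.fasta files in {input_dir}")
    records = load_dataset(by_library, libraries, by_species)
    if not records:
        raise PipelineError("core_io", "input FASTA set contains no records")
    return records, libraries


def classify_records(
    records: Sequence[ProteinRecord],
    models: Sequence[FamilyModel],
    *,
    annotation_identity: float = 95.0,
    params: AlignParams | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assign every record; returns the assignments table and the
    record -> family map of verified records (UNASSIGNED excluded)."""
    assignments = [
        assign_family(
            rec,
            models,
            annotation_identity=annotation_identity,
            params=params or GLOBAL,
        )
        for rec in sorted(records, key=lambda r: r.record_id)
    ]
    table = assignments_table(assignments)
    family_of = {
        a.record_id: a.family_id
        for a in assignments
        if a.family_id != UNASSIGNED
    }
    return table, family_of


def dedup_all(
    records: Sequence[ProteinRecord],
    family_of: Mapping[str, str],
    *,
    threshold: float = 95.0,
    params: AlignParams | None = None,
) -> list[RedundancyCluster]:
    """Greedy redundancy collapse per (species, family) cell."""
    by_cell: dict[tuple[str, str], list[ProteinRecord]] = {}
    for rec in records:
        fam = family_of.get(rec.record_id)
        if fam is None:
            continue
        by_cell.setdefault((rec.species_code, fam), []).append(rec)
    clusters: list[RedundancyCluster] = []
    for (sp, fam) in sorted(
        by_cell, key=lambda cell: (cell[0], family_sort_key(cell[1]))
    ):
        clusters.extend(
            dedup(
                by_cell[(sp, fam)],
                fam,
                threshold=threshold,
                params=params or GLOBAL,
            )
        )
    return clusters


def clusters_from_table(df: pd.DataFrame) -> list[RedundancyCluster]:
    """Rebuild clusters from a clusters TSV (stage-wise CLI use)."""
    out = []
    for row in df.itertuples(index=False):
        members = str(row.members).split(",")
        idents = [float(x) for x in str(row.identities).split(",")]
        out.append(
            RedundancyCluster(
                family_id=row.family,
                species_code=row.species,
                representative_id=row.representative,
                member_ids=members,
                member_identities=dict(zip(members, idents)),
            )
        )
    return out


def repertoire_all(
    clusters: Sequence[RedundancyCluster],
    records: Sequence[ProteinRecord],
    libraries: Sequence[Library],
    focal_species: str,
    *,
    families: Sequence[str] = FAMILY_IDS,
) -> dict[str, RepertoireMatrix]:
    records_by_id = {r.record_id: r for r in records}
    focal = [c for c in clusters if c.species_code == focal_species]
    return {
        axis: build_repertoire_matrix(
            focal,
            records_by_id,
            ConditionAxis.from_libraries(libraries, axis),
            families=families,
        )
        for axis in AXIS_NAMES
    }


def conserve_all(
    clusters: Sequence[RedundancyCluster],
    records: Sequence[ProteinRecord],
    focal_species: str,
    *,
    min_identity: float = 50.0,
    min_query_coverage: float = 0.5,
    params: AlignParams | None = None,
) -> tuple[list[ConservationHit], pd.DataFrame]:
    """Screen focal representatives against other species' non-redundant
    same-family representatives."""
    records_by_id = {r.record_id: r for r in records}
    queries_by_family: dict[str, list[ProteinRecord]] = {}
    subjects_by_family: dict[str, list[ProteinRecord]] = {}
    for c in clusters:
        rep = records_by_id[c.representative_id]
        target = (
            queries_by_family
            if c.species_code == focal_species
            else subjects_by_family
        )
        target.setdefault(c.family_id, []).append(rep)
    hits: list[ConservationHit] = []
    all_queries: list[ProteinRecord] = []
    for fam in sorted(queries_by_family, key=family_sort_key):
        queries = sorted(queries_by_family[fam], key=lambda r: r.record_id)
        all_queries.extend(queries)
        subjects = subjects_by_family.get(fam, [])
        if not subjects:
            continue
        hits.extend(
            screen_conservation(
                queries,
                subjects,
                fam,
                min_identity=min_identity,
                min_query_coverage=min_query_coverage,
                params=params or LOCAL,
            )
        )
    hits.sort(key=lambda h: (-h.identity_percent, h.query_id, h.subject_id))
    return hits, conservation_summary(hits, all_queries)


def report_table1(matrices: Mapping[str, RepertoireMatrix]) -> pd.DataFrame:
    """Render the three axis matrices as one comparative table.

    One row per family, columns F, M, F&M, FD, UF, FD&UF, SG, MG, SG&MG,
    Total (non-redundant count), Detected (clusters seen in any sex-axis
    library) and NeitherTissue (clusters absent from both SG and MG), plus a
    totals row.  Families are ordered numerically.
    """
    missing = [a for a in AXIS_NAMES if a not in matrices]
    if missing:
        raise ValueError(f"missing axes: {missing}")
    sex, feeding, tissue = (
        matrices["sex"], matrices["feeding"], matrices["tissue"]
    )
    if not (sex.families == feeding.families == tissue.families):
        raise ValueError("axis matrices disagree on the family universe")
    rows = {}
    for fam in sex.families:
        s, f, t = sex.data.loc[fam], feeding.data.loc[fam], tissue.data.loc[fam]
        rows[fam] = {
            "F": s["left_exclusive"],
            "M": s["right_exclusive"],
            "F&M": s["shared"],
            "FD": f["left_exclusive"],
            "UF": f["right_exclusive"],
            "FD&UF": f["shared"],
            "SG": t["left_exclusive"],
            "MG": t["right_exclusive"],
            "SG&MG": t["shared"],
            "Total": s["row_total"],
            "Detected": s["detected"],
            "NeitherTissue": t["neither"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    table = table.loc[sorted(table.index, key=family_sort_key), TABLE1_COLUMNS]
    table.loc["total"] = table.sum(axis=0)
    return table


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records, libraries = load_inputs(config.input_dir, config.manifest)
    logger.info("loaded %d records, %d libraries", len(records), len(libraries))

    try:
        models = (
            load_family_models(config.family_config)
            if config.family_config
            else default_models()
        )
        assign_df, family_of = classify_records(
            records, models, annotation_identity=config.annotation_identity
        )
    except (ValueError, KeyError) as exc:
        raise PipelineError("family_classification", str(exc)) from exc
    logger.info("classified %d/%d records", len(family_of), len(records))

    try:
        clusters = dedup_all(
            records, family_of, threshold=config.redundancy_identity
        )
        counts = nonredundant_counts(clusters, families=config.families)
    except ValueError as exc:
        raise PipelineError("redundancy_clustering", str(exc)) from exc
    logger.info("%d non-redundant clusters", len(clusters))

    focal = config.focal_species
    if focal is None:
        with_libs = {lib.species_code for lib in libraries}
        if len(with_libs) != 1:
            raise PipelineError(
                "repertoire_analysis",
                f"cannot infer focal species from manifest ({sorted(with_libs)})",
            )
        focal = with_libs.pop()

    try:
        matrices = repertoire_all(
            clusters, records, libraries, focal, families=config.families
        )
        table1 = report_table1(matrices)
        family_totals = {
            fam: int(
                sum(1 for c in clusters if c.family_id == fam)
            )
            for fam in config.families
        }
        rollup = catalytic_rollup(family_totals)
        tp_table = timepoint_table(
            [c for c in clusters if c.species_code == focal],
            {r.record_id: r for r in records},
            libraries,
        )
    except ValueError as exc:
        raise PipelineError("repertoire_analysis", str(exc)) from exc

    try:
        hits, summary = conserve_all(
            clusters,
            records,
            focal,
            min_identity=config.conservation_identity,
            min_query_coverage=config.min_query_coverage,
        )
    except ValueError as exc:
        raise PipelineError("conservation_screen", str(exc)) from exc
    logger.info("%d conservation hits", len(hits))

    # ---- report bundle ---------------------------------------------------
    write_table(assign_df, out_dir / "assignments.tsv", index=False)
    write_table(clusters_table(clusters), out_dir / "clusters.tsv", index=False)
    write_table(counts, out_dir / "counts.tsv")
    for axis, matrix in matrices.items():
        write_table(matrix.with_totals_row(), out_dir / f"matrix_{axis}.tsv")
    write_table(table1, out_dir / "table1.tsv")
    write_table(rollup, out_dir / "catalytic_rollup.tsv")
    write_table(hits_table(hits), out_dir / "conservation_hits.tsv", index=False)
    write_table(summary, out_dir / "conservation_summary.tsv", index=False)
    write_table(tp_table, out_dir / "timepoints.tsv", index=False)

    by_library, by_species = discover_inputs(config.input_dir)
    run_log = {
        "tickpi_version": __version__,
        "thresholds": {
            "redundancy_identity": config.redundancy_identity,
            "annotation_identity": config.annotation_identity,
            "conservation_identity": config.conservation_identity,
            "min_query_coverage": config.min_query_coverage,
        },
        "focal_species": focal,
        "inputs": {
            str(p): _sha256(p)
            for p in sorted(
                [Path(config.manifest), *by_library.values(), *by_species.values()]
            )
        },
        "n_records": len(records),
        "n_assigned": len(family_of),
        "n_clusters": len(clusters),
        "n_conservation_hits": len(hits),
    }
    (out_dir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True)
    )

    return PipelineResult(
        records=records,
        libraries=libraries,
        assignments=assign_df,
        clusters=clusters,
        counts=counts,
        matrices=matrices,
        table1=table1,
        rollup=rollup,
        hits=hits,
        summary=summary,
        out_dir=out_dir,
    )
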