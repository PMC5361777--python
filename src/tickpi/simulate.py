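"""Synthetic multi-species inhibitor-repertoire scenarios with planted truth.

The generator emulates the statistical structure of a comparative tick
protease-inhibitor dataset: several species, per-family sequence sets
containing near-identical redundancy clusters, cross-species homolog pairs at
controlled identity levels, and per-sequence library memberships across the
study's condition design (whole-body female/male x fed/unfed, plus female
salivary-gland and midgut libraries at 48, 96 and 120 h of feeding).  It
emits exactly the pipeline's input contract — per-library FASTA, a manifest
TSV, per-species reference FASTA for the non-focal species — together with a
machine-readable ground truth (cluster partition, family labels, library
memberships, homolog pairs and the expected repertoire matrix per axis).

Construction guarantees
-----------------------
* Every (species, family) cell has its own random ancestor carrying the
  family's diagnostic motifs; species share nothing else, so cross-species
  identity is high only where the homolog plan plants it.
* Cluster ancestors within a cell are substitution mutants of the cell
  ancestor at the inter-cluster identity (default 80%), keeping any two
  clusters far below the redundancy threshold.
* Cluster members mutate only inside a small per-cluster variable window, so
  every intra-cluster PAIRWISE identity stays at or above the planted intra
  level (default 97%), not just member-to-ancestor identity.
* The member destined to be the greedy representative (all members share a
  length, so the rule picks the smallest id) carries the ancestor sequence
  unchanged; planted homologs are mutated from it, making their realized
  global identity exactly the target.
* Record ids are opaque serials assigned after a global shuffle — nothing
  about cluster, family or species is recoverable from an id.

Substitution-only mutation keeps realized identities analytically exact;
robustness to gapped variation is exercised separately by small hand-built
fixtures in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .families import DEFAULT_MOTIFS, FAMILY_IDS, family_sort_key
from .io import write_fasta, write_library_manifest
from .records import CANONICAL_AA, Library, ProteinRecord, round_half_up

_AA = np.frombuffer(CANONICAL_AA.encode(), dtype="S1").astype("U1")


def default_library_plan(focal_species: str = "aam") -> tuple[Library, ...]:
    """The study's library design: whole-body F/M x fed/unfed, and female
    SG/MG at 48, 96 and 120 h of feeding (10 libraries)."""
    libs = [
        Library("WF_FD", focal_species, sex="F", feeding_state="fed", tissue="whole"),
        Library("WF_UF", focal_species, sex="F", feeding_state="unfed", tissue="whole"),
        Library("WM_FD", focal_species, sex="M", feeding_state="fed", tissue="whole"),
        Library("WM_UF", focal_species, sex="M", feeding_state="unfed", tissue="whole"),
    ]
    for tissue in ("SG", "MG"):
        for tp in (48, 96, 120):
            libs.append(
                Library(
                    f"{tissue}{tp}",
                    focal_species,
                    sex="F",
                    feeding_state="fed",
                    tissue=tissue,
                    timepoint_h=tp,
                )
            )
    return tuple(libs)


@dataclass(frozen=True)
class HomologPlan:
    """Plant one cross-species homolog: a mutant of the focal species'
    cluster representative at *target_identity*, placed in
    *subject_species* as a singleton cluster."""

    family_id: str
    subject_species: str
    target_identity: float
    query_cluster: int = 0  # index of the focal cluster within the family


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    ``cluster_sizes`` maps (species, family) to a tuple of planted cluster
    sizes; :func:`default_config` supplies a three-species, six-family,
    40-cluster design mirroring a scaled-down repertoire study.
    """

    seed: int
    species: tuple[str, ...] = ("aam", "isca", "iric")
    focal_species: str = "aam"
    families: tuple[str, ...] = ("I1", "I2", "I4", "I25", "I39", "I43")
    cluster_sizes: Mapping[tuple[str, str], tuple[int, ...]] = field(
        default_factory=dict
    )
    homologs: tuple[HomologPlan, ...] = ()
    seq_length: int = 150
    intra_identity: tuple[float, float] = (97.0, 100.0)
    inter_identity: float = 80.0
    dedup_threshold: float = 95.0
    conservation_threshold: float = 50.0
    guard_band: tuple[float, float] = (47.0, 53.0)
    membership_prob: float = 0.5
    libraries: tuple[Library, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not self.libraries:
            self.libraries = default_library_plan(self.focal_species)
        if self.focal_species not in self.species:
            raise ValueError("focal species missing from species list")
        unknown = set(self.families) - set(FAMILY_IDS)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")
        lo, hi = self.intra_identity
        if not (self.inter_identity < self.dedup_threshold < lo <= hi <= 100):
            raise ValueError(
                "separation requires inter < dedup threshold < intra range"
            )
        glo, ghi = self.guard_band
        for plan in self.homologs:
            if glo < plan.target_identity < ghi:
                raise ValueError(
                    f"homolog target {plan.target_identity} falls inside the "
                    f"guard band {self.guard_band}"
                )
            if plan.family_id not in self.families:
                raise ValueError(f"homolog family {plan.family_id} not planted")
            if plan.subject_species == self.focal_species:
                raise ValueError("homolog subject must be a non-focal species")


def default_config(seed: int) -> ScenarioConfig:
    """Paper-scale-mini defaults: 3 species, 6 families, 40 planted clusters,
    homologs planted at identities bracketing the 50% threshold."""
    sizes: dict[tuple[str, str], tuple[int, ...]] = {
        ("aam", "I1"): (3, 2, 1, 1),
        ("aam", "I2"): (4, 3, 2, 2, 1, 1, 1),
        ("aam", "I4"): (3, 2, 2, 1, 1, 1),
        ("aam", "I25"): (2, 2, 1, 1),
        ("aam", "I39"): (2, 1, 1),
        ("aam", "I43"): (2, 2, 1, 1),
    }
    for fam in ("I1", "I2", "I4", "I25", "I39", "I43"):
        sizes[("isca", fam)] = (2,)
        sizes[("iric", fam)] = (1,)
    homologs = (
        HomologPlan("I1", "isca", 85.0),
        HomologPlan("I1", "iric", 70.0),
        HomologPlan("I2", "isca", 55.0),
        HomologPlan("I2", "iric", 40.0),
        HomologPlan("I4", "isca", 70.0, query_cluster=1),
        HomologPlan("I25", "isca", 85.0),
        HomologPlan("I25", "iric", 45.0),
        HomologPlan("I39", "isca", 55.0),
        HomologPlan("I43", "iric", 65.0),
    )
    return ScenarioConfig(seed=seed, cluster_sizes=sizes, homologs=homologs)


def mutate_to_identity(
    seq: str,
    target_identity: float,
    seed: int | np.random.Generator,
    *,
    protected: Sequence[int] = (),
    allowed: Optional[Sequence[int]] = None,
) -> str:
    """Substitution-only mutant at exactly the target gapless identity.

    Exactly ``round(len * (100 - target) / 100)`` positions (half-up) are
    substituted, chosen without replacement from *allowed* (default: all
    positions not in *protected*), each to one of the 19 alternative
    residues.  Raises if the required number of substitutions does not fit
    outside the protected positions.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    if len(seq) < 20:
        raise ValueError("sequence too short to mutate controllably (< 20)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_sub = int(round_half_up(len(seq) * (100.0 - target_identity) / 100.0))
    if allowed is None:
        allowed = [i for i in range(len(seq)) if i not in set(protected)]
    else:
        allowed = [i for i in allowed if i not in set(protected)]
    if n_sub > len(allowed):
        raise ValueError(
            f"target {target_identity}% needs {n_sub} substitutions but only "
            f"{len(allowed)} mutable positions exist"
        )
    chars = list(seq)
    positions = rng.choice(np.asarray(allowed, dtype=int), n_sub, replace=False)
    for pos in sorted(int(p) for p in positions):
        alternatives = [aa for aa in CANONICAL_AA if aa != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


@dataclass
class TrueCluster:
    key: str
    species_code: str
    family_id: str
    representative_id: str
    member_ids: list[str]
    library_ids: list[str]


@dataclass
class TrueHomolog:
    family_id: str
    subject_species: str
    query_representative: str
    subject_id: str
    target_identity: float
    realized_identity: float
    expect_retained: bool


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a scenario."""

    family_of: dict[str, str]
    cluster_of: dict[str, str]
    clusters: list[TrueCluster]
    homologs: list[TrueHomolog]
    expected_matrices: dict[str, pd.DataFrame]

    def partition(self, species_code: str | None = None) -> set[frozenset[str]]:
        return {
            frozenset(c.member_ids)
            for c in self.clusters
            if species_code is None or c.species_code == species_code
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_of": self.family_of,
            "cluster_of": self.cluster_of,
            "clusters": [asdict(c) for c in self.clusters],
            "homologs": [asdict(h) for h in self.homologs],
            "expected_matrices": {
                axis: df.to_dict(orient="index")
                for axis, df in self.expected_matrices.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class Scenario:
    config: ScenarioConfig
    records: list[ProteinRecord]
    libraries: list[Library]
    truth: SyntheticTruth

    @property
    def records_by_id(self) -> dict[str, ProteinRecord]:
        return {r.record_id: r for r in self.records}


def _motif_layout(seq_length: int) -> dict[str, list[tuple[int, str]]]:
    """Fixed positions at which each family's two diagnostic motifs are
    embedded (same layout in every species)."""
    layout = {}
    for fam, (m1, m2) in DEFAULT_MOTIFS.items():
        p1 = 15
        p2 = seq_length - 25 - len(m2)
        layout[fam] = [(p1, m1), (p2, m2)]
    return layout


def _random_ancestor(rng: np.random.Generator, length: int, motifs) -> str:
    chars = list(rng.choice(_AA, size=length))
    for pos, motif in motifs:
        chars[pos : pos + len(motif)] = list(motif)
    return "".join(chars)


def _expected_matrix(
    clusters: Sequence[TrueCluster],
    libraries: Sequence[Library],
    axis_sides: tuple[set[str], set[str]],
    families: Sequence[str],
) -> pd.DataFrame:
    """Expected repertoire matrix computed directly from planted memberships
    with plain set arithmetic (independent of the analysis modules)."""
    left_libs, right_libs = axis_sides
    rows = {}
    for fam in sorted(set(families), key=family_sort_key):
        lx = rx = sh = neither = total = 0
        for c in clusters:
            if c.family_id != fam:
                continue
            total += 1
            libs = set(c.library_ids)
            on_l, on_r = bool(libs & left_libs), bool(libs & right_libs)
            if on_l and on_r:
                sh += 1
            elif on_l:
                lx += 1
            elif on_r:
                rx += 1
            else:
                neither += 1
        rows[fam] = {
            "left_exclusive": lx,
            "right_exclusive": rx,
            "shared": sh,
            "detected": lx + rx + sh,
            "neither": neither,
            "row_total": total,
        }
    return pd.DataFrame.from_dict(rows, orient="index", dtype=int)


def generate_scenario(
    config: ScenarioConfig, out_dir: str | Path | None = None
) -> Scenario:
    """Generate a scenario (deterministic given ``config.seed``).

    If *out_dir* is given, writes ``lib_<library_id>.fasta`` per focal
    library, ``species_<code>.fasta`` per non-focal species,
    ``manifest.tsv`` and ``truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    layout = _motif_layout(config.seq_length)
    libraries = list(config.libraries)
    lib_ids = [lib.library_id for lib in libraries]

    # ---- plan slots ------------------------------------------------------
    # Build every sequence slot first, then assign opaque shuffled ids.
    cells = sorted(config.cluster_sizes)
    n_members = sum(
        sum(sizes) for sizes in config.cluster_sizes.values()
    ) + len(config.homologs)
    serials = np.array([f"sq{k:06d}" for k in range(1, n_members + 1)])
    rng.shuffle(serials)
    serial_iter = iter(serials.tolist())

    intra_lo, intra_hi = config.intra_identity
    window = int(
        round_half_up(config.seq_length * (100.0 - intra_lo) / 100.0)
    )

    records: list[ProteinRecord] = []
    truth_clusters: list[TrueCluster] = []
    family_of: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    # ancestors[(species, family)][cluster_index] -> (representative_id, seq)
    ancestors: dict[tuple[str, str], list[tuple[str, str]]] = {}
    membership_by_record: dict[str, set[str]] = {}

    for sp, fam in cells:
        if fam not in config.families or sp not in config.species:
            raise ValueError(f"cluster cell ({sp}, {fam}) outside config scope")
        sub = np.random.default_rng(
            [config.seed, sorted(config.species).index(sp), family_sort_key(fam)]
        )
        motifs = layout[fam]
        protected = [
            p for pos, motif in motifs for p in range(pos, pos + len(motif))
        ]
        cell_ancestor = _random_ancestor(sub, config.seq_length, motifs)
        ancestors[(sp, fam)] = []
        for c_idx, size in enumerate(config.cluster_sizes[(sp, fam)]):
            cl_ancestor = mutate_to_identity(
                cell_ancestor, config.inter_identity, sub, protected=protected
            )
            member_ids = sorted(next(serial_iter) for _ in range(size))
            rep_id = member_ids[0]  # smallest id: the greedy tie-break winner
            mutable = [
                i for i in range(config.seq_length) if i not in set(protected)
            ]
            var_window = sub.choice(
                np.asarray(mutable, dtype=int), window, replace=False
            ).tolist()
            key = f"{sp}:{fam}:{c_idx}"
            # focal clusters carry library memberships; others are reference-only
            if sp == config.focal_species:
                present = [
                    lid for lid in lib_ids if sub.random() < config.membership_prob
                ]
                if not present:
                    present = [lib_ids[int(sub.integers(len(lib_ids)))]]
            else:
                present = []
            member_libs: dict[str, set[str]] = {m: set() for m in member_ids}
            for lid in present:
                member_libs[member_ids[int(sub.integers(size))]].add(lid)
            for m in member_ids:
                if present and not member_libs[m]:
                    member_libs[m].add(present[int(sub.integers(len(present)))])
            for m_idx, member_id in enumerate(member_ids):
                if member_id == rep_id:
                    seq = cl_ancestor
                else:
                    target = float(sub.uniform(intra_lo, intra_hi))
                    seq = mutate_to_identity(
                        cl_ancestor, target, sub, allowed=var_window
                    )
                records.append(
                    ProteinRecord(
                        record_id=member_id,
                        species_code=sp,
                        sequence=seq,
                        library_ids=frozenset(member_libs[member_id]),
                    )
                )
                family_of[member_id] = fam
                cluster_of[member_id] = key
                membership_by_record[member_id] = member_libs[member_id]
            ancestors[(sp, fam)].append((rep_id, cl_ancestor))
            truth_clusters.append(
                TrueCluster(
                    key=key,
                    species_code=sp,
                    family_id=fam,
                    representative_id=rep_id,
                    member_ids=member_ids,
                    library_ids=sorted(present),
                )
            )

    # ---- planted homologs ------------------------------------------------
    truth_homologs: list[TrueHomolog] = []
    for plan in sorted(
        config.homologs,
        key=lambda p: (p.family_id, p.subject_species, p.query_cluster),
    ):
        cell = (config.focal_species, plan.family_id)
        if cell not in ancestors or plan.query_cluster >= len(ancestors[cell]):
            raise ValueError(
                f"homolog plan {plan} references a missing focal cluster"
            )
        rep_id, rep_seq = ancestors[cell][plan.query_cluster]
        motifs = layout[plan.family_id]
        protected = [
            p for pos, motif in motifs for p in range(pos, pos + len(motif))
        ]
        sub = np.random.default_rng(
            [
                config.seed,
                997,
                family_sort_key(plan.family_id),
                sorted(config.species).index(plan.subject_species),
                plan.query_cluster,
            ]
        )
        seq = mutate_to_identity(
            rep_seq, plan.target_identity, sub, protected=protected
        )
        hom_id = next(serial_iter)
        records.append(
            ProteinRecord(
                record_id=hom_id,
                species_code=plan.subject_species,
                sequence=seq,
            )
        )
        family_of[hom_id] = plan.family_id
        key = f"{plan.subject_species}:{plan.family_id}:hom:{rep_id}"
        cluster_of[hom_id] = key
        truth_clusters.append(
            TrueCluster(
                key=key,
                species_code=plan.subject_species,
                family_id=plan.family_id,
                representative_id=hom_id,
                member_ids=[hom_id],
                library_ids=[],
            )
        )
        truth_homologs.append(
            TrueHomolog(
                family_id=plan.family_id,
                subject_species=plan.subject_species,
                query_representative=rep_id,
                subject_id=hom_id,
                target_identity=plan.target_identity,
                realized_identity=_hamming_identity(rep_seq, seq),
                expect_retained=plan.target_identity
                >= config.conservation_threshold,
            )
        )

    # ---- separation self-check ------------------------------------------
    by_cell: dict[tuple[str, str], list[ProteinRecord]] = {}
    rec_by_id = {r.record_id: r for r in records}
    for r in records:
        if "hom" not in cluster_of[r.record_id]:
            by_cell.setdefault(
                (r.species_code, family_of[r.record_id]), []
            ).append(r)
    for (sp, fam), cell_records in sorted(by_cell.items()):
        for i, ra in enumerate(cell_records):
            for rb in cell_records[i + 1 :]:
                same = cluster_of[ra.record_id] == cluster_of[rb.record_id]
                ident = _hamming_identity(ra.sequence, rb.sequence)
                if same and ident < config.dedup_threshold:
                    raise RuntimeError(
                        f"infeasible separation: intra-cluster pair in "
                        f"({sp}, {fam}) at {ident:.1f}%"
                    )
                if not same and ident > config.dedup_threshold - 5:
                    raise RuntimeError(
                        f"infeasible separation: inter-cluster pair in "
                        f"({sp}, {fam}) at {ident:.1f}%"
                    )

    # ---- expected matrices ----------------------------------------------
    focal_clusters = [
        c for c in truth_clusters if c.species_code == config.focal_species
    ]
    axis_defs = {
        "sex": (
            {l.library_id for l in libraries if l.sex == "F"},
            {l.library_id for l in libraries if l.sex == "M"},
        ),
        "feeding": (
            {l.library_id for l in libraries if l.feeding_state == "fed"},
            {l.library_id for l in libraries if l.feeding_state == "unfed"},
        ),
        "tissue": (
            {l.library_id for l in libraries if l.tissue == "SG"},
            {l.library_id for l in libraries if l.tissue == "MG"},
        ),
    }
    expected = {
        axis: _expected_matrix(focal_clusters, libraries, sides, config.families)
        for axis, sides in axis_defs.items()
    }

    truth = SyntheticTruth(
        family_of=family_of,
        cluster_of=cluster_of,
        clusters=truth_clusters,
        homologs=truth_homologs,
        expected_matrices=expected,
    )
    scenario = Scenario(
        config=config, records=records, libraries=libraries, truth=truth
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lib in libraries:
            members = sorted(
                (r.record_id, r.sequence)
                for r in records
                if lib.library_id in r.library_ids
            )
            write_fasta(members, out_dir / f"lib_{lib.library_id}.fasta")
        for sp in sorted(config.species):
            if sp == config.focal_species:
                continue
            members = sorted(
                (r.record_id, r.sequence)
                for r in records
                if r.species_code == sp
            )
            write_fasta(members, out_dir / f"species_{sp}.fasta")
        write_library_manifest(libraries, out_dir / "manifest.tsv")
        truth.to_json(out_dir / "truth.json")
    return scenario
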