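# Methods

This note documents the models, conventions and design choices behind
`tickpi`, in the order the pipeline applies them.  Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and assumptions

The pipeline performs qualitative (presence/absence) repertoire analysis of
protease inhibitors across condition-stratified transcriptome libraries.
It assumes:

- protein (or six-frame-translatable nucleotide) input per library, with a
  manifest declaring each library's species, sex, feeding state, tissue and
  — for dissected salivary-gland/midgut libraries — feeding time point
  (48/96/120 h);
- family membership is decidable from sequence alone (motif or reference
  identity); anything unverifiable is eliminated rather than guessed,
  mirroring conservative catalogue-building practice;
- no quantitative abundance: a sequence observed once in a library counts
  the same as one observed in thousands of reads.  Differential-expression
  claims require orthogonal validation (e.g. qRT-PCR) and are out of scope.

## Translation of nucleotide contigs

Contigs are translated in all six frames under the standard genetic code
(stops as `*`, N-containing codons as `X`, trailing partial codons
dropped).  When a single protein per contig is needed, the longest
stop-free stretch across the frames is used — the stretch a translated
similarity search would effectively score.  Ties break by frame order
(+1, +2, +3, −1, −2, −3), then leftmost start.  Note the longest stretch
need not start at a methionine and frequently comes from the reverse
strand; this is a deliberate, deterministic convention, not ORF prediction.
(An input whose six frames are all stops would return an empty protein;
over the {A,C,G,T} alphabet no such sequence exists, because stop codons
cannot overlap by two bases in any frame combination.)

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with affine
gaps (Gotoh), BLOSUM62 scores, gap open −11 and extend −1 (a length-L gap
costs 11 + L), the BLASTP defaults.  All parameters are configurable and
matrices load from NCBI text format.  Numerical conventions:

- `X` scores 0 against everything and never counts as a match — unknown
  residues cannot inflate identity.
- Traceback ties resolve diagonal → up → left, a gap closes rather than
  extends on a tie, and the local end cell is the first maximum in
  row-major order, making every output bit-stable.
- The row-wise dynamic program resolves the same-row affine recurrence
  with a prefix maximum, which is exact because re-opening a gap out of a
  gap-ending cell can never beat extending (gap open ≤ 0).

Percent identity is reported to one decimal, ties rounded half-up, under
two denominators:

- **shorter** (matches / shorter sequence length) for redundancy decisions,
  so a fragment collapses onto its full-length transcript;
- **columns** (matches / alignment columns, gaps included) for conservation
  decisions, approximating translated-search identity reports.

The paired thresholds honour the two phrasings they implement: redundancy
is *≥ 95%* (inclusive), annotation-by-identity is *> 95%* (strict), and
conservation is *≥ 50%* (inclusive).  Thresholds compare the rounded
one-decimal value.

## Family models

Each of the 18 MEROPS inhibitor families carries a fixed catalytic type:
serine = {I1, I2, I4, I8, I21, I51, I53, I72, I74}, cysteine = {I25, I29,
I31, I32}, metallo = {I35, I43, I63, I68}, non-specific = {I39}.  The
shipped motif models are heuristic literal 10-mer consensus peptides (two
per family, either sufficing), scanned as sliding windows tolerating up to
2 mismatches; regex motifs are supported with exact matching.  The
tolerance makes assignment robust to ~5% residue noise while keeping the
false-positive rate on shuffled sequences far below 5% (both measured in
the test suite).  These defaults are a self-contained stand-in for a
conserved-domain database search, are marked heuristic, and are fully
overridable via the YAML family config (motifs, `min_motif_hits`,
reference FASTA per family).

Rule order is motif first, then identity: the motif is the stronger,
domain-like evidence, and a multi-family motif tie yields UNASSIGNED with
an ambiguity flag rather than a guess (one MEROPS entry is dual-listed
across families, which motivates flagging over dual membership).

## Redundancy collapse

Greedy incremental clustering, longest sequence first (ties by ascending
id), each record joining the first cluster whose representative it matches
at ≥ 95% shorter-denominator identity; the seed is the representative.
Longest-first retains the most complete contig.  When the data are
separated — all intra-cluster pairs above the threshold, all inter-cluster
pairs below — the greedy result provably equals single-linkage clustering
and is order-independent; the test suite checks this against a
connected-components oracle over 50 input permutations and across 20
generator seeds.  Cross-species or cross-family redundancy is never
collapsed: non-redundant counts are per species per family.

## Repertoire matrices

Presence is defined at cluster level as the union of member library
memberships — an inhibitor is "found in" a library if any redundant variant
of it was observed there.  For each axis (sex F/M, feeding fed/unfed,
tissue SG/MG) the per-family counts are the two-way set partition
(left-exclusive, right-exclusive, shared); families with no detections are
kept as zero rows; a totals row equals the column sums.  Clusters absent
from both sides of the tissue axis are surfaced in a `NeitherTissue`
column rather than dropped — on whole-body-plus-tissue designs this number
is biologically meaningful (inhibitors not expressed in either
host-exposed tissue).  Time-point-resolved presence (SG/MG × 48/96/120 h)
is a supplementary per-cluster table, not folded into the two-way matrix.

The package also ships the published survey counts it mirrors
(`tickpi.datasets`) as worked-example inputs.  Two transcription notes:
the source table's footnoted import rows (I4, I68) do not sum to their
printed totals, so the printed totals row is kept verbatim and used for
marginal arithmetic; and the survey's printed cysteine/metallo aggregates
disagree with its own per-family components (which sum to 206 and 167 and
do reproduce its printed percentages), so the component counts are carried.

## Conservation screen

Within each family, every focal representative is aligned locally against
each other species' representatives; the single best hit per
(query, species) by score is retained iff column identity ≥ 50% — best-hit,
not reciprocal-best-hit, matching one reported homolog identity per species
pair.  Because same-family sequences share short diagnostic motifs even
when otherwise unrelated, a motif-sized local alignment can reach 100%
identity over ~10 columns; a minimum query-coverage filter (default: the
alignment must span half the query; set 0 to disable) stands in for the
length-dependent significance statistics of a database search and keeps
such micro-alignments out.  Summaries band each query's best identity as
≥80, 65–80 or 50–65.

## Synthetic scenarios

The generator emulates the statistical structure of the study design, not
its biology.  Defaults (the study conditions for all recovery tests):
3 species with one focal species, 6 families, 40 planted clusters
(sequence length 150), intra-cluster identity 97–100%, inter-cluster
ancestor identity 80%, homologs planted at {40, 45, 55, 65, 70, 85}% —
outside the 47–53% guard band around the screen threshold — and 10
libraries mirroring the design (whole-body F/M × fed/unfed; female SG and
MG at 48, 96, 120 h), each cluster present in a library with probability
0.5 (at least one).

Construction guarantees that make recovery exact rather than probabilistic:

- per-(species, family) random ancestors share only the family motifs
  across species, pinning cross-species background identity far below 50%;
- cluster members mutate only inside a small per-cluster window, bounding
  every intra-cluster *pairwise* identity at ≥ 97% (independent mutation
  would let pairs drift below the 95% threshold);
- the member destined to be the greedy representative carries the ancestor
  sequence unchanged, so planted homolog identities are exact by
  construction (±2 points after alignment, from substitution-count
  discretisation and occasional gap rescue);
- record ids are opaque serials assigned after a global shuffle (no truth
  leakage);
- a post-generation self-check recomputes realized intra/inter identities
  and aborts before writing files if separation is violated.

Mutation is substitution-only, which keeps realized identities analytic;
indel robustness is exercised separately by fragment fixtures in the tests.
What passing recovery tests therefore show is that the pipeline's decisions
are correct *given* well-separated clusters and motif-intact homologs; they
do not show robustness to assembly artifacts, alternative splicing,
chimeric contigs or genuinely boundary-identity variants, none of which the
generator emulates.

## Determinism and problem sizes

A single integer seed drives one named random stream, with per-cell
substreams derived from fixed (seed, species, family) tuples, so edits to
one cell's plan do not reshuffle others.  Analysis stages are seed-free;
two runs on identical inputs are byte-identical (the run log records
versions, thresholds and input digests, not timestamps).  Test and
acceptance runs use the mini scenario above (~75–90 records, ~50
clusters), chosen so the whole suite exercises every decision path in
seconds while the planted structure matches the study design's shape.

## Known limitations

- Default motifs are heuristics, not curated domain models; real analyses
  should supply their own family config with reference members.
- The 95% redundancy rule's original tool and denominator are unreported
  in the source methods; shorter-denominator global identity is this
  package's documented choice (both conventions are exposed).
- Best-hit conservation with a coverage filter approximates, but is not, a
  full translated-search protocol: no significance statistics, no
  composition-based adjustments.
- Presence/absence is qualitative; absence in a library may be technical.
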