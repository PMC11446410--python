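# Methods

This note documents the models and procedures implemented in `hcrkit`,
their assumptions, the parameters that matter, and the choices made
where the design was genuinely open.

## Target normalization and junction masking

Probes that span a splice junction fail to hybridize to the spliced
mRNA, so multi-exon targets carry a junction mask. Two FASTA
conventions are accepted and normalized to the same internal form —
exons concatenated with exactly one `N` between consecutive exons:

* a single record with one or more `N` characters between exons (runs
  of `N` are collapsed to a single masked position; the input does not
  fix a separator length, so equivalence is defined at the
  masked-position level);
* one record per exon in transcript order (per-exon suffixes such as
  `_exon1` are stripped from the gene id when all records share a stem).

`U` is silently mapped to `T` (probes are DNA oligos); IUPAC ambiguity
codes other than `N` are rejected rather than expanded, because an
ambiguous target cannot be tiled deterministically. Coordinates are
0-based half-open internally; all user-facing reports are 1-based
inclusive and say so in their headers.

## Candidate tiling

One candidate window per start position `0 … L − w`, with
`w = 2·arm_len + gap_len` (defaults 25/2 → 52 nt: two 25-nt binding
arms separated by a 2-nt unbound target gap, the canonical HCR v3
split-probe geometry; every dimension is configurable). Windows
containing `N` are emitted with verdict `fail`/`CONTAINS_N`, which is
what excludes junction-spanning probes. Candidate count is therefore
always `L − w + 1`.

## Thermodynamic model

Each arm hybridizes as an independent duplex, so filtering is per-arm,
not per-window. Melting temperature uses the unified nearest-neighbor
model (SantaLucia 1998 parameter set) for a two-state,
non-self-complementary DNA:DNA duplex:

    Tm(K) = 1000·ΔH° / (ΔS° + 0.368·(N−1)·ln[Na⁺] + R·ln(C_T/4))

with ΔH°, ΔS° summed over stacked pairs plus terminal initiation terms,
the SantaLucia (1998) entropic monovalent-salt correction, total strand
concentration `C_T = oligo_conc_molar`, and a linear formamide
correction of −0.6 °C per volume-percent applied last as a pure offset
(keeping the NN core independently checkable). The computation is
delegated to biopython's `Tm_NN` with the `DNA_NN3` table; the test
suite verifies it against a hand-coded summation of the published
table to within 0.01 °C. The sequence is canonicalized to
`min(seq, revcomp(seq))` before scoring so that a duplex and its
reverse complement — the same molecule — get bit-identical Tm.

Choices worth flagging:

* **Salt correction.** The GC-independent entropic correction was
  chosen over GC-dependent 1/Tm corrections (e.g. Owczarzy 2004)
  deliberately: it pairs with the unified parameter set and makes Tm
  strictly increasing in [Na⁺] for *every* sequence, a property the
  package asserts. GC-dependent corrections violate that monotonicity
  for GC fractions above ~0.92 near 1 M salt.
* **DNA:DNA, not DNA:RNA.** The target is mRNA, but probes are scored
  as DNA:DNA duplexes; RNA:DNA nearest-neighbor parameters are less
  standardized and the acceptance windows are calibrated to DNA:DNA
  values. Users should treat the absolute Tm as a consistent ranking
  score under the chosen buffer rather than a measured hybrid Tm.
* **Defaults from the hybridization protocol.** `na_molar = 0.75`
  (5×SSC), `formamide_pct = 30`, `oligo_conc_molar = 1e-8` (10 nM).
  Acceptance windows: post-formamide Tm ∈ [40, 60] °C, GC ∈
  [0.35, 0.65], homopolymer runs ≤ 4 nt — conventional smFISH/HCR
  heuristics; every threshold is exposed in `ThermoConfig`.

## Off-target screen

Criterion: a candidate fails iff its window shares a **contiguous exact
match longer than `max_contig_match` = 16 nt** (i.e. ≥ 17 nt) with any
transcript not in `exclude_ids` (the target's own isoforms). Only the
sense strand is compared: probes are antisense to the target, so they
can only capture another transcript where it is sense-identical to the
target window. Contiguous-match length is a deterministic,
oracle-checkable proxy for cross-hybridization, not a thermodynamic
model; the screen is run on the full 52-nt window (a match spanning the
2-nt gap still tethers the pair region), with the overlapped arm(s)
recorded per hit.

The internal backend indexes every N-free k-mer (`seed_k` = 15) of the
transcriptome and extends each seed hit to its maximal exact match;
since any match of length ≥ `seed_k` contains an aligned seed, the
screen finds exactly the maximal exact matches ≥ `seed_k` (verified
against a quadratic all-substring oracle). The constraint
`seed_k ≤ max_contig_match + 1` guarantees no disqualifying match can
be missed. An optional `blastn` backend (task `blastn-short`, plus
strand, BTOP-parsed longest identity run) supports pre-built BLAST
databases; the internal backend is the default so that designs are
deterministic and dependency-free. BLAST parameters of the original
workflow are not public; this criterion is a documented proxy, not a
reproduction.

By default only candidates that survived the thermodynamic filter are
screened (speed); `screen_failed=True` screens everything, which is
what the fixture-truth comparisons use.

## Selection

`max_count` (default): greedy earliest-end scan over passing windows
with ≥ `min_inter_probe_gap` (default 2) nt between consecutive
windows — optimal for unweighted non-overlapping interval selection,
deterministic with ties broken toward the smaller start.
`even_spread`: binary search on spacing with a greedy feasibility
check, returning `min(target_pairs, achievable)` windows maximizing the
minimum spacing — for users who read "distributed along the target" as
spread rather than count. Fewer than `min_pairs_warn` = 5 final pairs
raises `FEWER_THAN_MIN_PAIRS` as a warning, not an error: five pairs is
the recommended minimum for sufficient amplified signal, but smaller
deliberate designs are not blocked. Note that five 52-nt windows with
2-nt gaps need only 268 nt of clean sequence; short targets usually
fail the rule through filtering, not geometry.

## Pair assembly and validation

Layout convention (arm1 = 5′-proximal target arm, arm2 = 3′-proximal):

    oligo_P1 = half_up + conn_up + revcomp(arm2)
    oligo_P2 = revcomp(arm1) + conn_dn + half_dn

The B1–B5 initiator sequences (36 nt, published HCR v3 amplifier
definitions) ship as an editable TSV registry with 18 + 18 splits and
default `AA`/`TT` dinucleotide connectors; users with vendor-issued
sequences or connectors substitute their own file — no code changes.
The exact vendor oligo layout (which half rides which probe, connector
identity) is not publicly fixed, so the **validation contract, not the
layout, is the source of truth**: `validate_pair` simulates antiparallel
hybridization of both oligos onto the target window, requires both arms
to bind mismatch-free, and reads the unbound overhangs 5′→3′ in
presentation order; the read-off must equal the full initiator exactly.
Arm lengths are inferred from the oligos themselves, so any layout that
reconstitutes the initiator passes, and swapped halves or a single arm
mismatch fail.

Order sheets list one row per oligo (well, name, 5′→3′ sequence,
25 nmol scale, standard desalting) with a pooling note (100 µM stock,
1 µM working); the CSV round-trips sequences byte-exactly. The probe
map reports 1-based window coordinates with per-arm Tm and GC, and
marks junctions.

## Colocalization statistics

For spot sets A and B (coordinates in nm; anisotropic voxel sizes are
applied at load), a spot of A is colocalized iff its nearest neighbor
in B lies at Euclidean distance strictly below the radius (750 nm
default, matching the strict "< radius" convention; a toggle provides
≤). Matching is neighbor-existence rather than one-to-one bipartite
matching — the two directional fractions are independent, which is the
only way they can differ given equal pair counts. KD-tree search is
exact (verified against all-pairs brute force). `summarize_samples`
reports mean counts, the relative percent count difference
`100·(mean_A − mean_B)/mean_B`, and both plausible aggregations of the
directional fractions (per-sample mean and pooled counts), since which
one a given study used is often unstated.

## Synthetic fixtures

All fixtures are pure functions of a seeded `FixtureSpec`; truth
records are computed by interval arithmetic or the sampling plan,
never by the code paths they test.

* **Targets**: uniform-random exons (GC 0.5 by default, configurable),
  emitted in both junction conventions.
* **Decoy transcriptomes**: uniform-random decoys with verbatim copies
  of target segments planted at recorded positions. The bases flanking
  each plant are forced to mismatch the corresponding target bases, so
  the maximal exact match equals the planted overlap exactly and the
  truth record (windows overlapping a plant by > 16 nt) is exact rather
  than probabilistic. Random 15-mer collisions at the tested sizes are
  negligible (~10⁻²-scale expected counts).
* **Spot fields**: `n_shared` true positions duplicated into both sets
  with independent per-axis Gaussian jitter (100 nm default — a
  standard localization-error model), plus exclusive spots per set.
  Defaults (260 shared + 120/85 exclusive → 380 vs 345 spots,
  directional overlaps 68.4 %/75.4 %) emulate the scale of a
  dual-method HCR-vs-smFISH comparison on one sample. The box
  (60 × 60 × 12 µm) keeps spot density low enough that chance
  colocalization at 750 nm is ~1 %, as in sparse single-molecule data;
  at denser packing the statistic measures density, not agreement.

What the fixtures do **not** emulate: real transcriptome composition
(repeats, codon bias, GC skew), transcript abundance, detection errors
correlated between methods, or intensity information. Passing tests
show the algorithms are correct on their contracts, not that a given
probe set will perform in tissue.

## Numerical and determinism notes

Problem sizes in the tests and the acceptance script (2-kb targets,
≤ 10-kb decoy transcriptomes, ≤ 500-spot brute-force comparisons, 200
selection instances of ≤ 25 candidates) were chosen so every oracle is
exhaustively checkable while the full suite stays fast. Selection
optimality is checked against a top-down dynamic program over
(index, last-end) — exact and algorithmically independent of the
greedy path — itself cross-checked against pure subset enumeration on
small instances. All pipeline stages are deterministic: repeated runs
on the same inputs and config produce byte-identical order sheets and
result JSON (asserted end-to-end through the CLI).

## Known limitations

* No secondary-structure (hairpin/self-dimer) screening of oligos and
  no thermodynamic (ΔG) off-target scoring; the contiguous-match proxy
  is conservative for near-exact matches but blind to GC-rich partial
  homology.
* The internal screen is exact-match only (no mismatch tolerance);
  use the BLAST backend for mismatch-tolerant screening.
* DNA:RNA hybrid thermodynamics, divalent-cation corrections, and
  genome-wide (intronic/intergenic) screening are out of scope.
* Spot detection itself is out of scope: the colocalization module
  consumes coordinate tables exported by an image-analysis pipeline.
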