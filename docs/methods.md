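# Methods

## Similarity measure

The similarity between an ordered pair of genomes is fragment-based
average nucleotide identity. The query is cut, contig by contig, into
consecutive non-overlapping windows of `fragment_length` (default
1020 bp); the trailing window of a contig is kept and judged against
its own length, and windows never span contig junctions, so draft
assemblies do not produce artifactual junction fragments. Each
fragment's best local alignment against either strand of the subject
is scored; a fragment passes when the alignment covers at least
`coverage_min` (0.70) of the fragment's length *and* has at least
`identity_min` (30%) identity. Both comparisons are inclusive (a
fragment at exactly the boundary passes), a deliberate choice that
makes the filter boundary testable. ANI is the arithmetic mean of the
passed fragments' identities; the *percentage of aligned fragments* is
the passed fraction of all query fragments and serves as a proxy for
how much of the query genome is alignable at all. When no fragment
passes, ANI is undefined (`None`) and is treated downstream like an
unalignable genome. The measure is asymmetric by construction; code
assignment always uses the new genome as the query.

Identity is defined as identical aligned bases divided by alignment
columns, gap columns included, and `N` never matches anything —
ambiguous input bases (all non-ACGT IUPAC letters are normalized to
`N` on reading) can only lower identity, never raise it.

## Alignment backends

The alignment kernel is an exact Smith–Waterman with match +1,
mismatch −1, linear gap −2, compiled with numba. Three backends share
the filter semantics:

* **exact** — full scan of every subject contig and strand in O(nm)
  time with O(m) memory, followed by traceback inside a window that
  provably contains the optimum (a positive-score local alignment of a
  length-n query spans < 1.5 n subject bases under these penalties).
  Ties on score are broken toward the lower subject contig index, the
  lower subject start, and the forward strand. Intended for small
  subjects; cost grows with fragment × subject size.
* **seeded** (default) — edlib's infix alignment locates the
  best-matching region of each contig per strand in O(nm/64); the same
  Smith–Waterman kernel then runs inside a ±200 bp window around it.
  For genome-scale subjects this is ~50× faster than the full scan and
  agrees with it everywhere the fragment has a genuine homolog; it is
  heuristic only for fragments with no real match, which the filters
  discard anyway.
* **blast** — one external `blastn` invocation per genome pair with
  all fragments as queries (best HSP per fragment by bit score), for
  parity runs against published ANIb values. Requires BLAST+ on PATH.

The test suite checks the production backends against an independent
exhaustive dynamic-programming oracle (biotite's optimal local
alignment with the same scoring): identities agree within 0.5
percentage points on ≥ 95% of random 200–500 bp fragments. Exact
agreement is not required because co-optimal alignments may differ in
their gap placement.

## Core-genome filter

With `core_filter_enabled`, a second filtration step keeps only passed
fragments whose identity lies within `core_filter_halfwidth` (default
0.1 percentage points, boundary inclusive) of the median passed
identity; the percentage of aligned fragments always refers to the
pre-filter count. The window phrase "within a 0.1 interval of the
median" admits two readings — halfwidth 0.1 (total width 0.2) or total
width 0.1 — and the halfwidth reading is the default here, with the
alternative one configuration value away. Horizontally transferred
regions sit far below the median identity of the vertical backbone and
are excluded, so the filtered ANI approximates vertical descent. The
result is never empty: the median-attaining fragments always survive;
for degenerate strongly bimodal inputs where even the two central
values lie more than the halfwidth from their mean, the filter returns
its input unchanged and sets a warning flag rather than crashing.

## Code assignment

Codes live over an ordered threshold table (default 24 positions, 60%
to 99.9999%, strictly increasing; the spacing tightens to the right
because the system's resolution goal is among near-identical genomes).
The first genome registered receives 0 at every position. Every later
genome is compared to *all* registered genomes; subjects reaching
`trust_min_pct_aligned` (20%) aligned fragments take precedence, and
among them the highest ANI wins (ties to the earliest registered).
The threshold walk copies the anchor's value while ANI *strictly*
exceeds the position's cutoff — a genome at exactly the threshold does
not share the position — and at the first failure issues a fresh value
and zeros to the right. An ANI above all thresholds copies the
anchor's full code; code collisions among effectively identical
genomes are legitimate, and only genome identity (a SHA-256 over the
ordered contig sequences) is unique. Duplicate submissions are
rejected with the existing entry.

Fresh values are numbered within the *sibling group*: 1 + the maximum
value at that position among entries whose codes agree with the new
code at every earlier position, or 0 when the prefix is brand new.
This reproduces sequential 0, 1, 2, … numbering inside each lineage
without collisions or skipped values; a walk that fails at position y
always yields at least 1 there, because the anchor itself is a sibling.

A query that no registered genome anchors (all below the 20% cutoff,
or undefined ANI) founds a new lineage: a fresh value at the first
position, zeros elsewhere. Its highest-ANI subject and ANI are still
recorded for provenance but flagged untrusted.

Codes are immutable: registering genome n+1 never alters codes
1..n. The registry serializes to JSON-lines with a header carrying the
threshold table and configuration digest; entries store the genome's
checksum and source FASTA path, so a registry can be reloaded,
verified against its sequences, and extended bit-identically.

## Synthetic clades

The simulator evolves a uniformly random ancestor down a rooted tree
whose branch lengths are per-site substitution probabilities; each
site mutates at most once per branch, to one of the three alternative
bases uniformly (the simplest symmetric model — the package tests
classification machinery, not evolutionary realism). The closed-form
expected identity between leaves is `25 + 75·∏(1 − 4·p_i/3)` percent
over the path's branches. Optional horizontal transfer replaces a
same-length segment of one leaf with a copy mutated at a chosen donor
rate; optional short indels (1–10 bp, terminal branches only, default
off) keep coordinates interpretable. Every mutation is recorded in a
ledger whose replay reproduces each leaf exactly, giving an oracle for
ANI-recovery and core-filter tests that is independent of the aligner.

What the simulator does *not* emulate: rearrangements, gene content
differences, repeat families, sequencing error, and unalignable
accessory genomes. Passing tests therefore demonstrate the correctness
of the tiling/filtering/assignment machinery under controlled
divergence, not performance on real draft assemblies, where the
percentage of aligned fragments carries most of the burden.

## Order-robustness study

`permutation_study` replays registry construction under n uniformly
random orders and records, per unordered genome pair, the last shared
code position (−1 when none). The reference for "changed" is the modal
value across orders (ties toward the smaller position) — an order-free
choice, with the alphabetical-order result reported alongside. The
per-pair outputs are the count of deviating orders and the maximum
absolute shift; pairs shifting by more than one position are flagged,
not failed, since the one-position bound is an empirical regularity,
not a theorem. Similarities are cached by content checksum and
configuration digest, so a 100-order study aligns each ordered pair
exactly once.

## Problem sizes and numerical choices

The validation battery uses a 12-genome clade (3 families × 2 genera ×
2 strains) from a 100 kb ancestor, with expected identities ≈ 88.1%,
98.5% and 99.95% — each tier placed well inside a threshold interval
(margins of several times the fragment-sampling noise) so clade
recovery is deterministic; the horizontal-transfer fixture is a
99.9%-identical 61.2 kb pair with a 10.2 kb segment at 30% donor
divergence (10 of 60 fragments). These sizes keep per-fragment
statistics stable (≈ 0.1 pp ANI standard error) while a full study
remains a desk-scale computation. Seeds are fixed throughout;
identical inputs, configuration and seed reproduce every output
byte-for-byte.

Known limitations: one best alignment per fragment (no HSP merging);
the seeded backend can misplace fragments that have several equally
good homologous copies (ties are then resolved by edlib's placement
rather than the documented subject-order rule); ANI between genomes
sharing < 20% aligned fragments is reported but deliberately never
used as a basis for code assignment; and there is no global numbering
authority — each registry numbers its own lineages.
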