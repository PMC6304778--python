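# Methods

This note documents the algorithms, defaults and design decisions behind
`surecell`, and what its synthetic-data tests do and do not demonstrate
about real sequencing data.

## Read model

A SureCell Read 1 is modelled as the concatenation

```
phase block (variable) · BC1 (6) · L1 (15) · BC2 (6) · L2 (15) · BC3 (6) · ACG · UMI (8) · GAC · trailing bases
```

The phase block's variable length is the defining nuisance of this
chemistry: it de-phases every downstream feature, so the two linkers are
the only usable anchors. All lengths and sequences are configuration
(`ReadStructureConfig`, editable via a `key=value` structure file):

| parameter | default | role |
|---|---|---|
| `linker1`, `linker2` | `TAGCCATCGCATTGC`, `TACCTCTGAGCTGAA` | 15-nt anchors; package defaults, replaceable per kit |
| `barcode_len` | 6 nt | length of each whitelist block |
| `umi_len` | 8 nt | UMI length (not derivable from structure; 8 nt is standard for this chemistry) |
| `pre/post_umi_flanker` | `ACG` / `GAC` | fixed trinucleotides bracketing the UMI |
| `expected_linker_gap` | 21 nt | L1→L2 start distance; must equal `barcode_len + len(linker1)` |
| `min_l1_start` | 7 | enforces a ≥ 1-nt phase block before BC1 |
| `max_linker_edits` | 1 | per-linker Levenshtein budget (0 or 1) |
| `max_flanker_mismatches` | 1 | total across both trinucleotides; no indel search |
| `max_barcode_edits` | 1 | per-block whitelist budget (0 or 1) |
| `strict_gap` | off | when on, only the exact 21-nt spacing is accepted |

## Linker search

`find_linker` scans every read offset for four interpretations of the
linker: exact (span 15), one substitution (span 15), one deletion (span
14) and one insertion (span 16). 'N' matches nothing. All matching
interpretations are emitted, ordered by (edit distance, start, type
priority exact > substitution > deletion > insertion), with one filter:
when an exact occurrence exists, 1-edit interpretations overlapping it
are suppressed. An exact hit always spawns such "shadows" (drop the first
linker base and a deletion reading appears one position over), and
treating them as independent evidence lets structurally failing reads
masquerade as valid ones.

The per-linker budget is total Levenshtein distance ≤ 1 — one
substitution *or* one indel, never both. Linker variants with two or more
edits are rare in real data, so widening the budget would buy little
recovery at a real cost in mis-anchoring risk.

## Parse selection

Candidate (L1 hit, L2 hit) pairs are tried in order of total edit
distance, then left-most starts. A pair must pass, in order: the spacing
check (`D`; accepted gaps {20, 21, 22} unless strict — a single indel in
L1 or BC2 shifts the spacing by exactly one), the L1-offset check (`P`),
and the read-length check (`S`; the read must reach the end of the
post-UMI flanker). For a validated pair the flankers are checked (`T`)
and the three blocks resolved (`B`).

Two refinements matter in edge cases:

- **Equal-distance fallback.** An edit at a linker edge can admit two
  equal-distance interpretations (e.g. a deletion at linker position 0
  also reads as a substitution one base earlier), and only one lines the
  barcode windows up with the whitelist. All validated pairs at the
  *minimal* total edit distance are therefore tried, and among fully
  valid parses the one requiring the fewest whitelist corrections wins
  (ties: pair order). The fallback never crosses to a higher edit
  distance — a failed best parse is a failed read, not an invitation to
  speculate.
- **BC1 prefix rescue.** BC1 has no left anchor, so an indel between the
  read start and L1 shifts its window undetectably. When the standard
  window has *no* whitelist match (never on an ambiguous match), the
  window moved one base left and then the 5-mer window are tried. This
  recovers insertions at the BC1/L1 boundary and deletions inside
  BC1/phase. The UMI side needs no analogue: the ACG/GAC flankers are
  checked without indel search by design, so indels downstream of L2
  surface as `T`.

Error precedence is `LX > L1 > L2 > D > P > S > T > B` — one code per
read, structural failures masking content failures. The code names beyond
L1/L2/LX/B are this package's own (the taxonomy is closed and documented
in `ErrorCode`).

The UMI is reported verbatim, never corrected: UMIs are random by design,
so there is nothing to correct against, and downstream deduplicators
expect raw UMIs.

## Whitelist correction

A block resolves to an exact whitelist entry, else to the *unique* entry
within Levenshtein distance 1 (5- and 7-mer blocks, produced by
indel-implying spacings, resolve the same way). Two candidates mean
ambiguity and the read fails with `B`; guessing would silently
cross-contaminate cells. One whitelist serves all three positions.

The shipped whitelist is a synthetic, deterministically generated set of
96 6-mers with pairwise Hamming distance ≥ 3 (the vendor list is not
public material this package can ship). Distance ≥ 3 makes every
single-substitution error uniquely correctable, which the analytic
error-rate machinery exploits; real kits may not have this property, in
which case ambiguous-block (`B`) rates rise but nothing else changes.

## QC and cell calling

- **Outcome distribution**: counts and fractions for PASS plus all eight
  codes (zero counts included; fractions sum to 1).
- **Per-cell counts**: valid reads per 18-nt barcode, sorted by count
  descending with lexicographic tie-breaks, so every derived file is
  deterministic.
- **Cumulative curve**: cumulative fraction of *total* valid reads in the
  top-n barcodes (default n = 5000).
- **Knee estimate**: both axes of the cumulative curve are normalized to
  [0, 1] (otherwise rank span dominates the geometry) and the returned
  rank maximizes perpendicular distance to the chord joining the curve's
  endpoints; ties go to the smallest rank, so a perfectly straight curve
  returns 1. When top-n exceeds the number of observed barcodes the curve
  is padded flat, which makes a k-cells-only table yield exactly k. The
  estimate is deterministic and invariant to uniform scaling of counts.
  The method is swappable; any rank/fraction-based alternative can be
  applied to the same count table.

## Output contract

Every input pair yields exactly one unmapped BAM record (flag 4, no
reference, Read 2 sequence and qualities verbatim): valid reads carry the
cell and UMI tags, invalid ones the error tag and neither of the others.
`--drop-invalid` exists for pipelines that want only taggable reads. Tag
names default to the Drop-seq convention (XC/XM) plus XE and are
user-configurable; collisions with reserved SAM tags are rejected at
configuration time, except the predefined cell/UMI tags (CB, CR, …) whose
meaning is the intended one. With `--cores k`, chunks are extracted in a
process pool but consumed in submission order, so output is identical to
a single-core run.

## Synthetic data generator

The generator assembles reads from explicit parts, draws each error class
independently per read with its configured probability, mutates the named
part, and records the realized errors. Defaults: phase-block length
uniform on 1–5 nt, 8-nt random UMI, constant high base qualities
(extraction never reads qualities), random 60-nt Read 2 (alignment is out
of scope, so no transcriptome is emulated), 4-nt trailing bases.
Identical seeds give byte-identical gzip outputs (gzip mtime pinned).

**The oracle.** `expected_status` derives each read's mandated outcome
from the realized parts alone — per-linker Levenshtein distance against
budget, spacing from part lengths, flanker mismatches at shifted
coordinates, exhaustive whitelist neighborhoods — through an independent
code path (its own DP, its own scan). Two subtleties:

- *Boundary canonicalization.* An insertion at a linker edge produces a
  read identical to one with the edit in the adjacent block; likewise a
  deletion at the edge of a homopolymer run shared with a neighbor.
  Outcomes must depend on the sequence, not on which part was labelled as
  edited, so the oracle re-assigns such edits to the neighboring block
  before classifying.
- *Lookalike redraw.* A multi-edit linker mutation occasionally recreates
  a window within the edit budget (two substitutions mimicking one
  deletion); such a read is no longer an over-budget read at all, so the
  generator redraws the mutation (bounded retries) to keep each error
  class semantically clean.

With these rules, extraction reproduces the oracle's expected status for
100% of generated reads across all single-error classes, the empty model,
and substitution-based mixtures — verified at n = 50,000 in the
acceptance suite. One irreducible residue remains: for roughly 0.5% of
deletion-in-linker reads, two equal-distance parses exist whose blocks
are *both* exact whitelist entries (a shift happens to spell a different
valid barcode). Both parses are fully consistent with the read; the
extractor's tie-break picks one deterministically. Status always agrees
with the oracle (both say valid), but the barcode identity on such reads
is genuinely undecidable, so barcode-level assertions in the tests are
restricted to classes without this degeneracy.

**Analytic expectations.** For substitution-based error models (plus
linker/BC2 indels), exact per-code outcome probabilities are computed by
enumerating error-spec subsets and averaging the content-dependent
barcode branch over the realized cells' blocks. The 50,000-read
acceptance check requires every observed code count within 3 binomial
standard deviations of this expectation.

**What passing does not show.** The generator emulates structural errors,
not sequencing physics: no quality-correlated error profile, no
transcriptome, no doublets, no ambient RNA. Agreement on synthetic data
validates the extraction *logic*; PASS rates on real runs depend on run
quality and will differ.

## Problem sizes

Defaults were chosen so the whole suite exercises meaningful scales while
staying comfortably interactive: perfect recovery at 10,000 reads,
aggregate recovery at 50,000 reads, oracle equivalence at 10,000 random
reads (length 50) plus all 4⁵+4⁶+4⁷ barcode queries, knee recovery at
300 cells against 2000 noise barcodes, exhaustive single-edit sweeps at
all 15 positions × 3 edit kinds × 2 linkers and all 105 double-substitution
position pairs per linker.

## Known limitations

- Linker edit distance is capped at 1; reads with a 2-edit linker are
  rejected rather than rescued.
- No quality-weighted correction; base qualities pass through untouched.
- No UMI deduplication, alignment, or gene counting — the tagged BAM is
  the hand-off point.
- Per-position whitelists are not supported (one list serves BC1–BC3).
- The flanker check performs no indel search, so indels between L2 and
  the UMI region surface as `T` rather than being absorbed.
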