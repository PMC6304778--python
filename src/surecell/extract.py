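"""Tag extraction from Read 1.

Implements the six-step recovery procedure for SureCell reads:

1. locate both 15-nt linkers, tolerating one substitution OR one indel
   per linker (total Levenshtein distance <= 1);
2. check the linker start-to-start spacing (nominally 21 nt; 20/22
   accepted as evidence of a single indel in linker 1 or BC2);
3. check that linker 1 starts at offset >= 7 (a >=1-nt phase block must
   precede BC1);
4. check the two trinucleotides flanking the UMI (ACG / GAC, at most one
   mismatch total, no indel search);
5. extract BC1, BC2, BC3 and the UMI positionally relative to the linker
   hits, so indel-induced coordinate shifts are absorbed;
6. resolve each barcode block against the whitelist (exact, else unique
   within one edit).

Failures are never exceptions: each read yields exactly one
:class:`~surecell.model.TagResult`, either valid (corrected 18-nt cell
barcode + verbatim UMI) or invalid with a single error code.
"""

from __future__ import annotations

from surecell.model import (
    AMBIGUOUS,
    NO_MATCH,
    BarcodeWhitelist,
    EDIT_TYPE_RANK,
    EditType,
    ErrorCode,
    LinkerHit,
    ReadStructureConfig,
    TagResult,
)

__all__ = [
    "find_linker",
    "validate_structure",
    "check_flankers",
    "correct_barcode",
    "extract_tags",
]


def _mismatches_leq(seg: str, pat: str, budget: int) -> int | None:
    """Hamming mismatches of equal-length strings if <= budget, else None.

    'N' in the read never matches a pattern base.
    """
    d = 0
    for a, b in zip(seg, pat):
        if a != b or a == "N":
            d += 1
            if d > budget:
                return None
    return d


def _matches_one_deletion(seg: str, pat: str) -> bool:
    """True if seg equals pat with exactly one base deleted (len(seg)=len(pat)-1)."""
    i = 0
    n = len(seg)
    while i < n and seg[i] == pat[i] and seg[i] != "N":
        i += 1
    # skip pat[i]; the remainder must match exactly
    while i < n:
        if seg[i] != pat[i + 1] or seg[i] == "N":
            return False
        i += 1
    return True


def _matches_one_insertion(seg: str, pat: str) -> bool:
    """True if seg equals pat with one base inserted (len(seg)=len(pat)+1)."""
    return _matches_one_deletion(pat, seg) if "N" not in pat else False


def find_linker(read1_seq: str, linker: str, max_edits: int = 1) -> list[LinkerHit]:
    """All occurrences of ``linker`` in ``read1_seq`` within ``max_edits``.

    Returns hits ordered by (edit distance, start).  At a given start only
    the best interpretation is kept, preferring
    exact > substitution > deletion > insertion.  A deletion hit spans
    ``len(linker) - 1`` read bases, an insertion hit ``len(linker) + 1``.
    """
    if max_edits not in (0, 1):
        raise ValueError("max_edits must be 0 or 1")
    n, m = len(read1_seq), len(linker)
    hits: list[LinkerHit] = []
    for s in range(n):
        # every interpretation matching at this start is emitted: an edit at
        # a linker edge can admit e.g. both a substitution and a deletion
        # reading, and only downstream context can tell which is right
        if s + m <= n:
            seg = read1_seq[s : s + m]
            if seg == linker:
                hits.append(LinkerHit(s, s + m, 0, EditType.EXACT))
            elif max_edits >= 1 and _mismatches_leq(seg, linker, 1) == 1:
                hits.append(LinkerHit(s, s + m, 1, EditType.SUBSTITUTION))
        if max_edits >= 1:
            if s + m - 1 <= n and _matches_one_deletion(read1_seq[s : s + m - 1], linker):
                hits.append(LinkerHit(s, s + m - 1, 1, EditType.DELETION))
            if s + m + 1 <= n and _matches_one_insertion(read1_seq[s : s + m + 1], linker):
                hits.append(LinkerHit(s, s + m + 1, 1, EditType.INSERTION))
    exact_spans = [(h.start, h.end) for h in hits if h.edit_distance == 0]
    if exact_spans:
        # an exact occurrence makes overlapping 1-edit reinterpretations
        # (drop/duplicate an edge base) shadows, not independent evidence
        hits = [
            h
            for h in hits
            if h.edit_distance == 0
            or all(h.end <= s or h.start >= e for s, e in exact_spans)
        ]
    hits.sort(key=lambda h: (h.edit_distance, h.start, EDIT_TYPE_RANK[h.edit_type]))
    return hits


def validate_structure(
    hit1: LinkerHit, hit2: LinkerHit, read_len: int, cfg: ReadStructureConfig
) -> ErrorCode | None:
    """Spacing / offset / length checks for a candidate linker pair.

    Checks run in the order D (gap), P (linker-1 offset), S (read length);
    the first failure is returned, ``None`` means the pair is usable.
    The S check requires the read to reach the end of the post-UMI
    flanker: ``hit2.end + barcode_len + 3 + umi_len + 3``.
    """
    if hit2.start - hit1.start not in cfg.accepted_gaps:
        return ErrorCode.D
    if hit1.start < cfg.min_l1_start:
        return ErrorCode.P
    need = (
        hit2.end
        + cfg.barcode_len
        + len(cfg.pre_umi_flanker)
        + cfg.umi_len
        + len(cfg.post_umi_flanker)
    )
    if read_len < need:
        return ErrorCode.S
    return None


def check_flankers(
    read1_seq: str, bc3_end: int, cfg: ReadStructureConfig
) -> ErrorCode | None:
    """Verify the ACG / GAC trinucleotides around the UMI.

    Counts mismatches of the bases at ``bc3_end`` against the pre-UMI
    flanker plus the bases after the UMI against the post-UMI flanker;
    no shifting or indel search is attempted.  Returns T when the total
    exceeds ``cfg.max_flanker_mismatches``.
    """
    pre = cfg.pre_umi_flanker
    post = cfg.post_umi_flanker
    umi_start = bc3_end + len(pre)
    post_start = umi_start + cfg.umi_len
    mism = 0
    for a, b in zip(read1_seq[bc3_end : bc3_end + len(pre)], pre):
        if a != b or a == "N":
            mism += 1
    for a, b in zip(read1_seq[post_start : post_start + len(post)], post):
        if a != b or a == "N":
            mism += 1
    return None if mism <= cfg.max_flanker_mismatches else ErrorCode.T


def correct_barcode(block: str, whitelist: BarcodeWhitelist, max_edits: int = 1):
    """Resolve one barcode block against the whitelist.

    Returns the (corrected) whitelist entry, or :data:`NO_MATCH` /
    :data:`AMBIGUOUS`.  Blocks one base shorter or longer than the
    whitelist length arise from indel-implying linker spacings and are
    matched at Levenshtein distance 1.
    """
    return whitelist.lookup(block, max_edits=max_edits)


#: candidate linker-hit pairs examined per read (bounds pathological inputs)
_MAX_PAIRS = 32


def _extract_from_pair(
    seq: str, h1: LinkerHit, h2: LinkerHit, cfg: ReadStructureConfig,
    whitelist: BarcodeWhitelist,
) -> tuple[ErrorCode | None, str | None, str | None, int]:
    """Steps 4-6 for one structurally validated linker pair.

    Returns (error, cell_barcode, umi, n_corrected_blocks).
    """
    k = cfg.barcode_len
    bc1 = seq[h1.start - k : h1.start]
    bc2 = seq[h1.end : h2.start]
    bc3 = seq[h2.end : h2.end + k]
    bc3_end = h2.end + k
    err = check_flankers(seq, bc3_end, cfg)
    if err is not None:
        return err, None, None, 0
    corrected = []
    n_corr = 0
    m1 = correct_barcode(bc1, whitelist, cfg.max_barcode_edits)
    if m1 is AMBIGUOUS:
        return ErrorCode.B, None, None, 0
    if m1 is NO_MATCH:
        # an indel in the phase-block/BC1 prefix shifts the BC1 window
        # without disturbing the linker anchor: retry the window moved
        # one base left (insertion), then shrunk to k-1 (deletion)
        for alt in (
            seq[h1.start - k - 1 : h1.start - 1] if h1.start >= k + 1 else "",
            seq[h1.start - k + 1 : h1.start],
        ):
            m_alt = correct_barcode(alt, whitelist, cfg.max_barcode_edits) if alt else NO_MATCH
            if m_alt is not NO_MATCH and m_alt is not AMBIGUOUS:
                m1 = m_alt
                break
        else:
            return ErrorCode.B, None, None, 0
    if m1 != bc1:
        n_corr += 1
    corrected.append(m1)
    for block in (bc2, bc3):
        m = correct_barcode(block, whitelist, cfg.max_barcode_edits)
        if m is NO_MATCH or m is AMBIGUOUS:
            return ErrorCode.B, None, None, 0
        if m != block:
            n_corr += 1
        corrected.append(m)
    umi_start = bc3_end + len(cfg.pre_umi_flanker)
    umi = seq[umi_start : umi_start + cfg.umi_len]
    return None, "".join(corrected), umi, n_corr


def extract_tags(
    read1_seq: str,
    cfg: ReadStructureConfig,
    whitelist: BarcodeWhitelist,
    read_id: str = "",
) -> TagResult:
    """Run the full recovery procedure on one Read 1 sequence.

    Candidate linker-hit pairs are tried in order of total edit distance,
    then left-most starts; the first pair that yields a fully valid parse
    wins (an edit at a linker edge can admit two equal-distance
    interpretations, only one of which lines the barcode windows up with
    the whitelist).  If no pair parses, the highest-priority pair's
    failure code is reported.  Returns a valid :class:`TagResult`
    carrying the corrected BC1+BC2+BC3 cell barcode and the verbatim
    (never corrected) UMI, or an invalid result with a single error code.
    """
    seq = read1_seq if read1_seq.isupper() else read1_seq.upper()
    hits1 = find_linker(seq, cfg.linker1, cfg.max_linker_edits)
    hits2 = find_linker(seq, cfg.linker2, cfg.max_linker_edits)
    if not hits1 and not hits2:
        return TagResult(read_id, error_code=ErrorCode.LX)
    if not hits1:
        return TagResult(read_id, error_code=ErrorCode.L1)
    if not hits2:
        return TagResult(read_id, error_code=ErrorCode.L2)

    pairs = [
        (
            h1.edit_distance + h2.edit_distance,
            h1.start,
            h2.start,
            EDIT_TYPE_RANK[h1.edit_type] + EDIT_TYPE_RANK[h2.edit_type],
            h1,
            h2,
        )
        for h1 in hits1
        for h2 in hits2
        if h2.start > h1.start
    ]
    pairs.sort(key=lambda p: p[:4])
    if not pairs:
        # hits exist but linker 2 never lies downstream of linker 1
        return TagResult(read_id, error_code=ErrorCode.D)

    first_code: ErrorCode | None = None
    min_valid_dist: int | None = None
    candidates: list[tuple[int, int, str, str]] = []
    for idx, (dist, _, _, _, h1, h2) in enumerate(pairs[:_MAX_PAIRS]):
        if min_valid_dist is not None and dist > min_valid_dist:
            break  # never rescue with a worse parse than the best structural one
        err = validate_structure(h1, h2, len(seq), cfg)
        if err is None:
            if min_valid_dist is None:
                min_valid_dist = dist
            err, barcode, umi, n_corr = _extract_from_pair(seq, h1, h2, cfg, whitelist)
            if err is None:
                if n_corr == 0:
                    return TagResult(read_id, cell_barcode=barcode, umi=umi)
                candidates.append((n_corr, idx, barcode, umi))
        if first_code is None:
            first_code = err
    if candidates:
        # among equal-distance parses, the one needing the fewest barcode
        # corrections is the least speculative reading of the read
        _, _, barcode, umi = min(candidates)
        return TagResult(read_id, cell_barcode=barcode, umi=umi)
    return TagResult(read_id, error_code=first_code)
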