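"""Synthetic paired-FASTQ generator with ground truth.

Reads are assembled from explicit generative parts (phase block, three
barcode blocks, linkers, flankers, UMI, tail), errors are injected into
named parts, and the expected extraction outcome is derived from the
realized parts by budget arithmetic that never touches the extraction
code path — so generated datasets come with an independent oracle for
every read.

The generator emulates the variable phase block (default 1-5 nt), which
is what makes linker positions float across reads.  It does not emulate
transcriptome content (Read 2 is random sequence) or quality-correlated
error processes; extraction ignores base qualities, so neither matters
for the properties tested here.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from surecell.model import (
    BarcodeCountTable,
    BarcodeWhitelist,
    ErrorCode,
    ReadStructureConfig,
)

__all__ = [
    "ErrorSpec",
    "ReadParts",
    "TruthRecord",
    "GeneratedDataset",
    "generate_dataset",
    "expected_status",
    "expected_code_fractions",
    "simulate_count_table",
]

import random

_BASES = "ACGT"

#: order of the generative parts along Read 1
PART_ORDER = (
    "phase",
    "bc1",
    "linker1",
    "bc2",
    "linker2",
    "bc3",
    "flanker_pre",
    "umi",
    "flanker_post",
    "tail",
)

ERROR_TARGETS = frozenset(PART_ORDER) - {"tail"}
ERROR_KINDS = frozenset({"substitution", "insertion", "deletion"})


@dataclass(frozen=True)
class ErrorSpec:
    """One error class to inject: where, what kind, how many edits."""

    target: str
    kind: str
    position: int | str = "random"
    count: int = 1

    def __post_init__(self) -> None:
        if self.target not in ERROR_TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.position != "random" and self.count != 1:
            raise ValueError("fixed position requires count == 1")


@dataclass
class ReadParts:
    """The realized segments of one Read 1, in generative coordinates."""

    phase: str
    bc1: str
    linker1: str
    bc2: str
    linker2: str
    bc3: str
    flanker_pre: str
    umi: str
    flanker_post: str
    tail: str

    def sequence(self) -> str:
        return "".join(getattr(self, p) for p in PART_ORDER)

    @classmethod
    def clean(
        cls,
        cell: tuple[str, str, str],
        umi: str,
        phase: str,
        cfg: ReadStructureConfig,
        tail: str = "",
    ) -> "ReadParts":
        return cls(
            phase=phase,
            bc1=cell[0],
            linker1=cfg.linker1,
            bc2=cell[1],
            linker2=cfg.linker2,
            bc3=cell[2],
            flanker_pre=cfg.pre_umi_flanker,
            umi=umi,
            flanker_post=cfg.post_umi_flanker,
            tail=tail,
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated read pair."""

    read_id: str
    true_cell_barcode: str
    expected_cell_barcode: str | None
    expected_umi: str | None
    phase_block_len: int
    injected_errors: tuple[str, ...]
    expected_status: str  # "valid" or an ErrorCode value


@dataclass(frozen=True)
class GeneratedDataset:
    r1_path: Path
    r2_path: Path
    truth_path: Path
    cells: tuple[tuple[str, str, str], ...]
    n_reads: int

    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# oracle: expected outcome from realized parts (independent of extract.py)
# ---------------------------------------------------------------------------


def _levenshtein(a: str, b: str) -> int:
    """Plain full-matrix Levenshtein distance ('N' matches nothing)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cost = 0 if (ca == cb and ca != "N") else 1
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost))
        prev = cur
    return prev[-1]


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N") + abs(len(a) - len(b))


_AMBIG = object()


def _classify_block(block: str, whitelist: BarcodeWhitelist, max_edits: int):
    """Exhaustive whitelist resolution (the test oracle for correction).

    Returns the unique entry, ``None`` (no match) or the ambiguity marker.
    """
    if block in whitelist:
        return block
    if max_edits == 0:
        return None
    hits = [e for e in whitelist if _levenshtein(block, e) <= max_edits]
    if len(hits) == 1:
        return hits[0]
    return None if not hits else _AMBIG


def _canonicalize_boundary(
    prev: str, link: str, nxt: str, canonical: str
) -> tuple[str, str, str]:
    """Re-assign boundary indels that leave the canonical linker intact.

    An insertion at a linker edge, or a deletion at the edge of a
    homopolymer run shared with the neighboring block, produces a read
    IDENTICAL to one with the edit in the adjacent barcode block; a
    positional extractor necessarily binds the exact linker occurrence.
    Classification must therefore depend on the sequence, not on which
    generative part was labelled as edited.
    """
    L = len(canonical)
    changed = True
    while changed:
        changed = False
        if len(link) > L:
            if link[:L] == canonical:
                nxt = link[L:] + nxt
                link = canonical
                changed = True
            elif link[-L:] == canonical:
                prev = prev + link[:-L]
                link = canonical
                changed = True
        elif len(link) == L - 1:
            if prev and prev[-1] + link == canonical:
                prev = prev[:-1]
                link = canonical
                changed = True
            elif nxt and link + nxt[0] == canonical:
                nxt = nxt[1:]
                link = canonical
                changed = True
    return prev, link, nxt


def expected_status(
    parts: ReadParts,
    cfg: ReadStructureConfig,
    whitelist: BarcodeWhitelist,
) -> tuple[str, str | None, str | None]:
    """Outcome the extraction contract mandates for a read built from ``parts``.

    Returns ``(status, expected_cell_barcode, expected_umi)`` where status
    is ``"valid"`` or an error-code string.  Derived purely from budget
    arithmetic on the realized parts (linker Levenshtein distance, linker
    spacing from part lengths, flanker mismatch counts at shifted
    coordinates, exhaustive whitelist neighborhoods) — no extraction code
    is involved, so this is an independent oracle.
    """
    k = cfg.barcode_len
    bc1, bc2, bc3 = parts.bc1, parts.bc2, parts.bc3
    bc1, l1_real, bc2 = _canonicalize_boundary(bc1, parts.linker1, bc2, cfg.linker1)
    bc2, l2_real, bc3 = _canonicalize_boundary(bc2, parts.linker2, bc3, cfg.linker2)
    parts = replace(parts, bc1=bc1, linker1=l1_real, bc2=bc2, linker2=l2_real, bc3=bc3)
    l1_d = _levenshtein(parts.linker1, cfg.linker1)
    l2_d = _levenshtein(parts.linker2, cfg.linker2)
    l1_ok = l1_d <= cfg.max_linker_edits
    l2_ok = l2_d <= cfg.max_linker_edits
    if not l1_ok and not l2_ok:
        return ErrorCode.LX.value, None, None
    if not l1_ok:
        return ErrorCode.L1.value, None, None
    if not l2_ok:
        return ErrorCode.L2.value, None, None

    gap = len(parts.linker1) + len(parts.bc2)
    if gap not in cfg.accepted_gaps:
        return ErrorCode.D.value, None, None
    prefix = parts.phase + parts.bc1
    if len(prefix) < cfg.min_l1_start:
        return ErrorCode.P.value, None, None

    downstream = (
        parts.bc3 + parts.flanker_pre + parts.umi + parts.flanker_post + parts.tail
    )
    pre_len = len(cfg.pre_umi_flanker)
    post_len = len(cfg.post_umi_flanker)
    need = k + pre_len + cfg.umi_len + post_len
    if len(downstream) < need:
        return ErrorCode.S.value, None, None
    pre_seen = downstream[k : k + pre_len]
    umi_seen = downstream[k + pre_len : k + pre_len + cfg.umi_len]
    post_seen = downstream[k + pre_len + cfg.umi_len : k + pre_len + cfg.umi_len + post_len]
    mism = _mismatches(pre_seen, cfg.pre_umi_flanker) + _mismatches(
        post_seen, cfg.post_umi_flanker
    )
    if mism > cfg.max_flanker_mismatches:
        return ErrorCode.T.value, None, None

    # BC1 mirrors the extractor's prefix-indel rescue: the standard window;
    # on NO match (never on ambiguity) the window shifted one base left,
    # then the k-1 window
    m1 = _classify_block(prefix[-k:], whitelist, cfg.max_barcode_edits)
    if m1 is None:
        for alt in (prefix[-k - 1 : -1] if len(prefix) >= k + 1 else "", prefix[-k + 1 :]):
            m_alt = _classify_block(alt, whitelist, cfg.max_barcode_edits) if alt else None
            if m_alt is not None and m_alt is not _AMBIG:
                m1 = m_alt
                break
    if m1 is None or m1 is _AMBIG:
        return ErrorCode.B.value, None, None
    corrected = [m1]
    for b in (parts.bc2, downstream[:k]):
        m = _classify_block(b, whitelist, cfg.max_barcode_edits)
        if m is None or m is _AMBIG:
            return ErrorCode.B.value, None, None
        corrected.append(m)
    return "valid", "".join(corrected), umi_seen


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


def _mutate(part: str, spec: ErrorSpec, rng: random.Random) -> tuple[str, list[int]]:
    positions: list[int] = []
    s = part
    if spec.kind == "substitution":
        if spec.position == "random":
            if spec.count > len(s):
                raise ValueError(f"cannot place {spec.count} substitutions in {s!r}")
            pos = sorted(rng.sample(range(len(s)), spec.count))
        else:
            pos = [int(spec.position)]
        out = list(s)
        for p in pos:
            out[p] = rng.choice([b for b in _BASES if b != out[p]])
        return "".join(out), pos
    for _ in range(spec.count):
        if spec.kind == "insertion":
            p = rng.randrange(len(s) + 1) if spec.position == "random" else int(spec.position)
            s = s[:p] + rng.choice(_BASES) + s[p:]
        else:  # deletion
            if not s:
                raise ValueError(f"cannot delete from empty part ({spec.target})")
            p = rng.randrange(len(s)) if spec.position == "random" else int(spec.position)
            s = s[:p] + s[p + 1 :]
        positions.append(p)
    return s, positions


def inject_errors(
    parts: ReadParts, specs: Sequence[ErrorSpec], rng: random.Random
) -> tuple[ReadParts, list[str]]:
    """Apply error specs to a read's parts; returns new parts + descriptions."""
    realized: list[str] = []
    for spec in specs:
        part = getattr(parts, spec.target)
        mutated, positions = _mutate(part, spec, rng)
        parts = replace(parts, **{spec.target: mutated})
        realized.append(
            f"{spec.target}:{spec.kind}:{'|'.join(map(str, positions))}"
        )
    return parts, realized


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _has_window_within(seq: str, pattern: str, max_edits: int) -> bool:
    """Brute-force scan: any substring of seq within ``max_edits`` of pattern."""
    m = len(pattern)
    for s in range(len(seq)):
        for span in range(m - max_edits, m + max_edits + 1):
            if s + span <= len(seq) and _levenshtein(seq[s : s + span], pattern) <= max_edits:
                return True
    return False


def _classifiable(parts: ReadParts, cfg: ReadStructureConfig) -> bool:
    """True unless an over-budget linker coincidentally left a lookalike.

    Multi-edit mutations of a linker occasionally recreate a window
    within the edit budget (e.g. two substitutions that mimic a single
    deletion); such reads are no longer over-budget reads at all, so the
    generator redraws them to keep each error class semantically clean.
    """
    seq = parts.sequence()
    for link, canonical in ((parts.linker1, cfg.linker1), (parts.linker2, cfg.linker2)):
        if _levenshtein(link, canonical) > cfg.max_linker_edits:
            if _has_window_within(seq, canonical, cfg.max_linker_edits):
                return False
    return True


def sample_cells(
    n_cells: int, whitelist: BarcodeWhitelist, rng: random.Random
) -> tuple[tuple[str, str, str], ...]:
    """Draw distinct (BC1, BC2, BC3) whitelist triples."""
    if n_cells > len(whitelist) ** 3:
        raise ValueError("n_cells exceeds the number of distinct barcode triples")
    entries = whitelist.entries
    cells: set[tuple[str, str, str]] = set()
    while len(cells) < n_cells:
        cells.add(
            (rng.choice(entries), rng.choice(entries), rng.choice(entries))
        )
    return tuple(sorted(cells))


def _open_gz(path: Path):
    # mtime pinned to 0 so identical seeds give byte-identical gzip output
    return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)


def generate_dataset(
    n_cells: int,
    reads_per_cell: int | tuple[int, int],
    out_dir,
    error_model: Mapping[ErrorSpec, float] | None = None,
    cfg: ReadStructureConfig | None = None,
    whitelist: BarcodeWhitelist | None = None,
    seed: int = 0,
    phase_range: tuple[int, int] = (1, 5),
    tail_len: int = 4,
    r2_len: int = 60,
    prefix: str = "sim",
) -> GeneratedDataset:
    """Generate paired FASTQ (gzip) plus a ground-truth TSV.

    Each cell is a distinct whitelist triple; each read gets a random
    phase block (uniform length over ``phase_range``), a random UMI and a
    random Read 2.  ``error_model`` maps :class:`ErrorSpec` to an
    independent per-read injection probability; realized errors and the
    oracle-expected status are recorded in the truth table.  Identical
    seeds give byte-identical outputs.
    """
    from surecell.readwrite import default_whitelist

    cfg = cfg or ReadStructureConfig()
    whitelist = whitelist or default_whitelist()
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1_path = out_dir / f"{prefix}_R1.fastq.gz"
    r2_path = out_dir / f"{prefix}_R2.fastq.gz"
    truth_path = out_dir / f"{prefix}_truth.tsv"

    cells = sample_cells(n_cells, whitelist, rng)
    specs = sorted(
        (error_model or {}).items(),
        key=lambda kv: (kv[0].target, kv[0].kind, str(kv[0].position), kv[0].count),
    )

    n_reads = 0
    with _open_gz(r1_path) as f1, _open_gz(r2_path) as f2, open(truth_path, "w") as ft:
        ft.write(
            "read_id\ttrue_cell_barcode\texpected_cell_barcode\texpected_umi"
            "\tphase_block_len\tinjected_errors\texpected_status\n"
        )
        for ci, cell in enumerate(cells):
            if isinstance(reads_per_cell, int):
                n = reads_per_cell
            else:
                n = rng.randint(reads_per_cell[0], reads_per_cell[1])
            for ri in range(n):
                read_id = f"sim:{ci:05d}:{ri:06d}"
                pb_len = rng.randint(*phase_range)
                parts = ReadParts.clean(
                    cell,
                    umi=_rand_seq(rng, cfg.umi_len),
                    phase=_rand_seq(rng, pb_len),
                    cfg=cfg,
                    tail=_rand_seq(rng, tail_len),
                )
                drawn = [s for s, p in specs if rng.random() < p]
                clean_parts = parts
                for _ in range(50):
                    parts, realized = inject_errors(clean_parts, drawn, rng)
                    if _classifiable(parts, cfg):
                        break
                status, exp_bc, exp_umi = expected_status(parts, cfg, whitelist)
                seq1 = parts.sequence()
                seq2 = _rand_seq(rng, r2_len)
                f1.write(
                    f"@{read_id}\n{seq1}\n+\n{'I' * len(seq1)}\n".encode()
                )
                f2.write(
                    f"@{read_id}\n{seq2}\n+\n{'I' * len(seq2)}\n".encode()
                )
                ft.write(
                    f"{read_id}\t{''.join(cell)}\t{exp_bc or ''}\t{exp_umi or ''}"
                    f"\t{pb_len}\t{';'.join(realized) or '-'}\t{status}\n"
                )
                n_reads += 1
    return GeneratedDataset(r1_path, r2_path, truth_path, cells, n_reads)


# ---------------------------------------------------------------------------
# analytic expectations for aggregate error-rate checks
# ---------------------------------------------------------------------------


def _p_block_unresolved(
    block: str, k_subs: int, whitelist: BarcodeWhitelist, cfg: ReadStructureConfig
) -> float:
    """P(no unique whitelist match) after k uniform substitutions on block."""
    bad = total = 0
    for pos in itertools.combinations(range(len(block)), k_subs):
        alt_sets = [[b for b in _BASES if b != block[p]] for p in pos]
        for alts in itertools.product(*alt_sets):
            mutated = list(block)
            for p, a in zip(pos, alts):
                mutated[p] = a
            total += 1
            res = _classify_block("".join(mutated), whitelist, cfg.max_barcode_edits)
            if res is None or res is _AMBIG:
                bad += 1
    return bad / total if total else 0.0


def expected_code_fractions(
    error_model: Mapping[ErrorSpec, float],
    cells: Sequence[tuple[str, str, str]],
    cfg: ReadStructureConfig,
    whitelist: BarcodeWhitelist,
) -> dict[str, float]:
    """Exact per-code outcome probabilities under an error model.

    Enumerates every subset of the (independent) error specs, applies the
    same budget arithmetic as :func:`expected_status`, and averages the
    content-dependent barcode branch over the realized cell blocks.
    Supports substitution specs anywhere plus indel specs on the linkers
    and BC2 (the classes whose outcome is position-independent).
    """
    specs = list(error_model.items())
    for spec, _ in specs:
        if spec.kind != "substitution" and spec.target not in (
            "linker1",
            "linker2",
            "bc2",
        ):
            raise ValueError(
                f"analytic expectation unsupported for {spec.target}:{spec.kind}"
            )
        if spec.target == "bc1" and spec.count > 1:
            # multi-edit BC1 blocks can engage the prefix-rescue windows,
            # whose outcome depends on phase-block content
            raise ValueError("analytic expectation unsupported for multi-edit bc1")
    # per-block P(unresolved | k subs), averaged over cells (equal read weights)
    block_cache: dict[tuple[int, int], float] = {}

    def p_unres(block_idx: int, k_subs: int) -> float:
        key = (block_idx, k_subs)
        if key not in block_cache:
            vals = [
                _p_block_unresolved(cell[block_idx], k_subs, whitelist, cfg)
                for cell in cells
            ]
            block_cache[key] = sum(vals) / len(vals)
        return block_cache[key]

    out = {c.value: 0.0 for c in ErrorCode}
    out["PASS"] = 0.0
    for mask in range(1 << len(specs)):
        prob = 1.0
        subset = []
        for i, (spec, p) in enumerate(specs):
            if mask >> i & 1:
                prob *= p
                subset.append(spec)
            else:
                prob *= 1.0 - p
        if prob == 0.0:
            continue
        l1_d = sum(s.count for s in subset if s.target == "linker1")
        l2_d = sum(s.count for s in subset if s.target == "linker2")
        l1_ok = l1_d <= cfg.max_linker_edits
        l2_ok = l2_d <= cfg.max_linker_edits
        if not l1_ok and not l2_ok:
            out["LX"] += prob
            continue
        if not l1_ok:
            out["L1"] += prob
            continue
        if not l2_ok:
            out["L2"] += prob
            continue
        delta = sum(
            (s.count if s.kind == "insertion" else -s.count)
            for s in subset
            if s.kind != "substitution" and s.target in ("linker1", "bc2")
        )
        if cfg.expected_linker_gap + delta not in cfg.accepted_gaps:
            out["D"] += prob
            continue
        flank = sum(
            s.count
            for s in subset
            if s.target in ("flanker_pre", "flanker_post")
        )
        if flank > cfg.max_flanker_mismatches:
            out["T"] += prob
            continue
        p_valid = 1.0
        for idx, name in enumerate(("bc1", "bc2", "bc3")):
            k_subs = sum(
                s.count for s in subset if s.target == name and s.kind == "substitution"
            )
            if k_subs:
                p_valid *= 1.0 - p_unres(idx, min(k_subs, cfg.barcode_len))
        out["PASS"] += prob * p_valid
        out["B"] += prob * (1.0 - p_valid)
    return out


def simulate_count_table(
    n_cells: int,
    reads_per_cell: int,
    noise_barcodes: int,
    noise_reads: tuple[int, int],
    whitelist: BarcodeWhitelist | None = None,
    seed: int = 0,
) -> BarcodeCountTable:
    """Simulate a per-cell valid-read count table for cell-calling checks.

    ``n_cells`` real cells receive ``reads_per_cell`` reads each;
    ``noise_barcodes`` ambient barcodes receive a uniform count drawn
    from ``noise_reads``.  All barcodes are distinct whitelist triples.
    """
    from surecell.readwrite import default_whitelist

    whitelist = whitelist or default_whitelist()
    rng = random.Random(seed)
    triples = sample_cells(n_cells + noise_barcodes, whitelist, rng)
    order = list(triples)
    rng.shuffle(order)
    counts: dict[str, int] = {}
    for i, cell in enumerate(order):
        bc = "".join(cell)
        if i < n_cells:
            counts[bc] = reads_per_cell
        else:
            counts[bc] = rng.randint(*noise_reads)
    return BarcodeCountTable(counts)
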