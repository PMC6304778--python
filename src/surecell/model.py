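"""Domain types shared across the package.

The Bio-Rad ddSEQ / Illumina SureCell library puts all molecular tags on
Read 1, laid out as::

    [phase block] BC1 [linker 1] BC2 [linker 2] BC3 ACG [UMI] GAC ...

The phase block has variable length, so nothing in the read is at a fixed
offset: the two 15-nt linkers are the positional anchors from which the
three 6-nt barcode blocks and the UMI are recovered.  The types here are
the vocabulary of that recovery: the declarative read anatomy
(:class:`ReadStructureConfig`), an approximate linker match
(:class:`LinkerHit`), the per-read outcome (:class:`TagResult`), the
closed error taxonomy (:class:`ErrorCode`), the barcode-block whitelist
(:class:`BarcodeWhitelist`) and the per-cell valid-read count table
(:class:`BarcodeCountTable`).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

_DNA = frozenset("ACGT")

#: Two-letter tags predefined by the SAM specification; user tag schemes
#: must not collide with these.
RESERVED_BAM_TAGS = frozenset(
    """AM AS BC BQ BZ CB CC CG CM CO CP CQ CR CS CT CY E2 FI FS FZ GC GQ GS
    H0 H1 H2 HI IH LB MC MD MF MI MQ NH NM OA OC OP OQ OX PG PQ PT PU Q2 QT
    QX R2 RG RT RX S2 SA SM SQ TC TS U2 UQ""".split()
)
# CB/CR/CY/UB... are "predefined" but routinely used as cell/UMI tags by
# droplet pipelines; allow the ones whose predefined meaning IS cell/UMI.
_ALLOWED_PREDEFINED = frozenset({"CB", "CR", "BC", "RX", "OX", "MI"})


class ErrorCode(str, enum.Enum):
    """Why a read failed tag extraction (written to the error BAM tag).

    Exactly one code is assigned to each invalid read; precedence is
    LX > L1 > L2 > D > P > S > T > B, i.e. structural failures mask
    content failures.
    """

    L1 = "L1"  #: linker 1 not located within the edit budget
    L2 = "L2"  #: linker 2 not located within the edit budget
    LX = "LX"  #: neither linker located
    D = "D"    #: linker-to-linker spacing outside the accepted set
    P = "P"    #: linker 1 starts too close to the read start
    S = "S"    #: read too short to contain the downstream structure
    T = "T"    #: UMI flanker trinucleotides exceed the mismatch budget
    B = "B"    #: a barcode block has no unique whitelist match

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Error precedence, highest first.  One code per read.
ERROR_PRECEDENCE = (
    ErrorCode.LX,
    ErrorCode.L1,
    ErrorCode.L2,
    ErrorCode.D,
    ErrorCode.P,
    ErrorCode.S,
    ErrorCode.T,
    ErrorCode.B,
)


def _check_dna(name: str, seq: str) -> None:
    if not seq or not set(seq) <= _DNA:
        raise ValueError(f"{name} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class ReadStructureConfig:
    """Declarative anatomy of Read 1.

    Defaults describe the SureCell WTA 3' chemistry: three 6-nt barcode
    blocks separated by two distinct 15-nt linkers, an 8-nt UMI bracketed
    by the trinucleotides ACG and GAC, and a >=1-nt phase block so linker 1
    can start no earlier than offset 7.  The linker sequences themselves
    are configuration (load alternates with :func:`load_structure`).
    """

    linker1: str = "TAGCCATCGCATTGC"
    linker2: str = "TACCTCTGAGCTGAA"
    barcode_len: int = 6
    umi_len: int = 8
    pre_umi_flanker: str = "ACG"
    post_umi_flanker: str = "GAC"
    expected_linker_gap: int = 21
    min_l1_start: int = 7
    max_linker_edits: int = 1
    max_flanker_mismatches: int = 1
    max_barcode_edits: int = 1
    strict_gap: bool = False

    def __post_init__(self) -> None:
        _check_dna("linker1", self.linker1)
        _check_dna("linker2", self.linker2)
        _check_dna("pre_umi_flanker", self.pre_umi_flanker)
        _check_dna("post_umi_flanker", self.post_umi_flanker)
        if self.linker1 == self.linker2:
            raise ValueError("linker1 and linker2 must differ")
        if self.barcode_len < 1 or self.umi_len < 1:
            raise ValueError("barcode_len and umi_len must be positive")
        if self.min_l1_start < self.barcode_len + 1:
            raise ValueError(
                "min_l1_start must leave room for BC1 plus a >=1-nt phase block"
            )
        if self.expected_linker_gap != self.barcode_len + len(self.linker1):
            raise ValueError(
                "expected_linker_gap must equal barcode_len + len(linker1) "
                f"({self.barcode_len + len(self.linker1)}), got "
                f"{self.expected_linker_gap}"
            )
        if self.max_linker_edits not in (0, 1) or self.max_barcode_edits not in (0, 1):
            raise ValueError("edit budgets are limited to 0 or 1")
        if self.max_flanker_mismatches < 0:
            raise ValueError("max_flanker_mismatches must be >= 0")

    @property
    def accepted_gaps(self) -> frozenset[int]:
        """Accepted linker start-to-start distances.

        The nominal spacing is ``barcode_len + len(linker1)`` (21 nt for the
        defaults); +/-1 is accepted unless ``strict_gap`` because a single
        indel inside linker 1 or BC2 shifts the spacing by one base.
        """
        g = self.expected_linker_gap
        if self.strict_gap:
            return frozenset({g})
        return frozenset({g - 1, g, g + 1})

    @property
    def cell_barcode_len(self) -> int:
        return 3 * self.barcode_len


class EditType(str, enum.Enum):
    EXACT = "exact"
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"


#: tie-break priority among equal-distance interpretations at one offset
EDIT_TYPE_RANK = {
    EditType.EXACT: 0,
    EditType.SUBSTITUTION: 1,
    EditType.DELETION: 2,
    EditType.INSERTION: 3,
}


@dataclass(frozen=True)
class LinkerHit:
    """One approximate occurrence of a linker inside Read 1.

    ``start``/``end`` are 0-based, end-exclusive offsets into the read.
    A deletion hit (one linker base missing from the read) spans
    ``len(linker) - 1`` read bases; an insertion hit spans
    ``len(linker) + 1``.
    """

    start: int
    end: int
    edit_distance: int
    edit_type: EditType

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("invalid hit span")
        if (self.edit_distance == 0) != (self.edit_type is EditType.EXACT):
            raise ValueError("edit_distance 0 iff edit_type exact")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TagResult:
    """Outcome of tag extraction for one read pair."""

    read_id: str
    cell_barcode: str | None = None
    umi: str | None = None
    error_code: ErrorCode | None = None

    def __post_init__(self) -> None:
        if self.error_code is None:
            if not self.cell_barcode or not self.umi:
                raise ValueError("valid result requires cell_barcode and umi")
        else:
            if self.cell_barcode is not None or self.umi is not None:
                raise ValueError("invalid result must not carry barcode or umi")

    @property
    def is_valid(self) -> bool:
        return self.error_code is None


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: returned by whitelist lookup when no entry lies within the edit budget
NO_MATCH = _Sentinel("NO_MATCH")
#: returned when more than one entry lies within the edit budget
AMBIGUOUS = _Sentinel("AMBIGUOUS")


def _eq(a: str, b: str) -> bool:
    # 'N' never matches anything, including itself
    return a == b and a != "N"


def hamming1_or_less(a: str, b: str) -> int | None:
    """Hamming distance of equal-length strings if <= 1, else None."""
    d = 0
    for x, y in zip(a, b):
        if not _eq(x, y):
            d += 1
            if d > 1:
                return None
    return d


def within_one_edit(query: str, target: str) -> int | None:
    """Levenshtein distance between query and target if <= 1, else None.

    'N' in either string matches nothing.  Only length differences of at
    most one can be within a single edit.
    """
    la, lb = len(query), len(target)
    if la == lb:
        return hamming1_or_less(query, target)
    if abs(la - lb) != 1:
        return None
    if la > lb:
        query, target = target, query
        la, lb = lb, la
    # query is one shorter: allow a single gap
    i = 0
    while i < la and _eq(query[i], target[i]):
        i += 1
    while i < la:
        if not _eq(query[i], target[i + 1]):
            return None
        i += 1
    return 1


class BarcodeWhitelist:
    """Set of valid barcode blocks with exact and 1-edit unique lookup.

    Lookup semantics follow the extraction contract: an exact member is
    returned as-is; otherwise the unique entry within Levenshtein
    distance <= ``max_edits`` is returned; multiple candidates yield
    :data:`AMBIGUOUS`, none yield :data:`NO_MATCH`.
    """

    def __init__(self, entries: Iterable[str]) -> None:
        entries = [e.strip().upper() for e in entries]
        entries = [e for e in entries if e]
        if not entries:
            raise ValueError("whitelist is empty")
        length = len(entries[0])
        seen = set()
        for e in entries:
            if len(e) != length:
                raise ValueError(f"whitelist entries differ in length: {e!r}")
            _check_dna("whitelist entry", e)
            if e in seen:
                raise ValueError(f"duplicate whitelist entry {e!r}")
            seen.add(e)
        self._entries = tuple(entries)
        self._set = seen
        self.entry_len = length

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, block: str) -> bool:
        return block in self._set

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    @property
    def entries(self) -> tuple[str, ...]:
        return self._entries

    def lookup(self, block: str, max_edits: int = 1):
        """Resolve ``block`` to a whitelist entry, NO_MATCH or AMBIGUOUS."""
        block = block.upper()
        if block in self._set:
            return block
        if max_edits == 0:
            return NO_MATCH
        found = None
        for entry in self._entries:
            if within_one_edit(block, entry) is not None:
                if found is not None:
                    return AMBIGUOUS
                found = entry
        return found if found is not None else NO_MATCH

    @classmethod
    def from_file(cls, path) -> "BarcodeWhitelist":
        """Load a plain-text whitelist: one barcode per line, '#' comments."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    entries.append(line)
        return cls(entries)


class BarcodeCountTable:
    """Per-cell-barcode valid-read counts, sorted by count descending.

    Ties are broken lexicographically by barcode so the table (and every
    file derived from it) is deterministic.
    """

    def __init__(self, counts: Mapping[str, int]) -> None:
        for bc, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for {bc!r}")
        self._rows = tuple(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )

    @property
    def rows(self) -> tuple[tuple[str, int], ...]:
        return self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    @property
    def total(self) -> int:
        return sum(n for _, n in self._rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=["barcode", "count"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BarcodeCountTable":
        return cls(dict(zip(df["barcode"], df["count"])))


_TAG_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]$")


@dataclass(frozen=True)
class TagScheme:
    """Names of the BAM auxiliary tags carrying cell barcode, UMI and error.

    The default mirrors Drop-seq tools (XC/XM) plus XE for the error code;
    alternates such as CB/UB suit CellRanger-style downstream tools.
    """

    cell_tag: str = "XC"
    umi_tag: str = "XM"
    error_tag: str = "XE"

    def __post_init__(self) -> None:
        names = (self.cell_tag, self.umi_tag, self.error_tag)
        for t in names:
            if not _TAG_RE.match(t):
                raise ValueError(f"invalid BAM tag name {t!r}")
            if t in RESERVED_BAM_TAGS and t not in _ALLOWED_PREDEFINED:
                raise ValueError(f"tag {t!r} collides with a reserved BAM tag")
        if len(set(names)) != 3:
            raise ValueError("cell, umi and error tags must be distinct")

    @classmethod
    def parse(cls, spec: str) -> "TagScheme":
        """Parse ``cell=CB,umi=UB,error=XE`` (missing keys keep defaults)."""
        kwargs = {}
        key_map = {"cell": "cell_tag", "umi": "umi_tag", "error": "error_tag"}
        for item in spec.split(","):
            item = item.strip()
            if not item:
                continue
            if "=" not in item:
                raise ValueError(f"bad tag-scheme item {item!r}")
            k, v = item.split("=", 1)
            k = k.strip().lower()
            if k not in key_map:
                raise ValueError(f"unknown tag-scheme key {k!r}")
            kwargs[key_map[k]] = v.strip()
        return cls(**kwargs)
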