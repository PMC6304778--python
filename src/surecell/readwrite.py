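"""File formats: paired FASTQ in, tagged unmapped BAM and TSV tables out.

FASTQ reading goes through :class:`pysam.FastxFile` (gzip-transparent);
BAM writing through :class:`pysam.AlignmentFile`.  The unmapped BAM is the
hand-off container to downstream aligners: every record carries Read 2's
sequence and qualities, flag 4, no reference, and either the cell/UMI
tags (valid reads) or the error tag (invalid reads).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator

import pysam

from surecell.model import (
    BarcodeCountTable,
    ReadStructureConfig,
    BarcodeWhitelist,
    TagResult,
    TagScheme,
)

__all__ = [
    "FastqPairError",
    "read_pairs",
    "write_tagged_bam",
    "write_barcode_counts",
    "load_whitelist",
    "default_whitelist",
    "load_structure",
]


class FastqPairError(ValueError):
    """Paired FASTQ files disagree (record counts or read identifiers)."""


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str


def _core_id(name: str) -> str:
    # drop a /1 or /2 mate suffix; pysam already strips the comment field
    if len(name) > 1 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def read_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream synchronized (R1, R2) records from two FASTQ files.

    Sequences are uppercased; quality strings are passed through
    verbatim.  Raises :class:`FastqPairError` at the first position where
    the files fall out of step (unequal record counts or mismatched ids).
    """
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        it1, it2 = iter(f1), iter(f2)
        idx = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            idx += 1
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = r1_path if rec1 is None else r2_path
                raise FastqPairError(
                    f"record counts differ: {short} ends before pair {idx}"
                )
            id1, id2 = _core_id(rec1.name), _core_id(rec2.name)
            if id1 != id2:
                raise FastqPairError(
                    f"read ids disagree at pair {idx}: {id1!r} vs {id2!r}"
                )
            yield ReadPair(
                id1,
                rec1.sequence.upper(),
                rec1.quality or "",
                rec2.sequence.upper(),
                rec2.quality or "",
            )


def _bam_header(scheme: TagScheme) -> dict:
    from surecell import __version__

    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "PG": [
            {
                "ID": "surecell",
                "PN": "surecell",
                "VN": __version__,
                "CL": " ".join(sys.argv) or "surecell",
            }
        ],
        "CO": [
            f"tag scheme: cell={scheme.cell_tag} umi={scheme.umi_tag} "
            f"error={scheme.error_tag}"
        ],
    }


def write_tagged_bam(
    results: Iterable[tuple[TagResult, str, str]],
    out_path,
    scheme: TagScheme = TagScheme(),
    drop_invalid: bool = False,
) -> int:
    """Write one unmapped BAM record per (TagResult, r2_seq, r2_qual).

    Valid reads carry the cell and UMI tags; invalid reads carry the
    error tag and neither of the others (or are skipped entirely when
    ``drop_invalid``).  Returns the number of records written.
    """
    n = 0
    with pysam.AlignmentFile(str(out_path), "wb", header=_bam_header(scheme)) as bam:
        for result, r2_seq, r2_qual in results:
            if drop_invalid and not result.is_valid:
                continue
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = result.read_id
            rec.flag = 4  # unmapped
            rec.reference_id = -1
            rec.reference_start = -1
            rec.mapping_quality = 0
            rec.next_reference_id = -1
            rec.next_reference_start = -1
            rec.query_sequence = r2_seq
            if r2_qual:
                rec.qual = r2_qual
            if result.is_valid:
                rec.set_tag(scheme.cell_tag, result.cell_barcode, "Z")
                rec.set_tag(scheme.umi_tag, result.umi, "Z")
            else:
                rec.set_tag(scheme.error_tag, result.error_code.value, "Z")
            bam.write(rec)
            n += 1
    return n


def write_barcode_counts(
    table: BarcodeCountTable, out_path, header: bool = False
) -> None:
    """Write the per-cell valid-read counts as two-column TSV.

    Rows come pre-sorted from the table (count descending, barcode
    ascending among ties); no header unless requested.
    """
    with open(out_path, "w") as fh:
        if header:
            fh.write("barcode\tcount\n")
        for bc, n in table:
            fh.write(f"{bc}\t{n}\n")


def load_whitelist(path=None) -> BarcodeWhitelist:
    """Load a barcode-block whitelist; packaged default when path is None."""
    if path is None:
        return default_whitelist()
    return BarcodeWhitelist.from_file(path)


def default_whitelist() -> BarcodeWhitelist:
    """The packaged synthetic 96-block whitelist (pairwise distance >= 3)."""
    ref = resources.files("surecell.data").joinpath("whitelist96_synthetic.txt")
    with resources.as_file(ref) as path:
        return BarcodeWhitelist.from_file(path)


_BOOL_KEYS = {"strict_gap"}
_INT_KEYS = {
    "barcode_len",
    "umi_len",
    "expected_linker_gap",
    "min_l1_start",
    "max_linker_edits",
    "max_flanker_mismatches",
    "max_barcode_edits",
}
_STR_KEYS = {"linker1", "linker2", "pre_umi_flanker", "post_umi_flanker"}


def load_structure(path=None, **overrides) -> ReadStructureConfig:
    """Build a read-structure config from a key=value text file.

    All keys are optional; anything absent keeps the SureCell default.
    '#' starts a comment.  Keyword overrides win over the file.
    """
    kwargs: dict = {}
    if path is not None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key in _INT_KEYS:
                    kwargs[key] = int(value)
                elif key in _BOOL_KEYS:
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                elif key in _STR_KEYS:
                    kwargs[key] = value.upper()
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    kwargs.update(overrides)
    return ReadStructureConfig(**kwargs)
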