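"""End-to-end demultiplexing: paired FASTQ -> tagged unmapped BAM + QC.

The pipeline streams read pairs, runs tag extraction on Read 1, writes
every pair as one unmapped BAM record (Read 2 sequence, cell/UMI tags or
the error tag), and accumulates the QC counters as it goes.  With
``cores > 1`` extraction runs on chunks in a process pool; chunks are
consumed in submission order, so output is identical to a single-core
run.
"""

from __future__ import annotations

import itertools
import json
import multiprocessing
from dataclasses import dataclass

import pysam

from surecell.extract import extract_tags
from surecell.model import (
    BarcodeCountTable,
    BarcodeWhitelist,
    ReadStructureConfig,
    TagResult,
    TagScheme,
)
from surecell.qc import (
    cumulative_curve,
    error_distribution_from_counts,
    knee_estimate,
)
from surecell.readwrite import read_pairs, write_barcode_counts, _bam_header

__all__ = ["demux", "DemuxReport"]

_CHUNK = 2000

# worker globals, set once per pool process
_W_CFG: ReadStructureConfig | None = None
_W_WL: BarcodeWhitelist | None = None


def _init_worker(cfg: ReadStructureConfig, whitelist: BarcodeWhitelist) -> None:
    global _W_CFG, _W_WL
    _W_CFG, _W_WL = cfg, whitelist


def _extract_chunk(chunk: list[tuple[str, str]]) -> list[TagResult]:
    return [extract_tags(seq, _W_CFG, _W_WL, read_id) for read_id, seq in chunk]


@dataclass
class DemuxReport:
    """One-screen summary of a demultiplexing run."""

    total_pairs: int
    valid: int
    bam_records: int
    code_counts: dict[str, int]
    knee_cells: int | None = None

    @property
    def pass_fraction(self) -> float:
        return self.valid / self.total_pairs if self.total_pairs else 0.0

    def to_json(self) -> str:
        payload = {
            "total_pairs": self.total_pairs,
            "valid": self.valid,
            "pass_fraction": self.pass_fraction,
            "bam_records": self.bam_records,
            "code_counts": self.code_counts,
            "knee_cells": self.knee_cells,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def render(self) -> str:
        lines = [
            f"read pairs        {self.total_pairs}",
            f"valid (PASS)      {self.valid} ({100 * self.pass_fraction:.2f}%)",
            f"BAM records       {self.bam_records}",
        ]
        total = self.total_pairs or 1
        for code, n in sorted(self.code_counts.items()):
            if code != "PASS":
                lines.append(f"  {code:<4}            {n} ({100 * n / total:.2f}%)")
        if self.knee_cells is not None:
            lines.append(f"knee cell estimate {self.knee_cells}")
        return "\n".join(lines)


def _chunked(iterable, size):
    it = iter(iterable)
    while chunk := list(itertools.islice(it, size)):
        yield chunk


def demux(
    r1_path,
    r2_path,
    out_bam,
    whitelist: BarcodeWhitelist,
    cfg: ReadStructureConfig | None = None,
    scheme: TagScheme = TagScheme(),
    summary_prefix: str | None = None,
    drop_invalid: bool = False,
    cores: int = 1,
    top_n: int = 5000,
) -> DemuxReport:
    """Run the full pipeline; returns the run report.

    Writes the tagged BAM and, when ``summary_prefix`` is given, the
    three QC TSVs (error distribution, per-cell valid-read counts,
    cumulative curve) plus the report as ``<prefix>_report.json``.
    """
    import pandas as pd

    cfg = cfg or ReadStructureConfig()
    code_counts: dict[str, int] = {}
    barcode_counts: dict[str, int] = {}
    total = written = valid = 0

    pairs = read_pairs(r1_path, r2_path)
    pool = None
    try:
        with pysam.AlignmentFile(str(out_bam), "wb", header=_bam_header(scheme)) as bam:

            def emit(result: TagResult, r2_seq: str, r2_qual: str) -> None:
                nonlocal written, valid
                if result.is_valid:
                    valid += 1
                    code_counts["PASS"] = code_counts.get("PASS", 0) + 1
                    barcode_counts[result.cell_barcode] = (
                        barcode_counts.get(result.cell_barcode, 0) + 1
                    )
                else:
                    code = result.error_code.value
                    code_counts[code] = code_counts.get(code, 0) + 1
                    if drop_invalid:
                        return
                rec = pysam.AlignedSegment(bam.header)
                rec.query_name = result.read_id
                rec.flag = 4
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
                written += 1

            if cores <= 1:
                for pair in pairs:
                    total += 1
                    result = extract_tags(pair.r1_seq, cfg, whitelist, pair.read_id)
                    emit(result, pair.r2_seq, pair.r2_qual)
            else:
                pool = multiprocessing.Pool(
                    cores, initializer=_init_worker, initargs=(cfg, whitelist)
                )
                chunks = _chunked(pairs, _CHUNK)

                def r1_view():
                    for chunk in chunks:
                        yield chunk

                # keep the R2 halves in step with the submitted chunks
                pending: list[list] = []

                def submit_view():
                    for chunk in r1_view():
                        pending.append([(p.r2_seq, p.r2_qual) for p in chunk])
                        yield [(p.read_id, p.r1_seq) for p in chunk]

                for results in pool.imap(_extract_chunk, submit_view()):
                    r2_half = pending.pop(0)
                    for result, (r2_seq, r2_qual) in zip(results, r2_half):
                        total += 1
                        emit(result, r2_seq, r2_qual)
    finally:
        if pool is not None:
            pool.close()
            pool.join()

    report = DemuxReport(
        total_pairs=total,
        valid=valid,
        bam_records=written,
        code_counts=dict(sorted(code_counts.items())),
    )
    table = BarcodeCountTable(barcode_counts)
    if len(table) >= 3:
        report.knee_cells = knee_estimate(table, top_n=top_n)
    if summary_prefix:
        error_distribution_from_counts(code_counts).to_csv(
            f"{summary_prefix}_error_distribution.tsv", sep="\t", index=False
        )
        write_barcode_counts(table, f"{summary_prefix}_barcode_counts.tsv")
        pd.DataFrame(
            cumulative_curve(table, top_n=top_n),
            columns=["rank", "cumulative_fraction"],
        ).to_csv(f"{summary_prefix}_cumulative.tsv", sep="\t", index=False)
        with open(f"{summary_prefix}_report.json", "w") as fh:
            fh.write(report.to_json() + "\n")
    return report
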