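"""Run-level quality metrics: error-tag distribution, reads-per-barcode
counts, cumulative fraction curves and knee-based cell-number estimation.

All tables are plain pandas DataFrames written as TSV so they are easy to
diff, plot, or consume from R.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from surecell.model import BarcodeCountTable, ErrorCode, TagResult

__all__ = [
    "error_distribution",
    "error_distribution_from_counts",
    "count_valid_reads",
    "cumulative_curve",
    "knee_estimate",
    "write_qc_tables",
    "plot_qc",
]

#: row order of the error-distribution table
CODES_WITH_PASS = ("PASS",) + tuple(c.value for c in ErrorCode)


def error_distribution_from_counts(code_counts) -> pd.DataFrame:
    """Build the outcome table from a {code: count} mapping (PASS included)."""
    unknown = set(code_counts) - set(CODES_WITH_PASS)
    if unknown:
        raise ValueError(f"unknown outcome codes {sorted(unknown)}")
    counts = {c: int(code_counts.get(c, 0)) for c in CODES_WITH_PASS}
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "code": CODES_WITH_PASS,
            "count": [counts[c] for c in CODES_WITH_PASS],
            "fraction": [counts[c] / total if total else 0.0 for c in CODES_WITH_PASS],
        }
    )


def error_distribution(results: Iterable[TagResult]) -> pd.DataFrame:
    """Count outcomes per category (PASS plus every error code).

    Returns a DataFrame with columns ``code``, ``count``, ``fraction``;
    all codes appear even at zero count, and fractions sum to one (all
    zero for an empty stream).
    """
    counts: dict[str, int] = {}
    for r in results:
        key = "PASS" if r.is_valid else r.error_code.value
        counts[key] = counts.get(key, 0) + 1
    return error_distribution_from_counts(counts)


def count_valid_reads(results: Iterable[TagResult]) -> BarcodeCountTable:
    """Tally valid reads per 18-nt cell barcode."""
    counts: dict[str, int] = {}
    for r in results:
        if r.is_valid:
            counts[r.cell_barcode] = counts.get(r.cell_barcode, 0) + 1
    return BarcodeCountTable(counts)


def cumulative_curve(
    table: BarcodeCountTable, top_n: int = 5000
) -> list[tuple[int, float]]:
    """Cumulative fraction of valid reads in the ``top_n`` most-read barcodes.

    Fractions are of the TOTAL valid reads, so the curve reaches 1 only
    when ``top_n`` covers every barcode.  Empty table gives an empty list.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(table) == 0:
        return []
    total = table.total
    out = []
    cum = 0
    for rank, (_, n) in enumerate(table.rows[:top_n], start=1):
        cum += n
        out.append((rank, cum / total))
    return out


def knee_estimate(table: BarcodeCountTable, top_n: int = 5000) -> int:
    """Estimate the number of real cells from the ranked count curve.

    Builds the cumulative-fraction curve over ranks 1..top_n (flat at the
    final fraction beyond the last observed barcode), normalizes both
    axes to [0, 1], and returns the rank at maximal perpendicular
    distance from the chord joining the curve's endpoints.  Ties go to
    the smaller rank; a perfectly straight curve therefore returns 1.
    Deterministic and invariant to uniform scaling of the counts.
    """
    if len(table) < 3:
        raise ValueError("knee estimation needs at least 3 distinct barcodes")
    curve = cumulative_curve(table, top_n=top_n)
    fracs = np.array([f for _, f in curve], dtype=float)
    if top_n > len(fracs):
        fracs = np.concatenate([fracs, np.full(top_n - len(fracs), fracs[-1])])
    n = len(fracs)
    x = np.arange(1, n + 1, dtype=float)
    # normalize both axes so rank span and fraction span weigh equally
    x = (x - x[0]) / (x[-1] - x[0])
    y0, y1 = fracs[0], fracs[-1]
    y = (fracs - y0) / (y1 - y0) if y1 > y0 else np.zeros(n)
    # perpendicular distance to the chord from (0,0) to (1,1) direction
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * x - dx * y) / float(np.hypot(dx, dy))
    # ties (within float noise of the maximum) go to the smallest rank
    return int(np.argmax(dist >= dist.max() - 1e-12)) + 1


def write_qc_tables(
    results: Sequence[TagResult], prefix: str, top_n: int = 5000
) -> dict[str, str]:
    """Write the three QC TSVs for a finished run.

    Produces ``<prefix>_error_distribution.tsv``,
    ``<prefix>_barcode_counts.tsv`` and ``<prefix>_cumulative.tsv``;
    returns the paths keyed by table name.
    """
    from surecell.readwrite import write_barcode_counts

    paths = {
        "error_distribution": f"{prefix}_error_distribution.tsv",
        "barcode_counts": f"{prefix}_barcode_counts.tsv",
        "cumulative": f"{prefix}_cumulative.tsv",
    }
    error_distribution(results).to_csv(paths["error_distribution"], sep="\t", index=False)
    table = count_valid_reads(results)
    write_barcode_counts(table, paths["barcode_counts"])
    pd.DataFrame(
        cumulative_curve(table, top_n=top_n), columns=["rank", "cumulative_fraction"]
    ).to_csv(paths["cumulative"], sep="\t", index=False)
    return paths


def plot_qc(table: BarcodeCountTable, dist: pd.DataFrame, out_path, top_n: int = 5000):
    """Render the three QC panels (error dot plot, reads/barcode, cumulative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].scatter(dist["code"], 100 * dist["fraction"])
    axes[0].set_ylabel("% of reads")
    axes[0].set_title("outcome distribution")
    ranks = np.arange(1, min(top_n, len(table)) + 1)
    counts = [n for _, n in table.rows[: len(ranks)]]
    if len(ranks):
        axes[1].plot(ranks, counts)
        axes[1].set_yscale("log")
    axes[1].set_xlabel("barcode rank")
    axes[1].set_ylabel("valid reads")
    axes[1].set_title("reads per barcode")
    curve = cumulative_curve(table, top_n=top_n) if len(table) else []
    if curve:
        axes[2].plot([r for r, _ in curve], [f for _, f in curve])
        knee = knee_estimate(table, top_n=top_n) if len(table) >= 3 else None
        if knee is not None:
            axes[2].axvline(knee, ls="--", color="grey")
    axes[2].set_xlabel("barcode rank")
    axes[2].set_ylabel("cumulative fraction")
    axes[2].set_title("cumulative reads per cell")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
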