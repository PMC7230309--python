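"""Per-run quality control and the three-threshold sample filter.

A streamed prefix of a run is kept for the expression matrix only if the
quantifier mapped enough of it: at least a minimum absolute number of reads
pseudoaligned, a minimum percentage of processed reads pseudoaligned, and a
minimum percentage of genes with nonzero TPM.  All thresholds are inclusive
("at least").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .quantification import AbundanceTable, RunStats

__all__ = [
    "QCRecord",
    "QCThresholds",
    "compute_qc",
    "apply_filter",
    "passes",
    "qc_scatter_data",
    "write_qc_report",
    "read_qc_report",
]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive lower bounds a run must meet to pass QC.

    Defaults: one million reads pseudoaligned, 40% of processed reads
    mapped, 40% of genes with nonzero expression.
    """

    min_pseudoaligned: int = 1_000_000
    min_pct_mapped: float = 40.0
    min_pct_nonzero: float = 40.0

    def __post_init__(self) -> None:
        if self.min_pseudoaligned < 0:
            raise ValueError("min_pseudoaligned must be >= 0")
        for name in ("min_pct_mapped", "min_pct_nonzero"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100]")


@dataclass(frozen=True)
class QCRecord:
    accession: str
    n_processed: int
    n_pseudoaligned: int
    pct_pseudoaligned: float
    pct_genes_nonzero: float
    passed: bool | None = None

    def __post_init__(self) -> None:
        for name in ("pct_pseudoaligned", "pct_genes_nonzero"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


def compute_qc(accession: str, stats: RunStats,
               abundance: AbundanceTable) -> QCRecord:
    """QC statistics for one run (verdict left unset).

    ``pct_pseudoaligned`` is computed from the quantifier's processed-read
    count (not streamed bytes); ``pct_genes_nonzero`` uses strict tpm > 0.
    """
    n_genes = len(abundance.ids)
    if n_genes == 0:
        raise ValueError(f"empty abundance table for {accession}")
    pct_mapped = (100.0 * stats.n_pseudoaligned / stats.n_processed
                  if stats.n_processed else 0.0)
    pct_nonzero = 100.0 * float(np.count_nonzero(abundance.tpm > 0)) / n_genes
    return QCRecord(
        accession=accession,
        n_processed=stats.n_processed,
        n_pseudoaligned=stats.n_pseudoaligned,
        pct_pseudoaligned=pct_mapped,
        pct_genes_nonzero=pct_nonzero,
    )


def passes(record: QCRecord, thresholds: QCThresholds) -> bool:
    return (record.n_pseudoaligned >= thresholds.min_pseudoaligned
            and record.pct_pseudoaligned >= thresholds.min_pct_mapped
            and record.pct_genes_nonzero >= thresholds.min_pct_nonzero)


def apply_filter(
    records: list[QCRecord], thresholds: QCThresholds
) -> tuple[list[QCRecord], list[QCRecord]]:
    """Partition records into (pass, fail) lists, order preserved.

    Returned records carry the verdict in ``passed``.
    """
    passed_list: list[QCRecord] = []
    failed_list: list[QCRecord] = []
    for rec in records:
        verdict = passes(rec, thresholds)
        stamped = QCRecord(
            accession=rec.accession,
            n_processed=rec.n_processed,
            n_pseudoaligned=rec.n_pseudoaligned,
            pct_pseudoaligned=rec.pct_pseudoaligned,
            pct_genes_nonzero=rec.pct_genes_nonzero,
            passed=verdict,
        )
        (passed_list if verdict else failed_list).append(stamped)
    return passed_list, failed_list


def qc_scatter_data(records: list[QCRecord],
                    thresholds: QCThresholds | None = None) -> dict:
    """Plot-ready data for the two QC scatter panels.

    Panel one: percent of reads pseudoaligned vs. total processed reads.
    Panel two: percent pseudoaligned vs. percent of genes with nonzero TPM.
    Guide-lines mark the filter cutoffs; rendering is left to the caller.
    """
    if not records:
        raise ValueError("no QC records to plot")
    thresholds = thresholds or QCThresholds()
    return {
        "reads_vs_mapped": {
            "accession": [r.accession for r in records],
            "pct_pseudoaligned": [r.pct_pseudoaligned for r in records],
            "n_processed": [r.n_processed for r in records],
        },
        "mapped_vs_nonzero": {
            "accession": [r.accession for r in records],
            "pct_pseudoaligned": [r.pct_pseudoaligned for r in records],
            "pct_genes_nonzero": [r.pct_genes_nonzero for r in records],
        },
        "guides": {
            "min_pseudoaligned": thresholds.min_pseudoaligned,
            "min_pct_mapped": thresholds.min_pct_mapped,
            "min_pct_nonzero": thresholds.min_pct_nonzero,
        },
    }


def write_qc_report(records: list[QCRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "n_processed", "n_pseudoaligned",
                         "pct_pseudoaligned", "pct_genes_nonzero", "passed"])
        for r in records:
            writer.writerow([
                r.accession, r.n_processed, r.n_pseudoaligned,
                repr(r.pct_pseudoaligned), repr(r.pct_genes_nonzero),
                int(bool(r.passed)),
            ])


def read_qc_report(path: str | Path) -> list[QCRecord]:
    records = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(QCRecord(
                accession=row["accession"],
                n_processed=int(row["n_processed"]),
                n_pseudoaligned=int(row["n_pseudoaligned"]),
                pct_pseudoaligned=float(row["pct_pseudoaligned"]),
                pct_genes_nonzero=float(row["pct_genes_nonzero"]),
                passed=bool(int(row["passed"])),
            ))
    return records
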