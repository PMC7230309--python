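"""Pseudoaligner adaptation and TPM computation.

The pipeline pipes streamed fastq bytes into a pseudoalignment quantifier
(kallisto-style) and consumes two of its outputs: a run-info JSON summary
(reads processed / pseudoaligned) and a per-transcript abundance table
(target_id, length, eff_length, est_counts, tpm).  The quantifier sits
behind a small contract so the pipeline runs and is tested without any
aligner installed; an independent TPM computation validates parsed tables.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

__all__ = [
    "QuantParams",
    "RunStats",
    "AbundanceTable",
    "QuantEngine",
    "FixtureDirEngine",
    "KallistoEngine",
    "QuantificationError",
    "ParseError",
    "run_quantifier",
    "parse_run_info",
    "serialize_run_info",
    "parse_abundance",
    "compute_tpm",
]


class QuantificationError(RuntimeError):
    """The quantifier engine failed; carries engine diagnostics."""


class ParseError(ValueError):
    """A quantifier output document could not be parsed."""


@dataclass(frozen=True)
class QuantParams:
    """Quantifier invocation parameters.

    Defaults correspond to ``--single -l 200 -s 20 -t 2``: streamed prefixes
    are always quantified single-end (for paired runs only the first mate is
    streamed) with an assumed fragment length of 200 +/- 20 bp.
    """

    single_mode: bool = True
    fragment_length: float = 200.0
    fragment_sd: float = 20.0
    threads: int = 2
    index_path: str | None = None

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if self.fragment_sd <= 0:
            raise ValueError("fragment_sd must be positive")


@dataclass(frozen=True)
class RunStats:
    """Run-level pseudoalignment statistics."""

    n_processed: int
    n_pseudoaligned: int
    p_pseudoaligned: float
    n_targets: int = 0

    def __post_init__(self) -> None:
        if self.n_processed < 0 or self.n_pseudoaligned < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_pseudoaligned > self.n_processed:
            raise ValueError(
                f"n_pseudoaligned ({self.n_pseudoaligned}) exceeds "
                f"n_processed ({self.n_processed})"
            )
        expected = (100.0 * self.n_pseudoaligned / self.n_processed
                    if self.n_processed else 0.0)
        if abs(self.p_pseudoaligned - expected) > 0.1:
            raise ValueError(
                f"p_pseudoaligned {self.p_pseudoaligned} inconsistent with "
                f"counts (expected about {expected:.2f})"
            )


@dataclass
class AbundanceTable:
    """Per-transcript abundance estimates for one run.

    Column order follows the quantifier's standard TSV dialect:
    target_id, length, eff_length, est_counts, tpm.
    """

    ids: list[str]
    lengths: np.ndarray
    eff_lengths: np.ndarray
    est_counts: np.ndarray
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.eff_lengths = np.asarray(self.eff_lengths, dtype=float)
        self.est_counts = np.asarray(self.est_counts, dtype=float)
        self.tpm = np.asarray(self.tpm, dtype=float)
        n = len(self.ids)
        for name in ("lengths", "eff_lengths", "est_counts", "tpm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has wrong length")
        if len(set(self.ids)) != n:
            raise ValueError("transcript ids are not unique")
        if np.any(self.est_counts < 0) or np.any(self.tpm < 0):
            raise ValueError("counts and tpm must be non-negative")
        if np.any(self.est_counts > 0):
            total = self.tpm.sum()
            if not np.isclose(total, 1e6, rtol=1e-6):
                raise ValueError(
                    f"tpm column sums to {total!r}, expected 1e6"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "target_id": self.ids,
            "length": self.lengths,
            "eff_length": self.eff_lengths,
            "est_counts": self.est_counts,
            "tpm": self.tpm,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class QuantEngine(Protocol):
    """Contract: consume streamed bytes, emit run-info JSON and abundance TSV."""

    def quantify(self, accession: str, stream: Iterable[bytes],
                 params: QuantParams) -> tuple[str, str]:
        """Return ``(run_info_json_text, abundance_tsv_text)``."""
        ...


def parse_run_info(document: str) -> RunStats:
    """Parse the quantifier's run-info JSON into :class:`RunStats`."""
    try:
        data = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(f"run-info is not valid JSON: {exc}") from exc
    for key in ("n_processed", "n_pseudoaligned", "p_pseudoaligned"):
        if key not in data:
            raise ParseError(f"run-info is missing key {key!r}")
    return RunStats(
        n_processed=int(data["n_processed"]),
        n_pseudoaligned=int(data["n_pseudoaligned"]),
        p_pseudoaligned=float(data["p_pseudoaligned"]),
        n_targets=int(data.get("n_targets", 0)),
    )


def serialize_run_info(stats: RunStats) -> str:
    return json.dumps(
        {
            "n_processed": stats.n_processed,
            "n_pseudoaligned": stats.n_pseudoaligned,
            "p_pseudoaligned": stats.p_pseudoaligned,
            "n_targets": stats.n_targets,
        },
        sort_keys=True,
    )


def parse_abundance(text_or_path: str | Path) -> AbundanceTable:
    """Parse an abundance TSV (header: target_id length eff_length est_counts tpm)."""
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str) and "\n" not in text_or_path
    ):
        source: object = Path(text_or_path)
    else:
        import io

        source = io.StringIO(text_or_path)
    try:
        df = pd.read_csv(source, sep="\t")
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ParseError(f"cannot read abundance table: {exc}") from exc
    required = ["target_id", "length", "eff_length", "est_counts", "tpm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"abundance table missing columns {missing}")
    return AbundanceTable(
        ids=df["target_id"].astype(str).tolist(),
        lengths=df["length"].to_numpy(float),
        eff_lengths=df["eff_length"].to_numpy(float),
        est_counts=df["est_counts"].to_numpy(float),
        tpm=df["tpm"].to_numpy(float),
    )


def compute_tpm(est_counts: np.ndarray, eff_lengths: np.ndarray) -> np.ndarray:
    """Transcripts-per-million from estimated counts and effective lengths.

    tpm_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j); an all-zero count vector
    yields an all-zero tpm vector (degenerate sample, no renormalisation).
    """
    c = np.asarray(est_counts, dtype=float)
    l = np.asarray(eff_lengths, dtype=float)
    if c.shape != l.shape:
        raise ValueError(
            f"length mismatch: counts {c.shape} vs lengths {l.shape}"
        )
    if np.any((c > 0) & (l <= 0)):
        raise ValueError("positive count with non-positive effective length")
    rate = np.zeros_like(c)
    nz = l > 0
    rate[nz] = c[nz] / l[nz]
    total = rate.sum()
    if total == 0:
        return np.zeros_like(c)
    return 1e6 * rate / total


def run_quantifier(
    accession: str,
    stream: Iterable[bytes],
    params: QuantParams,
    engine: QuantEngine,
) -> tuple[RunStats, AbundanceTable]:
    """Drive one run through the quantifier engine and parse its outputs."""
    try:
        run_info_text, abundance_text = engine.quantify(accession, stream, params)
    except QuantificationError:
        raise
    except Exception as exc:  # engine-level failure with diagnostics
        raise QuantificationError(
            f"quantifier failed for {accession}: {exc}"
        ) from exc
    stats = parse_run_info(run_info_text)
    table = parse_abundance(abundance_text)
    return stats, table


class FixtureDirEngine:
    """Engine backed by pre-generated per-run output directories.

    Expects ``root/<accession>/run_info.json`` and ``abundance.tsv`` as
    written by the synthetic fixture generator.  The byte stream is drained
    (mirroring a real engine consuming stdin) but its content is ignored.
    """

    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)

    def quantify(self, accession: str, stream: Iterable[bytes],
                 params: QuantParams) -> tuple[str, str]:
        for _ in stream:
            pass
        run_dir = self.root / accession
        info = run_dir / "run_info.json"
        abundance = run_dir / "abundance.tsv"
        if not info.is_file() or not abundance.is_file():
            raise QuantificationError(
                f"no fixture outputs for {accession} under {run_dir}"
            )
        return info.read_text(), abundance.read_text()


class KallistoEngine:
    """Subprocess wrapper piping the byte stream to ``kallisto quant``.

    Requires a kallisto binary and a prebuilt index; exercised only when
    both are available (real-archive replication), never by the offline
    test suite.
    """

    def __init__(self, executable: str = "kallisto") -> None:
        self.executable = executable

    def build_command(self, params: QuantParams, out_dir: str) -> list[str]:
        if not params.index_path:
            raise ValueError("KallistoEngine requires params.index_path")
        cmd = [self.executable, "quant", "-i", params.index_path, "-o", out_dir]
        if params.single_mode:
            cmd += ["--single", "-l", str(params.fragment_length),
                    "-s", str(params.fragment_sd)]
        cmd += ["-t", str(params.threads), "-"]
        return cmd

    def quantify(self, accession: str, stream: Iterable[bytes],
                 params: QuantParams) -> tuple[str, str]:
        if shutil.which(self.executable) is None:
            raise QuantificationError(
                f"quantifier executable {self.executable!r} not found"
            )
        with tempfile.TemporaryDirectory() as out_dir:
            cmd = self.build_command(params, out_dir)
            proc = subprocess.Popen(cmd, stdin=subprocess.PIPE,
                                    stderr=subprocess.PIPE)
            assert proc.stdin is not None
            try:
                for chunk in stream:
                    proc.stdin.write(chunk)
            finally:
                proc.stdin.close()
            _, stderr = proc.communicate()
            if proc.returncode != 0:
                raise QuantificationError(
                    f"{self.executable} exited {proc.returncode} for "
                    f"{accession}: {stderr.decode(errors='replace')[-2000:]}"
                )
            info = Path(out_dir) / "run_info.json"
            abundance = Path(out_dir) / "abundance.tsv"
            if not info.is_file() or not abundance.is_file():
                raise ParseError("quantifier produced no output files")
            return info.read_text(), abundance.read_text()
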