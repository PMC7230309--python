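"""Stream-limited acquisition of public sequencing runs.

Public read archives expose each run's fastq files over FTP/HTTPS under a
deterministic directory layout keyed by the run accession.  Rather than
downloading whole archives, this module streams only a bounded prefix of each
file (by default the first 10^9 bytes) and aborts stalled or slow transfers,
recording a per-run status.  Transports are injectable so the whole module is
testable offline against local fixture files and a simulated clock.
"""

from __future__ import annotations

import csv
import re
import time
import urllib.error
import urllib.request
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Callable, Iterable, Iterator, Protocol

__all__ = [
    "RunRecord",
    "StreamPolicy",
    "AcquisitionResult",
    "Transport",
    "LocalFileTransport",
    "SimulatedTransport",
    "HTTPTransport",
    "build_fastq_urls",
    "stream_prefix",
    "acquire_manifest",
    "read_manifest",
    "write_download_report",
    "ENA_FASTQ_BASE",
]

#: Default base of the European Nucleotide Archive fastq mirror.
ENA_FASTQ_BASE = "https://ftp.sra.ebi.ac.uk/vol1/fastq"

_ACCESSION_RE = re.compile(r"^(SRR|ERR|DRR)(\d{6,})$")

_LAYOUTS = ("single", "paired")


@dataclass(frozen=True)
class RunRecord:
    """One sequencing run: archive accession plus library layout."""

    accession: str
    layout: str = "single"

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.match(self.accession):
            raise ValueError(
                f"malformed run accession {self.accession!r}: expected "
                "SRR/ERR/DRR prefix followed by at least six digits"
            )
        if self.layout not in _LAYOUTS:
            raise ValueError(
                f"layout must be one of {_LAYOUTS}, got {self.layout!r}"
            )


@dataclass(frozen=True)
class StreamPolicy:
    """Abort heuristics for a bounded streaming download.

    Defaults mirror a curl invocation ``-r 0-1,000,000,000 -m 600
    --speed-limit 1,000,000 --speed-time 30``: fetch at most the first
    billion bytes within 600 s, aborting if throughput averaged over the
    last 30 s drops below 1 MB/s.
    """

    byte_limit: int = 1_000_000_000
    max_duration: float = 600.0
    min_speed: float = 1_000_000.0
    speed_window: float = 30.0

    def __post_init__(self) -> None:
        for name in ("byte_limit", "max_duration", "min_speed", "speed_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"StreamPolicy.{name} must be strictly positive")


@dataclass(frozen=True)
class AcquisitionResult:
    accession: str
    status: str  # OK | NOT_FOUND | SLOW | TIMEOUT | ERROR
    bytes_received: int
    elapsed: float

    def __post_init__(self) -> None:
        if self.status == "OK" and self.bytes_received <= 0:
            raise ValueError("status OK requires bytes_received > 0")


class Transport(Protocol):
    """Byte source contract: ordered chunks plus a clock for elapsed time."""

    def open(self, url: str) -> Iterator[bytes]:
        """Yield chunks of the resource in order.

        Raises FileNotFoundError for a missing resource and OSError for
        other transport failures.
        """
        ...

    def clock(self) -> float:
        """Monotonic time in seconds, consistent with chunk delivery."""
        ...


def build_fastq_urls(record: RunRecord, base: str = ENA_FASTQ_BASE) -> list[str]:
    """Build the fastq URL(s) to stream for one run.

    The archive shards runs into directories by the first nine characters of
    the accession; accessions longer than nine characters gain an extra
    directory level holding the remaining digits left-padded with zeros to
    width three.  For paired layouts only the first mate (``_1.fastq.gz``)
    is fetched — it is later quantified in single-end mode — so exactly one
    URL is returned for either layout.
    """
    acc = record.accession
    parts = [base.rstrip("/"), acc[:6]]
    if len(acc) > 9:
        parts.append(acc[9:].zfill(3))
    parts.append(acc)
    suffix = "_1.fastq.gz" if record.layout == "paired" else ".fastq.gz"
    parts.append(acc + suffix)
    return ["/".join(parts)]


class LocalFileTransport:
    """Serve URLs from a local directory of fixture files (basename lookup)."""

    def __init__(self, root: str | Path, chunk_size: int = 65536,
                 clock: Callable[[], float] = time.monotonic) -> None:
        self.root = Path(root)
        self.chunk_size = chunk_size
        self._clock = clock

    def open(self, url: str) -> Iterator[bytes]:
        path = self.root / url.rsplit("/", 1)[-1]
        if not path.is_file():
            raise FileNotFoundError(str(path))
        with path.open("rb") as fh:
            while chunk := fh.read(self.chunk_size):
                yield chunk

    def clock(self) -> float:
        return self._clock()


class SimulatedTransport:
    """Scripted transport with a virtual clock, for deterministic tests.

    ``events`` is a sequence of ``(chunk, dt)`` pairs: each chunk arrives
    ``dt`` virtual seconds after the previous one.  Empty chunks model a
    stalled connection.
    """

    def __init__(self, events: Iterable[tuple[bytes, float]],
                 missing: bool = False) -> None:
        self.events = list(events)
        self.missing = missing
        self._now = 0.0

    def open(self, url: str) -> Iterator[bytes]:
        if self.missing:
            raise FileNotFoundError(url)
        for chunk, dt in self.events:
            self._now += dt
            yield chunk

    def clock(self) -> float:
        return self._now


class HTTPTransport:
    """Remote fetcher using HTTP Range requests to honor the byte limit.

    Not used by the test suite (which runs offline); provided for real
    archive access.
    """

    def __init__(self, byte_limit: int | None = None, chunk_size: int = 1 << 20,
                 timeout: float = 60.0) -> None:
        self.byte_limit = byte_limit
        self.chunk_size = chunk_size
        self.timeout = timeout

    def open(self, url: str) -> Iterator[bytes]:
        req = urllib.request.Request(url)
        if self.byte_limit is not None:
            req.add_header("Range", f"bytes=0-{self.byte_limit - 1}")
        try:
            resp = urllib.request.urlopen(req, timeout=self.timeout)
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise FileNotFoundError(url) from exc
            raise OSError(f"HTTP {exc.code} for {url}") from exc
        with resp:
            while chunk := resp.read(self.chunk_size):
                yield chunk

    def clock(self) -> float:
        return time.monotonic()


def stream_prefix(
    url: str,
    policy: StreamPolicy,
    transport: Transport,
    sink: Callable[[bytes], None] | BinaryIO | None = None,
    accession: str = "",
) -> AcquisitionResult:
    """Stream at most ``policy.byte_limit`` bytes of ``url`` into ``sink``.

    Termination rules, checked after every chunk:

    * byte limit reached or source exhausted -> ``OK``
    * elapsed time exceeds ``max_duration`` -> ``TIMEOUT``
    * average speed over the trailing ``speed_window`` seconds below
      ``min_speed`` (evaluated once a full window has elapsed) -> ``SLOW``
    * missing resource -> ``NOT_FOUND``; any other failure -> ``ERROR``

    Partial bytes already delivered to the sink are kept on abort; QC
    downstream decides the run's fate.
    """
    write = sink.write if hasattr(sink, "write") else sink
    start = transport.clock()
    received = 0
    # (time, cumulative bytes) samples for the sliding speed window
    window: deque[tuple[float, int]] = deque([(start, 0)])

    def result(status: str) -> AcquisitionResult:
        return AcquisitionResult(
            accession=accession or url,
            status=status,
            bytes_received=received,
            elapsed=transport.clock() - start,
        )

    try:
        for chunk in transport.open(url):
            now = transport.clock()
            remaining = policy.byte_limit - received
            if chunk:
                deliver = chunk[:remaining]
                received += len(deliver)
                if write is not None and deliver:
                    write(deliver)
            window.append((now, received))
            elapsed = now - start
            if received >= policy.byte_limit:
                return result("OK")
            if elapsed > policy.max_duration:
                return result("TIMEOUT")
            while len(window) > 1 and now - window[0][0] > policy.speed_window:
                window.popleft()
            if elapsed >= policy.speed_window:
                t0, b0 = window[0]
                span = now - t0
                if span > 0 and (received - b0) / span < policy.min_speed:
                    return result("SLOW")
    except FileNotFoundError:
        return result("NOT_FOUND")
    except OSError:
        return result("ERROR")
    # source exhausted before the limit
    if received > 0:
        return result("OK")
    return result("ERROR")


def acquire_manifest(
    records: list[RunRecord],
    policy: StreamPolicy,
    transport: Transport,
    sink_factory: Callable[[RunRecord], Callable[[bytes], None] | BinaryIO | None]
    | None = None,
    base: str = ENA_FASTQ_BASE,
    report_path: str | Path | None = None,
) -> list[AcquisitionResult]:
    """Stream every run in the manifest, preserving order.

    Per-run failures are captured as statuses, never raised.  ``sink_factory``
    maps each record to its byte consumer (or None to discard bytes).  If
    ``report_path`` is given the download report is written there as TSV.
    """
    if not records:
        raise ValueError("manifest is empty")
    results = []
    for record in records:
        (url,) = build_fastq_urls(record, base=base)
        sink = sink_factory(record) if sink_factory is not None else None
        try:
            results.append(
                stream_prefix(url, policy, transport, sink=sink,
                              accession=record.accession)
            )
        finally:
            if sink is not None and hasattr(sink, "close"):
                sink.close()
    if report_path is not None:
        write_download_report(results, report_path)
    return results


def read_manifest(path: str | Path) -> list[RunRecord]:
    """Read a run manifest: one accession per line, optional TAB layout column."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        layout = fields[1].strip().lower() if len(fields) > 1 else "single"
        records.append(RunRecord(accession=fields[0].strip(), layout=layout))
    return records


def write_download_report(results: list[AcquisitionResult],
                          path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "status", "bytes_received",
                         "elapsed_seconds"])
        for r in results:
            writer.writerow([r.accession, r.status, r.bytes_received,
                             f"{r.elapsed:.3f}"])


def read_download_report(path: str | Path) -> list[AcquisitionResult]:
    results = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            results.append(AcquisitionResult(
                accession=row["accession"],
                status=row["status"],
                bytes_received=int(row["bytes_received"]),
                elapsed=float(row["elapsed_seconds"]),
            ))
    return results
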