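"""End-to-end workflow orchestration with resumable stages.

Stages run in order — acquire, quantify, qc, matrix, network, organs — and
each stage declares its output files; a stage whose outputs already exist
is skipped (streaming a gigabyte per run is expensive), unless forced.
Every stage appends a machine-readable line to ``pipeline_log.jsonl`` in
the workspace.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition import (
    ENA_FASTQ_BASE,
    HTTPTransport,
    LocalFileTransport,
    RunRecord,
    StreamPolicy,
    acquire_manifest,
    read_download_report,
    read_manifest,
)
from .matrix import assemble_matrix, read_matrix, write_matrix
from .network import (
    AnnotationTable,
    NetworkParams,
    bait_neighborhood,
    build_network,
    export_cyjs,
    write_edge_list,
)
from .organs import (
    DEFAULT_ORGANS,
    SampleMetadata,
    UNTREATED_TERMS,
    WILDTYPE_TERMS,
    organ_profile,
)
from .qc import QCThresholds, apply_filter, compute_qc, write_qc_report
from .quantification import (
    FixtureDirEngine,
    KallistoEngine,
    QuantParams,
    parse_abundance,
    parse_run_info,
    run_quantifier,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config",
           "STAGES"]

STAGES = ("acquire", "quantify", "qc", "matrix", "network", "organs")


class PipelineError(RuntimeError):
    """A stage hard-failed; message carries the stage name and context."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; defaults mirror the published
    protocol (1e9-byte prefixes, 600 s/1 MB/s/30 s aborts, single-end
    quantification at 200 +/- 20 bp, QC at 1e6 reads / 40% / 40%,
    neighborhoods of at most 50 genes at PCC >= 0.7)."""

    manifest: str
    workspace: str
    bait: str | None = None
    policy: StreamPolicy = field(default_factory=StreamPolicy)
    quant: QuantParams = field(default_factory=QuantParams)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    max_neighbors: int = 50
    min_pcc: float = 0.7
    log2: bool = False
    neighbor_edges: bool = True
    engine: str = "kallisto"  # or "fixture"
    quant_fixtures: str | None = None
    remote_dir: str | None = None  # local mirror for offline runs
    remote_base: str = ENA_FASTQ_BASE
    annotation: str | None = None
    metadata: str | None = None
    organs: tuple[str, ...] = DEFAULT_ORGANS
    wildtype_terms: tuple[str, ...] = WILDTYPE_TERMS
    untreated_terms: tuple[str, ...] = UNTREATED_TERMS
    seed: int = 0


_POLICY_KEYS = {"byte_limit", "max_duration", "min_speed", "speed_window"}
_QUANT_KEYS = {"single_mode", "fragment_length", "fragment_sd", "threads",
               "index_path"}
_QC_KEYS = {"min_pseudoaligned", "min_pct_mapped", "min_pct_nonzero"}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a flat-key YAML config; relative paths resolve against the file.

    Flat keys matching streaming / quantifier / QC parameter names are
    routed into their parameter objects; anything else must be a
    :class:`PipelineConfig` field.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    raw.update(overrides)
    base = path.parent
    policy_kwargs = {k: raw.pop(k) for k in list(raw) if k in _POLICY_KEYS}
    quant_kwargs = {k: raw.pop(k) for k in list(raw) if k in _QUANT_KEYS}
    qc_kwargs = {k: raw.pop(k) for k in list(raw) if k in _QC_KEYS}
    for key in ("manifest", "annotation", "metadata", "quant_fixtures",
                "remote_dir"):
        if raw.get(key):
            raw[key] = str((base / raw[key]).resolve()
                           if not Path(raw[key]).is_absolute() else raw[key])
    raw.setdefault("workspace", str(base))
    if "organs" in raw:
        raw["organs"] = tuple(raw["organs"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(
        policy=StreamPolicy(**policy_kwargs),
        quant=QuantParams(**quant_kwargs),
        thresholds=QCThresholds(**qc_kwargs),
        **raw,
    )


class _Workspace:
    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    @property
    def streams(self) -> Path:
        return self.root / "streams"

    @property
    def quant(self) -> Path:
        return self.root / "quant"

    def path(self, name: str) -> Path:
        return self.root / name

    def log(self, stage: str, status: str, **counts) -> None:
        entry = {"stage": stage, "status": status, **counts}
        with (self.root / "pipeline_log.jsonl").open("a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _stage_acquire(config: PipelineConfig, ws: _Workspace,
                   force: bool) -> None:
    report = ws.path("download_report.tsv")
    if report.exists() and not force:
        ws.log("acquire", "skipped")
        return
    t0 = time.monotonic()
    records = read_manifest(config.manifest)
    if config.remote_dir:
        transport = LocalFileTransport(config.remote_dir)
    else:
        transport = HTTPTransport(byte_limit=config.policy.byte_limit)
    ws.streams.mkdir(parents=True, exist_ok=True)

    def sink_factory(record: RunRecord):
        return (ws.streams / f"{record.accession}.fastq.gz").open("wb")

    results = acquire_manifest(records, config.policy, transport,
                               sink_factory=sink_factory,
                               base=config.remote_base, report_path=report)
    ws.log("acquire", "ok", n_runs=len(results),
           n_ok=sum(r.status == "OK" for r in results),
           elapsed=round(time.monotonic() - t0, 3))


def _make_engine(config: PipelineConfig):
    if config.engine == "fixture":
        if not config.quant_fixtures:
            raise PipelineError("quantify: fixture engine needs quant_fixtures")
        return FixtureDirEngine(config.quant_fixtures)
    if config.engine == "kallisto":
        return KallistoEngine()
    raise PipelineError(f"quantify: unknown engine {config.engine!r}")


def _iter_stream_chunks(path: Path, chunk_size: int = 65536):
    with path.open("rb") as fh:
        while chunk := fh.read(chunk_size):
            yield chunk


def _stage_quantify(config: PipelineConfig, ws: _Workspace,
                    force: bool) -> None:
    done = ws.path("quantified.json")
    if done.exists() and not force:
        ws.log("quantify", "skipped")
        return
    t0 = time.monotonic()
    results = read_download_report(ws.path("download_report.tsv"))
    engine = _make_engine(config)
    quantified = []
    for res in results:
        if res.bytes_received <= 0:
            continue
        stream_path = ws.streams / f"{res.accession}.fastq.gz"
        try:
            stats, table = run_quantifier(
                res.accession, _iter_stream_chunks(stream_path),
                config.quant, engine)
        except Exception as exc:
            raise PipelineError(
                f"quantify: run {res.accession} failed: {exc}") from exc
        out = ws.quant / res.accession
        out.mkdir(parents=True, exist_ok=True)
        table.write_tsv(out / "abundance.tsv")
        from .quantification import serialize_run_info

        (out / "run_info.json").write_text(serialize_run_info(stats) + "\n")
        quantified.append(res.accession)
    done.write_text(json.dumps({"accessions": quantified}, indent=1) + "\n")
    ws.log("quantify", "ok", n_quantified=len(quantified),
           elapsed=round(time.monotonic() - t0, 3))


def _stage_qc(config: PipelineConfig, ws: _Workspace, force: bool) -> None:
    report = ws.path("qc_report.tsv")
    if report.exists() and not force:
        ws.log("qc", "skipped")
        return
    t0 = time.monotonic()
    accessions = json.loads(ws.path("quantified.json").read_text())["accessions"]
    records = []
    for acc in accessions:
        stats = parse_run_info((ws.quant / acc / "run_info.json").read_text())
        table = parse_abundance(ws.quant / acc / "abundance.tsv")
        records.append(compute_qc(acc, stats, table))
    passed, failed = apply_filter(records, config.thresholds)
    ordered = sorted(passed + failed,
                     key=lambda r: accessions.index(r.accession))
    write_qc_report(ordered, report)
    ws.log("qc", "ok", n_pass=len(passed), n_fail=len(failed),
           elapsed=round(time.monotonic() - t0, 3))


def _stage_matrix(config: PipelineConfig, ws: _Workspace, force: bool) -> None:
    out = ws.path("matrix.tsv")
    if out.exists() and not force:
        ws.log("matrix", "skipped")
        return
    t0 = time.monotonic()
    from .qc import read_qc_report

    records = read_qc_report(ws.path("qc_report.tsv"))
    pass_list = [r.accession for r in records if r.passed]
    if not pass_list:
        raise PipelineError("matrix: no runs passed QC")
    abundances = {acc: parse_abundance(ws.quant / acc / "abundance.tsv")
                  for acc in pass_list}
    matrix = assemble_matrix(abundances, pass_list)
    write_matrix(matrix, out)
    ws.log("matrix", "ok", n_genes=matrix.shape[0],
           n_samples=matrix.shape[1],
           elapsed=round(time.monotonic() - t0, 3))


def _stage_network(config: PipelineConfig, ws: _Workspace,
                   force: bool) -> None:
    out = ws.path("network.cyjs.json")
    edges_out = ws.path("network_edges.tsv")
    if out.exists() and edges_out.exists() and not force:
        ws.log("network", "skipped")
        return
    if not config.bait:
        ws.log("network", "skipped", reason="no bait gene configured")
        return
    t0 = time.monotonic()
    matrix = read_matrix(ws.path("matrix.tsv"))
    params = NetworkParams(bait=config.bait,
                           max_neighbors=config.max_neighbors,
                           min_pcc=config.min_pcc, log2=config.log2,
                           neighbor_edges=config.neighbor_edges)
    annotation = (AnnotationTable.read_tsv(config.annotation)
                  if config.annotation else None)
    try:
        neighborhood = bait_neighborhood(matrix, params)
    except KeyError as exc:
        raise PipelineError(f"network: {exc.args[0]}") from exc
    network = build_network(matrix, neighborhood, params, annotation)
    out.write_text(export_cyjs(network) + "\n")
    write_edge_list(network, edges_out)
    ws.log("network", "ok", n_nodes=network.graph.number_of_nodes(),
           n_edges=network.graph.number_of_edges(),
           elapsed=round(time.monotonic() - t0, 3))


def _stage_organs(config: PipelineConfig, ws: _Workspace,
                  force: bool) -> None:
    med_out = ws.path("organ_medians.tsv")
    rel_out = ws.path("organ_relative.tsv")
    if med_out.exists() and rel_out.exists() and not force:
        ws.log("organs", "skipped")
        return
    if not config.metadata:
        ws.log("organs", "skipped", reason="no sample metadata configured")
        return
    t0 = time.monotonic()
    matrix = read_matrix(ws.path("matrix.tsv"))
    metadata = SampleMetadata.read_tsv(config.metadata)
    genes = None
    network_path = ws.path("network.cyjs.json")
    if network_path.exists():
        doc = json.loads(network_path.read_text())
        genes = [n["data"]["id"] for n in doc["elements"]["nodes"]]
    profile = organ_profile(matrix, metadata, genes=genes,
                            organs=config.organs,
                            wildtype_terms=config.wildtype_terms,
                            untreated_terms=config.untreated_terms)
    profile.write_tsvs(med_out, rel_out)
    ws.log("organs", "ok", n_genes=len(profile.gene_ids),
           n_organs=len(profile.organs),
           elapsed=round(time.monotonic() - t0, 3))


_STAGE_FUNCS = {
    "acquire": _stage_acquire,
    "quantify": _stage_quantify,
    "qc": _stage_qc,
    "matrix": _stage_matrix,
    "network": _stage_network,
    "organs": _stage_organs,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES,
                 force: bool = False) -> Path:
    """Run the requested stages in canonical order; returns the workspace.

    Completed stages (declared outputs present) are skipped unless
    ``force``.  Stage errors raise :class:`PipelineError` naming the stage;
    earlier outputs stay intact.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ws = _Workspace(config.workspace)
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, ws, force)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
    return ws.root
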