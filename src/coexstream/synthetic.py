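"""Synthetic fixture generation: the package's stand-in for a public corpus.

Everything the pipeline consumes can be generated here from a seed:
expression matrices with planted coexpression modules (optionally
organ-specific), per-run quantifier output directories, QC populations with
known pass/fail composition, and a complete demo workspace (manifest, fake
fastq files, metadata, annotation) for the quickstart.

The generative model for a module matrix: each module m has one latent
positive profile z_m across samples (log-normal draws); a member gene g is
a noisy scaled copy ``a_g * z_m * (1 + eps)`` with multiplicative Gaussian
noise of relative scale ``noise_sd``, clamped at zero; background genes are
independent log-normal noise.  Columns are rescaled to sum to 1e6, so the
output is TPM-like.  Multiplicative noise means recovery difficulty is
controlled by the single ``noise_sd`` knob; this is a modeling convenience,
not a claim about real RNA-seq noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .acquisition import RunRecord, build_fastq_urls
from .matrix import ExpressionMatrix
from .organs import SampleAnnotation, SampleMetadata
from .qc import QCRecord, QCThresholds
from .quantification import AbundanceTable, RunStats, compute_tpm, serialize_run_info

__all__ = [
    "FixtureSpec",
    "generate_module_matrix",
    "generate_run_fixture",
    "generate_qc_population",
    "generate_demo_workspace",
]

# Log-normal location/scale for the module latents, per-gene scales and
# background genes.  Chosen so module latents dominate within-module
# variance while background genes stay uncorrelated.
_LATENT_MU, _LATENT_SIGMA = 2.0, 1.0
_SCALE_MU, _SCALE_SIGMA = 0.0, 0.5
_BG_MU, _BG_SIGMA = 2.0, 1.0
# Organ-specific modules: latent location is shifted up by log of this
# factor in the module's own organ samples.
_ORGAN_ELEVATION = 20.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-module expression matrix."""

    n_genes: int
    n_samples: int
    n_modules: int
    genes_per_module: int
    noise_sd: float
    seed: int
    organ_plan: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError("modules need more genes than n_genes provides")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.organ_plan is not None:
            if sum(self.organ_plan.values()) != self.n_samples:
                raise ValueError("organ_plan sample counts must sum to n_samples")


def _sample_ids(n: int) -> list[str]:
    return [f"SRR{9000000 + i}" for i in range(n)]


def _gene_ids(spec: FixtureSpec) -> tuple[list[str], dict[str, str]]:
    """Gene ids plus the truth map gene -> module label or 'background'."""
    ids: list[str] = []
    truth: dict[str, str] = {}
    for m in range(spec.n_modules):
        for j in range(spec.genes_per_module):
            gid = f"M{m:02d}G{j:03d}"
            ids.append(gid)
            truth[gid] = f"module{m}"
    n_background = spec.n_genes - len(ids)
    for j in range(n_background):
        gid = f"BG{j:04d}"
        ids.append(gid)
        truth[gid] = "background"
    return ids, truth


def _sample_organs(spec: FixtureSpec) -> list[str] | None:
    if spec.organ_plan is None:
        return None
    organs = []
    for organ, count in spec.organ_plan.items():
        organs.extend([organ] * count)
    return organs


def module_organ(spec: FixtureSpec, module_index: int) -> str:
    """The organ a module is planted in (round-robin over the plan)."""
    if spec.organ_plan is None:
        raise ValueError("spec has no organ plan")
    organ_names = list(spec.organ_plan)
    return organ_names[module_index % len(organ_names)]


def generate_module_matrix(
    spec: FixtureSpec,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Generate a TPM-like matrix with planted coexpression modules.

    Returns the matrix and the truth map (gene id -> ``moduleN`` or
    ``background``).  With an ``organ_plan``, module m's latent profile is
    elevated only in samples of organ ``module_organ(spec, m)``, making the
    module organ-specific.  Output is a pure function of the spec
    (including the seed).
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids, truth = _gene_ids(spec)
    sample_ids = _sample_ids(spec.n_samples)
    organs = _sample_organs(spec)
    values = np.empty((spec.n_genes, spec.n_samples))

    row = 0
    for m in range(spec.n_modules):
        mu = np.full(spec.n_samples, _LATENT_MU)
        if organs is not None:
            own = module_organ(spec, m)
            mu = np.where(np.array(organs) == own,
                          _LATENT_MU + math.log(_ORGAN_ELEVATION),
                          _LATENT_MU - math.log(_ORGAN_ELEVATION) / 2)
        z = rng.lognormal(mean=0.0, sigma=_LATENT_SIGMA,
                          size=spec.n_samples) * np.exp(mu)
        for _ in range(spec.genes_per_module):
            a = rng.lognormal(mean=_SCALE_MU, sigma=_SCALE_SIGMA)
            eps = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
            values[row] = np.clip(a * z * (1.0 + eps), 0.0, None)
            row += 1
    n_background = spec.n_genes - row
    if n_background:
        values[row:] = rng.lognormal(mean=_BG_MU, sigma=_BG_SIGMA,
                                     size=(n_background, spec.n_samples))
    col_sums = values.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    values = values / col_sums * 1e6
    matrix = ExpressionMatrix(values, gene_ids=gene_ids, sample_ids=sample_ids)
    return matrix, truth


def generate_organ_metadata(spec: FixtureSpec) -> SampleMetadata:
    """Wild-type, untreated metadata matching the spec's organ plan."""
    organs = _sample_organs(spec)
    if organs is None:
        raise ValueError("spec has no organ plan")
    return SampleMetadata({
        acc: SampleAnnotation(organ=organ, genotype="wild type",
                              treatment="untreated")
        for acc, organ in zip(_sample_ids(spec.n_samples), organs)
    })


def generate_run_fixture(
    accession: str,
    gene_ids: list[str],
    tpm: np.ndarray,
    stats: RunStats,
    out_dir: str | Path,
    seed: int = 0,
) -> Path:
    """Write one run's quantifier-output directory (abundance TSV + run-info).

    Effective lengths are drawn log-normally around ~1.5 kb; estimated
    counts are chosen consistent with the requested TPM column and scaled
    so their total approximates ``stats.n_pseudoaligned``.
    """
    rng = np.random.default_rng(seed)
    tpm = np.asarray(tpm, dtype=float)
    n = len(gene_ids)
    lengths = np.round(rng.lognormal(mean=math.log(1500), sigma=0.3, size=n))
    eff_lengths = np.clip(lengths - 150.0, 50.0, None)
    counts = tpm * eff_lengths
    total = counts.sum()
    if total > 0 and stats.n_pseudoaligned > 0:
        counts = counts / total * stats.n_pseudoaligned
    tpm_exact = compute_tpm(counts, eff_lengths)
    table = AbundanceTable(ids=list(gene_ids), lengths=lengths,
                           eff_lengths=eff_lengths, est_counts=counts,
                           tpm=tpm_exact)
    run_dir = Path(out_dir) / accession
    run_dir.mkdir(parents=True, exist_ok=True)
    table.write_tsv(run_dir / "abundance.tsv")
    (run_dir / "run_info.json").write_text(serialize_run_info(stats) + "\n")
    return run_dir


def generate_qc_population(
    n_pass: int,
    n_fail_each_reason: tuple[int, int, int],
    thresholds: QCThresholds,
    seed: int,
) -> list[QCRecord]:
    """QC records with exact, known pass/fail composition.

    ``n_fail_each_reason`` gives counts for (too few reads pseudoaligned,
    low percent mapped, low percent of nonzero genes); each failing record
    violates only its own criterion.
    """
    if n_pass < 0 or any(c < 0 for c in n_fail_each_reason):
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[QCRecord] = []
    idx = 0

    def make(n_pseudo: int, pct_mapped: float, pct_nonzero: float) -> QCRecord:
        nonlocal idx
        pct_mapped = float(np.clip(pct_mapped, 0.5, 100.0))
        n_processed = max(int(round(n_pseudo / (pct_mapped / 100.0))), n_pseudo)
        pct = 100.0 * n_pseudo / n_processed if n_processed else 0.0
        rec = QCRecord(
            accession=f"SRR{8000000 + idx}",
            n_processed=n_processed,
            n_pseudoaligned=n_pseudo,
            pct_pseudoaligned=pct,
            pct_genes_nonzero=float(np.clip(pct_nonzero, 0.0, 100.0)),
        )
        idx += 1
        return rec

    hi_reads = max(2 * thresholds.min_pseudoaligned, 1_000_000)
    hi_map = min(thresholds.min_pct_mapped + 25.0, 99.0)
    hi_nz = min(thresholds.min_pct_nonzero + 25.0, 99.0)
    for _ in range(n_pass):
        records.append(make(
            int(rng.integers(thresholds.min_pseudoaligned, hi_reads + 1)),
            rng.uniform(max(thresholds.min_pct_mapped, 1.0), hi_map),
            rng.uniform(thresholds.min_pct_nonzero, hi_nz),
        ))
    low_reads, low_map, low_nz = n_fail_each_reason
    for _ in range(low_reads):
        records.append(make(
            int(rng.integers(0, max(thresholds.min_pseudoaligned, 1))),
            rng.uniform(max(thresholds.min_pct_mapped, 1.0), hi_map),
            rng.uniform(thresholds.min_pct_nonzero, hi_nz),
        ))
    for _ in range(low_map):
        records.append(make(
            int(rng.integers(thresholds.min_pseudoaligned, hi_reads + 1)),
            rng.uniform(0.5, max(thresholds.min_pct_mapped - 1e-6, 0.5)),
            rng.uniform(thresholds.min_pct_nonzero, hi_nz),
        ))
    for _ in range(low_nz):
        records.append(make(
            int(rng.integers(thresholds.min_pseudoaligned, hi_reads + 1)),
            rng.uniform(max(thresholds.min_pct_mapped, 1.0), hi_map),
            rng.uniform(0.0, max(thresholds.min_pct_nonzero - 1e-6, 0.0)),
        ))
    return records


#: Bin labels cycled over planted modules in the demo annotation table.
_DEMO_BINS = [
    "secondary metabolism",
    "transport",
    "RNA biosynthesis",
    "cell wall organisation",
    "lipid metabolism",
]

_DEMO_STYLE = {
    "secondary metabolism": ("diamond", "#d62728"),
    "transport": ("triangle", "#1f77b4"),
    "RNA biosynthesis": ("rectangle", "#2ca02c"),
    "cell wall organisation": ("hexagon", "#9467bd"),
    "lipid metabolism": ("vee", "#ff7f0e"),
}


def generate_demo_workspace(
    root: str | Path,
    seed: int = 0,
    n_modules: int = 3,
    genes_per_module: int = 10,
    n_background: int = 60,
    organ_plan: dict[str, int] | None = None,
    n_bad_runs: int = 2,
) -> dict:
    """Emit a complete demo workspace under ``root``.

    Contents: ``manifest.tsv``; a ``remote/`` directory of small fake
    fastq files laid out like an archive mirror (streamed by the local
    transport); ``quant_fixtures/<accession>/`` quantifier outputs;
    ``metadata.tsv``; ``annotation.tsv``; and ``config.yaml`` wiring the
    pipeline to them.  ``n_bad_runs`` extra runs are planted to fail:
    one absent from the mirror (NOT_FOUND) and the rest with too few
    pseudoaligned reads (QC failure).

    Returns a manifest of what was planted (bait gene, truth map, paths).
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    organ_plan = organ_plan or {"root": 4, "leaf": 4, "flower": 4,
                                "shoot": 4, "stem": 4}
    n_samples = sum(organ_plan.values())
    spec = FixtureSpec(
        n_genes=n_modules * genes_per_module + n_background,
        n_samples=n_samples,
        n_modules=n_modules,
        genes_per_module=genes_per_module,
        noise_sd=0.1,
        seed=seed,
        organ_plan=organ_plan,
    )
    matrix, truth = generate_module_matrix(spec)
    metadata = generate_organ_metadata(spec)
    accessions = matrix.sample_ids
    rng = np.random.default_rng(spec.seed + 1)

    # extra runs destined to fail acquisition or QC
    bad_accessions = [f"SRR{9900000 + i}" for i in range(n_bad_runs)]
    all_accessions = accessions + bad_accessions

    manifest_path = root / "manifest.tsv"
    with manifest_path.open("w") as fh:
        for i, acc in enumerate(all_accessions):
            layout = "paired" if i % 3 == 0 else "single"
            fh.write(f"{acc}\t{layout}\n")

    remote = root / "remote"
    remote.mkdir(exist_ok=True)
    quant_dir = root / "quant_fixtures"
    for i, acc in enumerate(all_accessions):
        layout = "paired" if i % 3 == 0 else "single"
        record = RunRecord(accession=acc, layout=layout)
        (url,) = build_fastq_urls(record)
        basename = url.rsplit("/", 1)[-1]
        is_missing = acc in bad_accessions[:1]  # first bad run: NOT_FOUND
        if not is_missing:
            payload = rng.integers(0, 256, size=int(rng.integers(2000, 6000)),
                                   dtype=np.uint8).tobytes()
            (remote / basename).write_bytes(payload)
        if acc in accessions:
            col = matrix.frame[acc].to_numpy()
            n_pseudo = int(rng.integers(5_000_000, 20_000_000))
            n_proc = int(n_pseudo / rng.uniform(0.55, 0.8))
            stats = RunStats(
                n_processed=n_proc, n_pseudoaligned=n_pseudo,
                p_pseudoaligned=round(100.0 * n_pseudo / n_proc, 2),
                n_targets=spec.n_genes,
            )
            generate_run_fixture(acc, matrix.gene_ids, col, stats, quant_dir,
                                 seed=int(rng.integers(0, 2**31)))
        elif not is_missing:
            # streams fine but fails QC: too few reads pseudoaligned
            n_pseudo = int(rng.integers(1_000, 100_000))
            n_proc = n_pseudo * 2
            stats = RunStats(
                n_processed=n_proc, n_pseudoaligned=n_pseudo,
                p_pseudoaligned=round(100.0 * n_pseudo / n_proc, 2),
                n_targets=spec.n_genes,
            )
            tpm = np.zeros(spec.n_genes)
            tpm[: max(spec.n_genes // 10, 1)] = 1.0  # few genes nonzero
            generate_run_fixture(acc, matrix.gene_ids, tpm, stats, quant_dir,
                                 seed=int(rng.integers(0, 2**31)))

    metadata_path = root / "metadata.tsv"
    with metadata_path.open("w") as fh:
        fh.write("accession\torgan\tgenotype\ttreatment\n")
        for acc, ann in metadata.items():
            fh.write(f"{acc}\t{ann.organ}\t{ann.genotype}\t{ann.treatment}\n")

    annotation_path = root / "annotation.tsv"
    with annotation_path.open("w") as fh:
        for gene in matrix.gene_ids:
            label = truth[gene]
            if label == "background":
                bin_label = "not assigned"
            else:
                bin_label = _DEMO_BINS[int(label.removeprefix("module"))
                                       % len(_DEMO_BINS)]
            fh.write(f"{gene}\t{bin_label}\n")

    bait = "M00G000"  # first gene of the first planted module
    config_path = root / "config.yaml"
    config_path.write_text(
        "manifest: manifest.tsv\n"
        "remote_dir: remote\n"
        "engine: fixture\n"
        "quant_fixtures: quant_fixtures\n"
        f"bait: {bait}\n"
        "annotation: annotation.tsv\n"
        "metadata: metadata.tsv\n"
        f"seed: {seed}\n"
    )
    return {
        "root": root,
        "bait": bait,
        "truth": truth,
        "spec": spec,
        "matrix": matrix,
        "accessions": all_accessions,
        "bad_accessions": bad_accessions,
        "style_map": dict(_DEMO_STYLE),
    }
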