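# Methods

## Streaming model

Runs are fetched from the ENA fastq mirror by accession. The directory
convention is `<prefix+first-3-digits>/[<suffix-dir>/]<accession>/`, where
the suffix directory exists only for accessions longer than 9 characters
and holds the final `len−9` digits left-padded with zeros to width 3
(`SRR1234567 → SRR123/007/…`, `SRR12345678 → SRR123/078/…`; suffixes longer
than three digits are kept whole). Paired-end runs are represented by
their `_1.fastq.gz` mate only and quantified single-end; the `_2` file is
never requested.

A transfer delivers at most `byte_limit` bytes (default 10⁹ ≈ 953 MiB) and
is aborted on a wall-clock budget (600 s) or low throughput: the mean
rate over a trailing `speed_window` (30 s at ≥ 10⁶ B/s by default), checked
at chunk granularity once a full window has elapsed. curl's internal
speed smoothing is not publicly specified, so this sliding-window average
is declared behavior rather than an emulation. Aborted transfers keep
their partial prefix — a truncated fastq stream is still quantifiable, and
the QC filter decides whether the run survives. Transports are injectable
(`HTTPTransport` with Range requests, `LocalFileTransport`,
`SimulatedTransport` with a virtual clock), which is what makes the abort
logic deterministic under test.

## Quantification and TPM

The quantifier sits behind a two-method contract (consume a byte stream,
emit run-info JSON and an abundance TSV). The kallisto subprocess wrapper
reproduces the single-end invocation `--single -l 200 -s 20 -t 2`; fragment
length 200 ± 20 bp is an assumption imposed on all streamed prefixes, kept
as the configurable default. Abundance rows stay at the resolution the
index defines (CDS/gene-model level here); no transcript-to-gene
aggregation is attempted.

TPM is recomputed independently from estimated counts and effective
lengths, `tpm_i = 10⁶ (c_i/ℓ_i)/Σ_j(c_j/ℓ_j)`, and cross-checked against
the quantifier's own column at 1e−4 relative tolerance. A sample with
all-zero counts yields all-zero TPM (no renormalization); a run with zero
processed reads has its mapped percentage defined as 0.

## QC filter

Three inclusive thresholds, applied per run: n_pseudoaligned ≥ 10⁶,
percent of processed reads pseudoaligned ≥ 40, percent of genes with
strictly nonzero TPM ≥ 40. The mapped percentage is computed from the
quantifier's processed-read count, not streamed bytes (bytes include
compression and record overhead). No epsilon is applied to "nonzero".
The filter is a pure function of the record and thresholds, so the
partition is idempotent and monotone in each threshold (raising a
threshold can only shrink the pass set) — both are property-tested.

## Matrix

Dense float64, genes in index order as rows, passing samples in manifest
order as columns (≈ 8·G·S bytes; 0.5 GB at 60k × 1000). TSV serialization
uses `repr` round-trip floats and parsing uses pandas'
`float_precision="round_trip"`, making write→read an exact identity — the
basis of the pipeline's byte-identical rerun guarantee.

## Coexpression network

Neighborhood rule: all genes with Pearson correlation ≥ `min_pcc` (0.7)
against the bait, ranked by correlation descending, ties broken by gene id
ascending, truncated to `max_neighbors` (50). Zero-variance genes have no
defined correlation and are excluded (counted in the log) rather than
treated as r = 0; a constant bait is an error. Correlations are computed
on raw TPM by default — a `log2(TPM+1)` option exists but is off, matching
the protocol's use of raw TPM. The truncation-by-rank rule when more than
50 genes clear the floor is declared behavior (the obvious reading of "at
most 50", not a verified detail of any external implementation).

Edges: bait–neighbor edges always; neighbor–neighbor edges are included
when their pairwise correlation also clears the floor, because hub
neighborhoods in this domain are typically displayed with their internal
structure. A star-topology switch (`--star`) disables them. Undirected
edges serialize once with the lexicographically smaller id as source, and
the Cytoscape.js export sorts nodes, edges and keys, so network JSON is
deterministic. Node styling maps functional-bin labels (e.g. major Mapman
bins from a two-column annotation TSV) to shape/color, with a logged
default fallback for unstyled bins.

## Organ profiles

Sample metadata (accession → organ, genotype, treatment) mirrors a reduced
SRA run-selector export. Matching is term-list based because the source
metadata is free text: organ labels match case-insensitively after
trimming; genotype must be in the wild-type allow-list ("wild type",
"wild-type", "wildtype", "WT") and treatment in the untreated list
("untreated", "none", "control", empty). The lists are configurable and
deliberately conservative; no tissue-ontology mapping is attempted.
Per organ, a gene's expression is the median across samples (even counts:
midpoint of the central pair — the standard convention); each row of
medians is divided by its maximum, so relative values lie in [0, 1], every
non-zero row attains 1, and the profile is invariant to rescaling a gene.

## Synthetic corpus generator

The generator emulates what the pipeline needs from a public corpus, not
RNA-seq reads themselves. A module m has one latent positive profile
z_m ~ LogNormal(μ=2, σ=1) across samples; member gene g is
`a_g · z_m · (1+ε)` with gene scale a_g ~ LogNormal(0, 0.5) and
multiplicative noise ε ~ N(0, noise_sd), clamped at zero; background genes
are independent LogNormal(2, 1). Columns are rescaled to sum to 10⁶
(TPM-like). Multiplicative noise makes recovery difficulty a single-knob
property: at noise_sd = 0, module members are exact scaled copies (pairwise
r = 1, surviving the per-sample column rescale, which multiplies both genes
by the same factor); at 0.1 the reference condition (5 modules × 20 genes,
200 background, 50 samples) is comfortably but not trivially recoverable.
Organ-specific modules elevate the latent location by a factor of 20 in the
module's own organ samples (and damp it elsewhere), so each member gene's
argmax organ is known ground truth.

What this does **not** emulate: count noise (no Poisson/NB sampling),
length biases, batch effects, correlated background structure, or genuine
pseudoalignment. Passing recovery tests therefore demonstrates the
correctness of the correlation/ranking/normalization machinery on data
with known structure — not performance on real corpora.

Per-run fixtures write a consistent abundance table (effective lengths
drawn around 1.5 kb, counts scaled to the requested pseudoaligned total,
TPM recomputed exactly) and run-info JSON; QC populations are constructed
so each failure reason violates exactly one threshold. All generation is a
pure function of the spec, including the seed.

## Pipeline

Stages run in fixed order (acquire → quantify → qc → matrix → network →
organs), each skipped when its declared outputs exist (streaming is
expensive; `--force` recomputes) and each appending a JSON line (stage,
status, counts, elapsed) to the workspace log. Defaults across the whole
configuration mirror the published protocol, so a user with network access
and a kallisto index can replicate a real-corpus study; the test suite and
the demo exercise everything offline at small problem sizes — the demo
uses 3 modules × 10 genes + 60 background genes over 20 runs, and the
reference recovery condition uses a 300 × 50 matrix — chosen as the
smallest sizes at which the planted structure is unambiguous.

## Known limitations

- Library layout must be supplied in the manifest; archive metadata is not
  queried.
- The speed-abort semantics approximate, but are not bit-identical to,
  curl's.
- No between-sample normalization beyond TPM, no clustering, no PNG
  rendering, no full-corpus all-vs-all network persistence.
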