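"""Bait-gene Pearson coexpression neighborhoods and network export.

A single gene of interest (the bait) seeds the network: every other gene
whose expression profile across samples has a Pearson correlation of at
least ``r_min`` (default 0.7) with the bait is a candidate neighbor, and at
most ``k`` (default 50) of them — the highest-correlated — are kept.
Nodes carry a functional-bin annotation (e.g. major Mapman bins) used for
styling; the network serializes to the Cytoscape.js "elements" JSON
dialect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "NetworkParams",
    "AnnotationTable",
    "CoexpressionNetwork",
    "pearson",
    "bait_neighborhood",
    "build_network",
    "export_cyjs",
    "write_edge_list",
    "DEFAULT_STYLE",
    "UNANNOTATED",
]

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"

#: Fallback node style for bins without an explicit entry in the style map.
DEFAULT_STYLE = ("ellipse", "#cccccc")


@dataclass(frozen=True)
class NetworkParams:
    """Neighborhood parameters: bait gene, neighbor cap, correlation floor."""

    bait: str
    max_neighbors: int = 50
    min_pcc: float = 0.7
    log2: bool = False  # correlate log2(TPM+1) instead of raw TPM
    neighbor_edges: bool = True  # include neighbor-neighbor edges >= min_pcc

    def __post_init__(self) -> None:
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if not (-1 < self.min_pcc <= 1):
            raise ValueError("min_pcc must be in (-1, 1]")


class AnnotationTable:
    """Gene id -> functional bin label; unknown genes get ``unannotated``."""

    def __init__(self, mapping: dict[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        for gene, label in (mapping or {}).items():
            label = label.strip()
            if not label:
                raise ValueError(f"empty bin label for gene {gene!r}")
            self._map[gene] = label

    def __getitem__(self, gene: str) -> str:
        return self._map.get(gene, UNANNOTATED)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationTable":
        mapping = {}
        for line in Path(path).read_text().splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            gene, _, label = line.partition("\t")
            mapping[gene.strip()] = label.strip() or UNANNOTATED
        return cls(mapping)


@dataclass
class CoexpressionNetwork:
    """Bait-centered network: nodes with bins, undirected weighted edges."""

    bait: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[tuple[str, str, bool]]:
        return [(n, d.get("bin", UNANNOTATED), bool(d.get("is_bait")))
                for n, d in sorted(self.graph.nodes(data=True))]

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        # undirected edge serialized once, source = lexicographically smaller id
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(d["weight"])))
        return sorted(out)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two expression vectors.

    Returns NaN (an "undefined correlation" signal, not an exception) when
    either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        return float("nan")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def _expression_for_correlation(matrix: ExpressionMatrix,
                                params: NetworkParams) -> np.ndarray:
    values = matrix.values
    if params.log2:
        values = np.log2(values + 1.0)
    return values


def bait_neighborhood(matrix: ExpressionMatrix,
                      params: NetworkParams) -> list[tuple[str, float]]:
    """Rank the bait's coexpression neighborhood.

    All genes g != bait with PCC(bait, g) >= min_pcc, sorted by PCC
    descending then gene id ascending, truncated to max_neighbors.
    Zero-variance genes are excluded (their correlation is undefined); the
    exclusion count is logged.
    """
    genes = matrix.gene_ids
    if params.bait not in matrix.frame.index:
        raise KeyError(f"bait gene {params.bait!r} not in matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = _expression_for_correlation(matrix, params)
    bait_idx = genes.index(params.bait)
    bait_vec = values[bait_idx]
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    if norms[bait_idx] == 0:
        raise ValueError(f"bait gene {params.bait!r} has constant expression")
    n_zero_var = int(np.count_nonzero(norms == 0))
    if n_zero_var:
        logger.info("excluding %d zero-variance genes from the neighborhood",
                    n_zero_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (centered @ centered[bait_idx]) / (norms * norms[bait_idx])
    pcc = np.clip(pcc, -1.0, 1.0)
    candidates = [
        (genes[i], float(pcc[i]))
        for i in range(len(genes))
        if i != bait_idx and norms[i] > 0 and pcc[i] >= params.min_pcc
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[: params.max_neighbors]


def build_network(matrix: ExpressionMatrix,
                  neighborhood: list[tuple[str, float]],
                  params: NetworkParams,
                  annotation: AnnotationTable | None = None,
                  ) -> CoexpressionNetwork:
    """Assemble the annotated network from a ranked neighborhood.

    Edges: bait-neighbor edges weighted by their PCC, plus (by default)
    neighbor-neighbor edges whose pairwise PCC is also >= min_pcc; pass
    ``neighbor_edges=False`` in the params for a bait-only star topology.
    """
    annotation = annotation or AnnotationTable()
    g = nx.Graph()
    g.add_node(params.bait, bin=annotation[params.bait], is_bait=True)
    for gene, w in neighborhood:
        g.add_node(gene, bin=annotation[gene], is_bait=False)
        g.add_edge(params.bait, gene, weight=w)
    if params.neighbor_edges and len(neighborhood) > 1:
        ids = [gene for gene, _ in neighborhood]
        sub = matrix.subset_genes(ids)
        values = _expression_for_correlation(sub, params)
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered * centered).sum(axis=1))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if norms[i] == 0 or norms[j] == 0:
                    continue
                w = float(np.clip(
                    (centered[i] @ centered[j]) / (norms[i] * norms[j]),
                    -1.0, 1.0))
                if w >= params.min_pcc:
                    g.add_edge(ids[i], ids[j], weight=w)
    return CoexpressionNetwork(bait=params.bait, graph=g)


def export_cyjs(network: CoexpressionNetwork,
                style_map: dict[str, tuple[str, str]] | None = None) -> str:
    """Serialize to the Cytoscape.js "elements" JSON dialect.

    Each node's shape and color come from its bin's entry in ``style_map``;
    bins without a style fall back to a default (logged).  Output is
    deterministic: nodes and edges sorted, keys sorted, fixed float
    formatting via repr.
    """
    style_map = style_map or {}
    nodes = []
    for gene, bin_label, is_bait in network.nodes:
        if bin_label in style_map:
            shape, color = style_map[bin_label]
        else:
            shape, color = DEFAULT_STYLE
            if style_map:
                logger.info("no style for bin %r; using default", bin_label)
        nodes.append({"data": {
            "id": gene, "label": gene, "bin": bin_label,
            "shape": shape, "color": color, "is_bait": is_bait,
        }})
    edges = []
    for source, target, weight in network.edges:
        edges.append({"data": {
            "id": f"{source}--{target}", "source": source,
            "target": target, "weight": weight,
        }})
    return json.dumps({"elements": {"nodes": nodes, "edges": edges}},
                      sort_keys=True, indent=1)


def write_edge_list(network: CoexpressionNetwork, path: str | Path) -> None:
    """Flat TSV edge list: source, target, pcc."""
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tpcc\n")
        for source, target, weight in network.edges:
            fh.write(f"{source}\t{target}\t{repr(float(weight))}\n")
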