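"""Organ-level relative expression profiles.

Public-archive sample annotations are free text, so sample selection is
term-list based: a sample is used only if its organ label matches one of
the requested organs (case-insensitive, trimmed) and its genotype and
treatment fields match configurable wild-type / untreated allow-lists.
Per organ, each gene's expression is summarized by the median across the
organ's samples; each gene's row of medians is then divided by its maximum
so the organ of peak expression reads 1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "SampleMetadata",
    "OrganProfile",
    "DEFAULT_ORGANS",
    "WILDTYPE_TERMS",
    "UNTREATED_TERMS",
    "select_samples",
    "organ_medians",
    "normalize_rows",
    "organ_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_ORGANS = ("leaf", "flower", "root", "shoot", "stem")
WILDTYPE_TERMS = ("wild type", "wild-type", "wildtype", "wt")
UNTREATED_TERMS = ("untreated", "none", "control", "")


@dataclass(frozen=True)
class SampleAnnotation:
    organ: str
    genotype: str = ""
    treatment: str = ""


class SampleMetadata:
    """Run accession -> (organ, genotype, treatment) annotations."""

    def __init__(self, annotations: dict[str, SampleAnnotation]) -> None:
        self._map = dict(annotations)

    def __getitem__(self, accession: str) -> SampleAnnotation:
        return self._map[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        """Read a reduced run-selector export: accession, organ, genotype, treatment."""
        annotations = {}
        with Path(path).open() as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                acc = row["accession"].strip()
                if acc in annotations:
                    raise ValueError(f"duplicate accession {acc} in metadata")
                annotations[acc] = SampleAnnotation(
                    organ=row.get("organ", "").strip(),
                    genotype=row.get("genotype", "").strip(),
                    treatment=row.get("treatment", "").strip(),
                )
        return cls(annotations)


@dataclass
class OrganProfile:
    """Gene x organ medians and their row-max-normalized relative values."""

    medians: pd.DataFrame
    relative: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return self.medians.index.tolist()

    @property
    def organs(self) -> list[str]:
        return self.medians.columns.tolist()

    def write_tsvs(self, medians_path: str | Path,
                   relative_path: str | Path) -> None:
        self.medians.to_csv(medians_path, sep="\t", index_label="gene")
        if self.relative is None:
            raise ValueError("relative profile not computed")
        self.relative.to_csv(relative_path, sep="\t", index_label="gene")


def _norm(term: str) -> str:
    return term.strip().lower()


def select_samples(
    metadata: SampleMetadata,
    organs: tuple[str, ...] = DEFAULT_ORGANS,
    wildtype_terms: tuple[str, ...] = WILDTYPE_TERMS,
    untreated_terms: tuple[str, ...] = UNTREATED_TERMS,
) -> dict[str, list[str]]:
    """Group accessions by organ, keeping only wild-type untreated samples.

    Organs with no matching sample are dropped with a warning.
    """
    if not organs:
        raise ValueError("no organs requested")
    wt = {_norm(t) for t in wildtype_terms}
    untreated = {_norm(t) for t in untreated_terms}
    wanted = {_norm(o): o for o in organs}
    groups: dict[str, list[str]] = {o: [] for o in organs}
    for accession, ann in metadata.items():
        organ_key = _norm(ann.organ)
        if organ_key not in wanted:
            continue
        if _norm(ann.genotype) not in wt:
            continue
        if _norm(ann.treatment) not in untreated:
            continue
        groups[wanted[organ_key]].append(accession)
    for organ in list(groups):
        if not groups[organ]:
            logger.warning("no wild-type untreated samples for organ %r; "
                           "dropping it", organ)
            del groups[organ]
    return groups


def organ_medians(matrix: ExpressionMatrix,
                  groups: dict[str, list[str]],
                  genes: list[str] | None = None) -> OrganProfile:
    """Median expression per gene per organ.

    Even sample counts use the midpoint of the two central values; a
    single-sample organ contributes its value directly.  Organs whose
    accessions are absent from the matrix are excluded with a warning.
    """
    genes = genes if genes is not None else matrix.gene_ids
    sub = matrix.subset_genes(list(genes))
    columns = {}
    for organ, accessions in groups.items():
        present = [a for a in accessions if a in sub.frame.columns]
        if not present:
            logger.warning("organ %r has no samples in the matrix; excluded",
                           organ)
            continue
        if len(present) < len(accessions):
            missing = sorted(set(accessions) - set(present))
            raise KeyError(
                f"organ {organ!r} samples missing from matrix: {missing[:5]}"
            )
        columns[organ] = sub.frame[present].median(axis=1)
    if not columns:
        raise ValueError("no organ had samples present in the matrix")
    medians = pd.DataFrame(columns, index=list(genes))
    return OrganProfile(medians=medians)


def normalize_rows(profile: OrganProfile) -> OrganProfile:
    """Divide each gene's medians by its row maximum (all-zero rows stay 0)."""
    medians = profile.medians
    row_max = medians.max(axis=1)
    safe = row_max.replace(0, np.nan)
    relative = medians.div(safe, axis=0).fillna(0.0)
    return OrganProfile(medians=medians, relative=relative)


def organ_profile(matrix: ExpressionMatrix, metadata: SampleMetadata,
                  genes: list[str] | None = None,
                  organs: tuple[str, ...] = DEFAULT_ORGANS,
                  wildtype_terms: tuple[str, ...] = WILDTYPE_TERMS,
                  untreated_terms: tuple[str, ...] = UNTREATED_TERMS,
                  ) -> OrganProfile:
    """Select samples, compute organ medians, and row-normalize, in one call."""
    groups = select_samples(metadata, organs=organs,
                            wildtype_terms=wildtype_terms,
                            untreated_terms=untreated_terms)
    return normalize_rows(organ_medians(matrix, groups, genes=genes))
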