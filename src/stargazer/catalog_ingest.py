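"""Reading PheWAS- and GWAS-style association tables.

Builds the harmonized phenotype list across both catalogs and applies the
significance filter. Rows that cannot be interpreted (blank or non-numeric
odds ratio or p-value, GWAS beta coefficients, out-of-range values) are
dropped with a counted warning rather than aborting the load.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .core_model import (
    AssociationRecord,
    Source,
    ValidationError,
    normalize_trait,
)

__all__ = [
    "Catalog",
    "PhenotypeList",
    "LoadReport",
    "PHEWAS_COLUMNS",
    "GWAS_COLUMNS",
    "read_catalog",
    "write_catalog",
    "build_phenotype_list",
    "filter_significant",
    "records_for_phenotype",
]

logger = logging.getLogger("stargazer")

#: Default column names of the public PheWAS-catalog CSV export.
PHEWAS_COLUMNS: Mapping[str, str] = {
    "variant": "snp",
    "gene": "gene_name",
    "phenotype": "phewas phenotype",
    "odds_ratio": "odds-ratio",
    "p_value": "p",
    "study": "study",
}

#: Minimal GWAS-catalog dialect.
GWAS_COLUMNS: Mapping[str, str] = {
    "variant": "SNPS",
    "gene": "MAPPED_GENE",
    "phenotype": "DISEASE/TRAIT",
    "odds_ratio": "OR or BETA",
    "p_value": "P-VALUE",
    "study": "STUDY ACCESSION",
}

# Multi-gene mapped fields ("GENE1 - GENE2", "A; B", "A, B") split into one
# record per gene. Hyphen splits only with surrounding whitespace so that
# symbols like HLA-DRB1 stay intact.
_GENE_SPLIT = re.compile(r"\s+-\s+|\s*[;,]\s*")


@dataclass
class LoadReport:
    """Summary of a catalog load: how many rows survived and why rows fell."""

    path: str
    n_rows: int = 0
    n_records: int = 0
    dropped: List[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def drop(self, row_index: int, reason: str) -> None:
        self.dropped.append(f"row {row_index}: {reason}")

    def log(self) -> None:
        if self.dropped:
            logger.warning(
                "dropped %d rows while loading %s: %s",
                self.n_dropped,
                self.path,
                "; ".join(self.dropped),
            )


@dataclass
class Catalog:
    """All association records loaded from one source."""

    records: List[AssociationRecord]
    source: Source
    report: Optional[LoadReport] = None

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.source is not self.source:
                raise ValidationError(
                    f"record {rec.variant_id}/{rec.gene} tagged {rec.source} "
                    f"in a {self.source} catalog"
                )

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> frozenset:
        return frozenset(r.gene for r in self.records)

    def traits(self) -> frozenset:
        return frozenset(r.trait_key for r in self.records)


@dataclass(frozen=True)
class PhenotypeList:
    """Deduplicated, lexicographically ordered phenotype keys."""

    traits: tuple

    def __len__(self) -> int:
        return len(self.traits)

    def __iter__(self):
        return iter(self.traits)

    def __contains__(self, trait: str) -> bool:
        return normalize_trait(trait) in self.traits


def _infer_delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_float(raw) -> Optional[float]:
    if raw is None:
        return None
    text = str(raw).strip()
    if not text or text.lower() in {"nan", "na", "none"}:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def read_catalog(
    path,
    source: Source,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
) -> Catalog:
    """Load an association table into a :class:`Catalog`.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row. The delimiter is inferred from the
        extension (``.tsv``/``.tab``/``.txt`` are tab-separated) unless
        ``delimiter`` overrides it.
    source : Source
        Which catalog dialect to expect; chooses the default column names.
    column_map : mapping, optional
        Overrides for the logical column names ``variant``, ``gene``,
        ``phenotype``, ``odds_ratio``, ``p_value`` and (optional) ``study``.

    Rows with a missing or unparseable odds ratio or p-value are dropped and
    counted in the attached :class:`LoadReport`; non-positive effect values
    (beta coefficients in a GWAS export) are likewise dropped since the
    scoring framework is defined on odds ratios only. Multi-gene mapped
    fields yield one record per gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    defaults = PHEWAS_COLUMNS if source is Source.PHEWAS else GWAS_COLUMNS
    colmap: Dict[str, str] = dict(defaults)
    if column_map:
        colmap.update(column_map)

    frame = pd.read_csv(path, sep=_infer_delimiter(path, delimiter), dtype=str)
    if frame.empty and frame.columns.empty:
        raise ValidationError(f"empty catalog file: {path}")

    required = ("variant", "gene", "phenotype", "odds_ratio", "p_value")
    missing = [colmap[k] for k in required if colmap[k] not in frame.columns]
    if missing:
        raise ValidationError(
            f"missing required column(s) {missing} in {path}; "
            f"available headers: {list(frame.columns)}"
        )
    has_study = colmap.get("study") in frame.columns

    report = LoadReport(path=str(path), n_rows=len(frame))
    records: List[AssociationRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        odds_ratio = _parse_float(row[colmap["odds_ratio"]])
        p_value = _parse_float(row[colmap["p_value"]])
        if odds_ratio is None:
            report.drop(idx, "missing or unparseable odds ratio")
            continue
        if p_value is None:
            report.drop(idx, "missing or unparseable p-value")
            continue
        if odds_ratio <= 0:
            report.drop(idx, f"non-positive effect value {odds_ratio} (beta, not an OR)")
            continue
        if not 0.0 <= p_value <= 1.0:
            report.drop(idx, f"p-value {p_value} outside [0, 1]")
            continue
        gene_field = str(row[colmap["gene"]] or "").strip()
        phenotype = str(row[colmap["phenotype"]] or "").strip()
        variant = str(row[colmap["variant"]] or "").strip()
        if not gene_field or gene_field.lower() == "nan":
            report.drop(idx, "missing gene symbol")
            continue
        if not phenotype or phenotype.lower() == "nan":
            report.drop(idx, "missing phenotype")
            continue
        study = str(row[colmap["study"]]).strip() if has_study else None
        if study is not None and (not study or study.lower() == "nan"):
            study = None
        for gene in _GENE_SPLIT.split(gene_field):
            if not gene:
                continue
            records.append(
                AssociationRecord(
                    variant_id=variant,
                    gene=gene,
                    phenotype=phenotype,
                    odds_ratio=odds_ratio,
                    p_value=p_value,
                    source=source,
                    study_id=study,
                )
            )
    report.n_records = len(records)
    report.log()
    return Catalog(records=records, source=source, report=report)


def write_catalog(catalog: Catalog, path) -> None:
    """Write a catalog back to CSV/TSV in its source's default dialect.

    Round-trips with :func:`read_catalog`: re-reading the written file
    yields an identical record list.
    """
    path = Path(path)
    colmap = PHEWAS_COLUMNS if catalog.source is Source.PHEWAS else GWAS_COLUMNS
    rows = [
        {
            colmap["variant"]: r.variant_id,
            colmap["gene"]: r.gene,
            colmap["phenotype"]: r.phenotype,
            colmap["odds_ratio"]: repr(r.odds_ratio),
            colmap["p_value"]: repr(r.p_value),
            colmap["study"]: r.study_id if r.study_id is not None else "",
        }
        for r in catalog.records
    ]
    frame = pd.DataFrame(rows, columns=list(colmap.values()))
    frame.to_csv(path, sep=_infer_delimiter(path, None), index=False)


def build_phenotype_list(phewas: Catalog, gwas: Catalog) -> PhenotypeList:
    """Union of normalized trait labels from both catalogs, deduplicated
    and sorted lexicographically."""
    traits = {r.trait_key for r in phewas.records} | {r.trait_key for r in gwas.records}
    return PhenotypeList(traits=tuple(sorted(traits)))


def filter_significant(
    records: Sequence[AssociationRecord], alpha: float
) -> List[AssociationRecord]:
    """Keep records with ``p_value <= alpha`` (inclusive), preserving order.

    ``alpha`` must lie in (0, 1]; the default threshold used throughout the
    exploration modes is 0.05.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha!r}")
    return [r for r in records if r.p_value <= alpha]


def records_for_phenotype(catalog: Catalog, trait: str) -> List[AssociationRecord]:
    """All records whose normalized phenotype equals the normalized query."""
    if not trait or not trait.strip():
        raise ValidationError("empty trait query")
    key = normalize_trait(trait)
    return [r for r in catalog.records if r.trait_key == key]
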