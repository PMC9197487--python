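"""Aggregate feature vectors into ranked tables and serve the exploration
modes' query logic.

The aggregate score of a gene is the arithmetic mean of its five normalized
feature scores — each feature contributes equally and the maximum possible
score is exactly 1. Targets are ranked by descending score, ties broken by
gene symbol, and one table is produced per allele-class context (all
alleles, risk alleles, protective alleles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import pandas as pd

from .catalog_ingest import Catalog, filter_significant
from .core_model import (
    AssociationRecord,
    Context,
    FeatureVector,
    InteractionNetwork,
    ValidationError,
    classify_allele,
    RankedTarget,
    normalize_gene,
)
from .evidence_providers import ProviderBundle
from .feature_scoring import (
    compute_feature_vectors,
    context_records,
    network_degree_feature,
)

__all__ = [
    "RANKED_TABLE_COLUMNS",
    "SourceMode",
    "RankedTable",
    "PhenotypeAssociationView",
    "PhenotypeTable",
    "PPIView",
    "aggregate",
    "prioritize",
    "gene_view",
    "variant_view",
    "phenotype_view",
    "ppi_view",
]

#: Ranked-table CSV header, in column order.
RANKED_TABLE_COLUMNS = (
    "Gene Name",
    "StarGazer Score",
    "Odds-Ratio",
    "OpenTargets Associations",
    "Indicator Phe/GWAS",
    "Druggability Score",
    "Network Degree Score",
)


class SourceMode:
    """Source selector for the phenotype exploration modes."""

    PHEWAS = "PHEWAS"
    GWAS = "GWAS"
    UNION = "UNION"
    INTERSECTION = "INTERSECTION"
    ALL_MODES = (PHEWAS, GWAS, UNION, INTERSECTION)


def aggregate(features: FeatureVector) -> float:
    """Aggregate score: mean of the five normalized feature scores.

    All five components must lie in [0, 1]; the result then lies in [0, 1]
    with 1 attained only by a gene maximal in every feature. Tabular output
    renders it to 3 decimals; full precision is retained internally.
    """
    components = features.as_tuple()
    for value in components:
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"feature component {value!r} outside [0, 1]")
    return sum(components) / 5.0


@dataclass
class RankedTable:
    """Ranked targets for one phenotype in one allele-class context."""

    phenotype: str
    context: Context
    alpha: float
    rows: List[RankedTarget] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def genes(self) -> frozenset:
        return frozenset(r.gene for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        data = [
            (
                r.gene,
                r.stargazer_score,
                r.features.or_score,
                r.features.opentargets_score,
                r.features.intersection_indicator,
                r.features.druggability_score,
                r.features.network_degree_score,
            )
            for r in self.rows
        ]
        return pd.DataFrame(data, columns=list(RANKED_TABLE_COLUMNS))

    def to_csv(self, path=None) -> Optional[str]:
        """Render as CSV with 3-decimal scores; byte-reproducible."""
        frame = self.to_dataframe()
        for col in RANKED_TABLE_COLUMNS[1:]:
            frame[col] = frame[col].map(lambda v: f"{v:.3f}")
        text = frame.to_csv(index=False, lineterminator="\n")
        if path is None:
            return text
        with open(path, "w", newline="") as fh:
            fh.write(text)
        return None


class ViewRow(NamedTuple):
    phenotype: str
    variant_id: str
    gene: str
    odds_ratio: float
    p_value: float
    allele_class: str
    source: str
    study_id: str


@dataclass
class PhenotypeAssociationView:
    """All phenotype associations of one gene or variant, OR-descending."""

    query: str
    rows: List[ViewRow] = field(default_factory=list)

    COLUMNS = (
        "Phenotype",
        "Variant",
        "Gene Name",
        "Odds-Ratio",
        "P-Value",
        "Allele Class",
        "Source",
        "Study",
    )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def to_csv(self, path=None) -> Optional[str]:
        text = self.to_dataframe().to_csv(index=False, lineterminator="\n")
        if path is None:
            return text
        with open(path, "w", newline="") as fh:
            fh.write(text)
        return None


def _sorted_view_rows(records: Sequence[AssociationRecord]) -> List[ViewRow]:
    rows = [
        ViewRow(
            phenotype=r.phenotype,
            variant_id=r.variant_id,
            gene=r.gene,
            odds_ratio=r.odds_ratio,
            p_value=r.p_value,
            allele_class=classify_allele(r).value,
            source=r.source.value,
            study_id=r.study_id or "",
        )
        for r in records
    ]
    # OR-descending; deterministic tie-break on the remaining identity.
    rows.sort(key=lambda v: (-v.odds_ratio, v.phenotype, v.variant_id, v.source, v.study_id))
    return rows


def prioritize(
    phenotype: str,
    phewas: Catalog,
    gwas: Catalog,
    providers: ProviderBundle,
    alpha: float = 0.05,
) -> Dict[Context, RankedTable]:
    """Rank targets for a phenotype in the ALL, RISK and PROTECTIVE contexts.

    Each context recomputes and renormalizes its own feature vectors over
    its own gene set. A context with no qualifying records yields an empty
    table.
    """
    tables: Dict[Context, RankedTable] = {}
    for context in (Context.ALL, Context.RISK, Context.PROTECTIVE):
        vectors = compute_feature_vectors(
            phenotype, phewas, gwas, providers, alpha=alpha, context=context
        )
        rows = [
            RankedTarget(
                gene=gene,
                stargazer_score=aggregate(fv),
                features=fv,
                allele_class_context=context,
            )
            for gene, fv in vectors.items()
        ]
        rows.sort(key=lambda r: (-r.stargazer_score, r.gene))
        tables[context] = RankedTable(
            phenotype=phenotype, context=context, alpha=alpha, rows=rows
        )
    return tables


def gene_view(
    gene: str, phewas: Catalog, gwas: Catalog, alpha: float = 0.05
) -> PhenotypeAssociationView:
    """All post-filter associations of a gene across both catalogs."""
    key = normalize_gene(gene)
    records = [
        r
        for catalog in (phewas, gwas)
        for r in filter_significant(catalog.records, alpha)
        if r.gene == key
    ]
    return PhenotypeAssociationView(query=key, rows=_sorted_view_rows(records))


def variant_view(
    rsid: str, phewas: Catalog, gwas: Catalog, alpha: float = 0.05
) -> PhenotypeAssociationView:
    """All post-filter associations of a variant across both catalogs."""
    key = rsid.strip()
    records = [
        r
        for catalog in (phewas, gwas)
        for r in filter_significant(catalog.records, alpha)
        if r.variant_id == key
    ]
    return PhenotypeAssociationView(query=key, rows=_sorted_view_rows(records))


@dataclass
class PhenotypeTable:
    """One phenotype's associations in a source mode, with druggability.

    ``druggability_fractions`` reports, over the distinct genes in the
    table, the percentage falling in each druggability category; a gene is
    categorized by its most advanced target development level (Tclin >
    Tchem > Tbio > Tdark > None).
    """

    phenotype: str
    source_mode: str
    alpha: float
    rows: List[tuple] = field(default_factory=list)
    druggability_fractions: Dict[str, float] = field(default_factory=dict)

    COLUMNS = (
        "Variant",
        "Gene Name",
        "Odds-Ratio",
        "P-Value",
        "Allele Class",
        "Source",
        "Druggability Levels",
    )

    def genes(self) -> frozenset:
        return frozenset(row[1] for row in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def to_csv(self, path=None) -> Optional[str]:
        text = self.to_dataframe().to_csv(index=False, lineterminator="\n")
        if path is None:
            return text
        with open(path, "w", newline="") as fh:
            fh.write(text)
        return None

    def format_fractions(self) -> str:
        return ", ".join(
            f"{category}: {pct:.2f}%"
            for category, pct in self.druggability_fractions.items()
        )


def phenotype_view(
    trait: str,
    phewas: Catalog,
    gwas: Catalog,
    providers: ProviderBundle,
    alpha: float = 0.05,
    source_mode: str = SourceMode.UNION,
) -> PhenotypeTable:
    """Associations for a phenotype in one of the source exploration modes.

    PHEWAS / GWAS return that source's post-filter records; UNION their
    concatenation; INTERSECTION only rows whose rsID has post-filter
    records in *both* sources (the intersection is variant-level here,
    unlike the gene-level indicator used for ranking). Every row carries
    the gene's druggability levels, and per-category percentages are
    computed over the distinct genes in the table.
    """
    if source_mode not in SourceMode.ALL_MODES:
        raise ValidationError(
            f"unknown source mode {source_mode!r}; expected one of {SourceMode.ALL_MODES}"
        )
    ph_records, gw_records = context_records(phewas, gwas, trait, alpha, Context.ALL)
    if source_mode == SourceMode.PHEWAS:
        selected = list(ph_records)
    elif source_mode == SourceMode.GWAS:
        selected = list(gw_records)
    elif source_mode == SourceMode.UNION:
        selected = [*ph_records, *gw_records]
    else:  # INTERSECTION on rsID
        shared = {r.variant_id for r in ph_records} & {r.variant_id for r in gw_records}
        selected = [r for r in [*ph_records, *gw_records] if r.variant_id in shared]

    rows = []
    for r in sorted(
        selected, key=lambda r: (-r.odds_ratio, r.variant_id, r.gene, r.source.value)
    ):
        profile = providers.druggability.profile(r.gene)
        rows.append(
            (
                r.variant_id,
                r.gene,
                r.odds_ratio,
                r.p_value,
                classify_allele(r).value,
                r.source.value,
                ";".join(sorted(profile.levels)),
            )
        )

    genes = {r.gene for r in selected}
    fractions: Dict[str, float] = {}
    if genes:
        categories = [providers.druggability.profile(g).top_level() for g in genes]
        for category in ("Tclin", "Tchem", "Tbio", "Tdark", "None"):
            count = categories.count(category)
            if count:
                fractions[category] = 100.0 * count / len(genes)

    return PhenotypeTable(
        phenotype=trait,
        source_mode=source_mode,
        alpha=alpha,
        rows=rows,
        druggability_fractions=fractions,
    )


@dataclass
class PPIView:
    """Interaction networks and degree tables per allele-class context."""

    phenotype: str
    alpha: float
    networks: Dict[Context, InteractionNetwork] = field(default_factory=dict)
    degree_tables: Dict[Context, List[Tuple[str, int, float]]] = field(default_factory=dict)

    DEGREE_COLUMNS = ("Gene Name", "Degree", "Network Degree Score")

    def degree_dataframe(self, context: Context) -> pd.DataFrame:
        return pd.DataFrame(
            self.degree_tables.get(context, []), columns=list(self.DEGREE_COLUMNS)
        )


def ppi_view(
    trait: str,
    phewas: Catalog,
    gwas: Catalog,
    providers: ProviderBundle,
    alpha: float = 0.05,
) -> PPIView:
    """Interaction networks over the ALL / RISK / PROTECTIVE gene sets.

    Each context's network is built over that context's post-filter gene
    set; the degree table reports each node's raw degree and its ratio to
    the network's maximum degree. An empty gene set yields an empty
    network.
    """
    view = PPIView(phenotype=trait, alpha=alpha)
    for context in (Context.ALL, Context.RISK, Context.PROTECTIVE):
        ph_records, gw_records = context_records(phewas, gwas, trait, alpha, context)
        genes = {r.gene for r in [*ph_records, *gw_records]}
        network = providers.build_network(genes)
        ratios = network_degree_feature(network)
        table = [
            (gene, network.degree(gene), ratios.get(gene, 0.0))
            for gene in sorted(genes)
        ]
        table.sort(key=lambda row: (-row[1], row[0]))
        view.networks[context] = network
        view.degree_tables[context] = table
    return view
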