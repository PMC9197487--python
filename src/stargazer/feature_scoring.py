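"""The five per-gene feature scores, each normalized to [0, 1].

For a phenotype's post-filter gene set the pipeline computes:

1. **Odds-ratio score** — per-record association magnitude (the odds ratio
   itself for risk alleles, ``1 - OR`` for protective alleles, where a
   smaller ratio means a stronger protective association), averaged over a
   gene's records, then divided by the largest gene mean in the set.
2. **OpenTargets score** — the raw gene-disease association score divided
   by the largest raw score in the set.
3. **Intersection indicator** — 1 iff the gene has qualifying records in
   both the PheWAS and the GWAS catalog for this phenotype, else 0.
4. **Druggability score** — the number of distinct target development
   levels excluding Tdark (so 0..3), divided by the largest count in the
   set.
5. **Network degree score** — the gene's degree in the interaction network
   built over the gene set, divided by the maximum degree.

Every normalization is max-scaling within the current allele-class context
(ALL / RISK / PROTECTIVE tables are normalized independently), so each
feature attains 1 at some gene unless it is identically zero; a degenerate
all-zero feature scores 0 for every gene rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .catalog_ingest import Catalog, filter_significant, records_for_phenotype
from .core_model import (
    AlleleClass,
    AssociationRecord,
    AssociationScore,
    Context,
    DruggabilityProfile,
    FeatureVector,
    InteractionNetwork,
    classify_allele,
)
from .evidence_providers import ProviderBundle

__all__ = [
    "GeneEvidence",
    "or_magnitude",
    "gene_or_score",
    "opentargets_feature",
    "intersection_feature",
    "druggability_count",
    "druggability_feature",
    "network_degree_feature",
    "context_records",
    "compute_feature_vectors",
]


@dataclass
class GeneEvidence:
    """Everything known about one gene for one phenotype, post-filter."""

    gene: str
    records: List[AssociationRecord] = field(default_factory=list)
    druggability: Optional[DruggabilityProfile] = None
    association: Optional[AssociationScore] = None
    degree: int = 0


def _compatible(record: AssociationRecord, context: Context) -> bool:
    if context is Context.ALL:
        return True
    cls = classify_allele(record)
    return (context is Context.RISK) == (cls is AlleleClass.RISK)


def or_magnitude(record: AssociationRecord, context: Context = Context.ALL) -> Optional[float]:
    """Association magnitude of one record in a context, or None if the
    record's allele class is excluded by the context.

    Risk records contribute the odds ratio as-is; protective records
    contribute ``1 - OR`` so that a smaller ratio maps to a larger
    magnitude. In the ALL context each record contributes its
    class-appropriate magnitude.
    """
    if not _compatible(record, context):
        return None
    if classify_allele(record) is AlleleClass.RISK:
        return record.odds_ratio
    return 1.0 - record.odds_ratio


def _max_normalize(raw: Mapping[str, float]) -> Dict[str, float]:
    """Divide every value by the maximum; an all-zero map stays all zero."""
    if not raw:
        return {}
    top = max(raw.values())
    if top <= 0.0:
        return {gene: 0.0 for gene in raw}
    return {gene: value / top for gene, value in raw.items()}


def gene_or_score(
    records_by_gene: Mapping[str, Sequence[AssociationRecord]],
    context: Context = Context.ALL,
) -> Dict[str, float]:
    """Mean association magnitude per gene, max-normalized over the set.

    Odds ratios from multiple studies of the same gene are averaged before
    normalizing. A gene with no context-compatible record scores 0.
    """
    means: Dict[str, float] = {}
    for gene, records in records_by_gene.items():
        magnitudes = [
            m for m in (or_magnitude(r, context) for r in records) if m is not None
        ]
        means[gene] = sum(magnitudes) / len(magnitudes) if magnitudes else 0.0
    return _max_normalize(means)


def opentargets_feature(raw_scores: Mapping[str, float]) -> Dict[str, float]:
    """Raw gene-disease association scores max-normalized over the gene set."""
    return _max_normalize(dict(raw_scores))


def intersection_feature(gene: str, phewas_genes: Set[str], gwas_genes: Set[str]) -> int:
    """1 iff the gene appears in both catalogs' post-filter gene sets."""
    return 1 if gene in phewas_genes and gene in gwas_genes else 0


def druggability_count(profile: DruggabilityProfile) -> int:
    """Number of distinct druggability levels, Tdark excepted (0..3).

    A target labeled {Tbio, Tclin, Tdark} counts 2: one each for Tbio and
    Tclin, zero for Tdark.
    """
    return len(profile.levels - {"Tdark"})


def druggability_feature(counts: Mapping[str, int]) -> Dict[str, float]:
    """Druggability counts max-normalized over the gene set."""
    return _max_normalize({gene: float(c) for gene, c in counts.items()})


def network_degree_feature(network: InteractionNetwork) -> Dict[str, float]:
    """Node degree as a ratio of the highest degree in the network.

    An edgeless network (max degree 0) scores 0 everywhere.
    """
    degrees = {gene: float(d) for gene, d in network.degrees().items()}
    return _max_normalize(degrees)


def context_records(
    phewas: Catalog,
    gwas: Catalog,
    phenotype: str,
    alpha: float,
    context: Context = Context.ALL,
):
    """Post-filter, context-compatible records for a phenotype, per source.

    Returns ``(phewas_records, gwas_records)`` after the significance
    filter (p <= alpha) and the allele-class restriction.
    """
    ph = [
        r
        for r in filter_significant(records_for_phenotype(phewas, phenotype), alpha)
        if _compatible(r, context)
    ]
    gw = [
        r
        for r in filter_significant(records_for_phenotype(gwas, phenotype), alpha)
        if _compatible(r, context)
    ]
    return ph, gw


def compute_feature_vectors(
    phenotype: str,
    phewas: Catalog,
    gwas: Catalog,
    providers: ProviderBundle,
    alpha: float = 0.05,
    context: Context = Context.ALL,
) -> Dict[str, FeatureVector]:
    """Assemble the five normalized features for a phenotype's gene set.

    The gene set is every gene with at least one record surviving the
    significance filter and compatible with the context; a phenotype with
    no surviving record yields an empty map. Genes absent from a provider
    receive that provider's no-evidence default before normalization.
    """
    ph_records, gw_records = context_records(phewas, gwas, phenotype, alpha, context)
    records_by_gene: Dict[str, List[AssociationRecord]] = {}
    for record in [*ph_records, *gw_records]:
        records_by_gene.setdefault(record.gene, []).append(record)
    if not records_by_gene:
        return {}

    genes = records_by_gene.keys()
    or_scores = gene_or_score(records_by_gene, context)
    ot_scores = opentargets_feature(
        {gene: providers.association.score(gene, phenotype) for gene in genes}
    )
    phewas_genes = {r.gene for r in ph_records}
    gwas_genes = {r.gene for r in gw_records}
    drug_scores = druggability_feature(
        {gene: druggability_count(providers.druggability.profile(gene)) for gene in genes}
    )
    network = providers.build_network(genes)
    degree_scores = network_degree_feature(network)

    return {
        gene: FeatureVector(
            or_score=or_scores[gene],
            opentargets_score=ot_scores[gene],
            intersection_indicator=float(
                intersection_feature(gene, phewas_genes, gwas_genes)
            ),
            druggability_score=drug_scores[gene],
            network_degree_score=degree_scores.get(gene, 0.0),
        )
        for gene in genes
    }
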