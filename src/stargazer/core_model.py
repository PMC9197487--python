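"""Domain types and invariants shared across the prioritization pipeline.

The framework scores candidate drug targets per phenotype from five pieces
of evidence: PheWAS/GWAS odds ratios, an OpenTargets-style gene-disease
association score, presence in both catalogs, Pharos-style druggability
labels (target development levels), and degree centrality in a STRING-style
protein-protein interaction network. Everything downstream joins these
sources on gene symbol and phenotype string, so the normalization rules for
both live here.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import FrozenSet, Optional

import networkx as nx

__all__ = [
    "Source",
    "AlleleClass",
    "Context",
    "TDL_LEVELS",
    "ValidationError",
    "normalize_gene",
    "normalize_trait",
    "AssociationRecord",
    "classify_allele",
    "DruggabilityProfile",
    "AssociationScore",
    "InteractionNetwork",
    "FeatureVector",
    "RankedTarget",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class Source(enum.Enum):
    """Which catalog an association row came from."""

    PHEWAS = "PHEWAS"
    GWAS = "GWAS"


class AlleleClass(enum.Enum):
    """Direction of an association: odds ratio >= 1 is risk, < 1 protective."""

    RISK = "RISK"
    PROTECTIVE = "PROTECTIVE"


class Context(enum.Enum):
    """Allele-class stratum a ranked table is computed over."""

    ALL = "ALL"
    RISK = "RISK"
    PROTECTIVE = "PROTECTIVE"


#: Pharos/TCRD target development levels, in decreasing druggability order.
TDL_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark")

_WS = re.compile(r"\s+")


def normalize_gene(symbol: str) -> str:
    """Canonical join key for gene symbols: trimmed and uppercased.

    Cross-source joins (catalogs vs druggability vs edge lists) compare
    symbols exactly after this normalization.
    """
    return symbol.strip().upper()


def normalize_trait(trait: str) -> str:
    """Canonical phenotype key: trimmed, internal whitespace collapsed,
    case-folded.

    PheWAS and GWAS trait labels differ in casing and spacing for the same
    phenotype; matching is case-insensitive after collapsing runs of
    whitespace.
    """
    return _WS.sub(" ", trait.strip()).casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-phenotype association from a PheWAS- or GWAS-style source.

    Parameters
    ----------
    variant_id : str
        rsID of the variant.
    gene : str
        Gene symbol; normalized (trimmed, uppercased) on construction.
    phenotype : str
        Free-text trait label as reported by the source (matching is done
        through :func:`normalize_trait`).
    odds_ratio : float
        Effect size, strictly positive and dimensionless.
    p_value : float
        Reported significance, in [0, 1].
    source : Source
        Originating catalog.
    study_id : str, optional
        Opaque study identifier, when the source distinguishes studies.
    """

    variant_id: str
    gene: str
    phenotype: str
    odds_ratio: float
    p_value: float
    source: Source
    study_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        object.__setattr__(self, "phenotype", self.phenotype.strip())
        object.__setattr__(self, "variant_id", self.variant_id.strip())
        if not self.gene:
            raise ValidationError(f"empty gene symbol in record {self!r}")
        if not self.phenotype:
            raise ValidationError(f"empty phenotype in record {self!r}")
        if not self.odds_ratio > 0:
            raise ValidationError(
                f"odds ratio must be positive, got {self.odds_ratio!r} "
                f"for {self.variant_id}/{self.gene}"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"p-value must lie in [0, 1], got {self.p_value!r} "
                f"for {self.variant_id}/{self.gene}"
            )

    @property
    def trait_key(self) -> str:
        return normalize_trait(self.phenotype)


def classify_allele(record: AssociationRecord) -> AlleleClass:
    """Classify a record as risk (OR >= 1) or protective (OR < 1).

    The boundary OR = 1 counts as risk. Every valid record belongs to
    exactly one class.
    """
    return AlleleClass.RISK if record.odds_ratio >= 1.0 else AlleleClass.PROTECTIVE


@dataclass(frozen=True)
class DruggabilityProfile:
    """Target development levels attached to one gene.

    ``levels`` is a subset of :data:`TDL_LEVELS`; an empty set means the
    gene is absent from the druggability source ("None" category).
    """

    gene: str
    levels: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        object.__setattr__(self, "levels", frozenset(self.levels))
        unknown = self.levels - set(TDL_LEVELS)
        if unknown:
            raise ValidationError(
                f"unrecognized druggability label(s) {sorted(unknown)} for {self.gene}; "
                f"expected a subset of {list(TDL_LEVELS)}"
            )

    def top_level(self) -> str:
        """Most advanced level in the profile, or ``"None"`` if empty."""
        for level in TDL_LEVELS:
            if level in self.levels:
                return level
        return "None"


@dataclass(frozen=True)
class AssociationScore:
    """Gene-disease association score on the OpenTargets [0, 1] scale."""

    gene: str
    disease: str
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"association score must lie in [0, 1], got {self.score!r} "
                f"for {self.gene}/{self.disease}"
            )


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction graph with confidence-weighted edges.

    Thin wrapper around :class:`networkx.Graph` enforcing the conventions
    of a STRING-style network: no self-loops, one edge per unordered pair,
    confidences on the 0-1000 combined-score scale.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loop edges not allowed: {loops}")

    @classmethod
    def build(cls, nodes, edges=()) -> "InteractionNetwork":
        """Build from an iterable of nodes and (a, b, confidence) triples."""
        g = nx.Graph()
        g.add_nodes_from(normalize_gene(n) for n in nodes)
        for a, b, conf in edges:
            a, b = normalize_gene(a), normalize_gene(b)
            if a == b:
                raise ValidationError(f"self-loop edge on {a}")
            if a not in g or b not in g:
                raise ValidationError(f"edge ({a}, {b}) references unknown node")
            g.add_edge(a, b, confidence=float(conf))
        return cls(g)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        """Number of distinct neighbors of ``gene`` (0 if absent)."""
        gene = normalize_gene(gene)
        return self.graph.degree(gene) if gene in self.graph else 0

    def degrees(self) -> dict:
        return {n: d for n, d in self.graph.degree()}


def _check_unit(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class FeatureVector:
    """The five normalized per-gene feature scores, each in [0, 1].

    Field order matches the ranked-table columns: Odds-Ratio, OpenTargets
    Associations, Indicator Phe/GWAS, Druggability Score, Network Degree
    Score.
    """

    or_score: float
    opentargets_score: float
    intersection_indicator: float
    druggability_score: float
    network_degree_score: float

    def __post_init__(self) -> None:
        for name in (
            "or_score",
            "opentargets_score",
            "intersection_indicator",
            "druggability_score",
            "network_degree_score",
        ):
            object.__setattr__(self, name, _check_unit(name, getattr(self, name)))
        if self.intersection_indicator not in (0.0, 1.0):
            raise ValidationError(
                f"intersection indicator must be 0 or 1, got {self.intersection_indicator!r}"
            )

    def as_tuple(self) -> tuple:
        return (
            self.or_score,
            self.opentargets_score,
            self.intersection_indicator,
            self.druggability_score,
            self.network_degree_score,
        )


@dataclass(frozen=True)
class RankedTarget:
    """A gene with its aggregate score and feature vector in one context."""

    gene: str
    stargazer_score: float
    features: FeatureVector
    allele_class_context: Context = Context.ALL
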