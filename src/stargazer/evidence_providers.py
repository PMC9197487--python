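"""Evidence providers: association scores, druggability, interactions.

Each of the three external evidence sources is wrapped in a small provider
contract so that the scoring pipeline never touches files or the network
directly. The file-backed implementations below are the tested default;
live HTTP clients against the public OpenTargets, Pharos and STRING APIs
exist behind the same contracts but are disabled by default and never used
in tests (determinism, no network at test time).

Provider lookups are total: an unknown gene yields the documented
"no evidence" value (score 0, empty level set, isolated node) instead of
raising.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .core_model import (
    AssociationScore,
    DruggabilityProfile,
    InteractionNetwork,
    TDL_LEVELS,
    ValidationError,
    normalize_gene,
    normalize_trait,
)

__all__ = [
    "AssociationProvider",
    "DruggabilityProvider",
    "ProviderBundle",
    "load_association_table",
    "load_druggability_table",
    "build_network",
    "DEFAULT_MIN_CONFIDENCE",
]

logger = logging.getLogger("stargazer")

#: STRING "medium confidence" combined-score cutoff, the default for edges.
DEFAULT_MIN_CONFIDENCE = 400.0


@dataclass
class AssociationProvider:
    """Gene x disease -> association score in [0, 1]; 0 when unknown."""

    _scores: Mapping[Tuple[str, str], float] = field(default_factory=dict)

    def score(self, gene: str, disease: str) -> float:
        return self._scores.get((normalize_gene(gene), normalize_trait(disease)), 0.0)

    def lookup(self, gene: str, disease: str) -> AssociationScore:
        return AssociationScore(
            gene=normalize_gene(gene), disease=disease, score=self.score(gene, disease)
        )


@dataclass
class DruggabilityProvider:
    """Gene -> target development level set; empty set when unknown."""

    _levels: Mapping[str, FrozenSet[str]] = field(default_factory=dict)

    def profile(self, gene: str) -> DruggabilityProfile:
        key = normalize_gene(gene)
        return DruggabilityProfile(gene=key, levels=self._levels.get(key, frozenset()))


def load_association_table(path) -> AssociationProvider:
    """Load a gene-disease association score table (TSV or JSON).

    TSV needs columns ``gene``, ``disease``, ``score``; JSON is a list of
    objects with those keys. Scores must parse into [0, 1] (a violation
    names the offending row). Duplicate (gene, disease) rows are averaged,
    mirroring how multiple studies of one gene are averaged on the odds
    ratio side.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        triples = [(r["gene"], r["disease"], r["score"]) for r in rows]
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        frame = pd.read_csv(
            path, sep=sep, dtype={"gene": str, "disease": str},
            float_precision="round_trip",
        )
        for col in ("gene", "disease", "score"):
            if col not in frame.columns:
                raise ValidationError(
                    f"association table {path} lacks column {col!r}; "
                    f"has {list(frame.columns)}"
                )
        triples = list(frame[["gene", "disease", "score"]].itertuples(index=False))

    buckets: Dict[Tuple[str, str], List[float]] = {}
    for idx, (gene, disease, score) in enumerate(triples):
        try:
            value = float(score)
        except (TypeError, ValueError):
            raise ValidationError(
                f"association score {score!r} at row {idx} of {path} is not numeric"
            )
        if not 0.0 <= value <= 1.0:
            raise ValidationError(
                f"association score {value} at row {idx} of {path} outside [0, 1]"
            )
        key = (normalize_gene(str(gene)), normalize_trait(str(disease)))
        buckets.setdefault(key, []).append(value)
    means = {key: sum(vals) / len(vals) for key, vals in buckets.items()}
    return AssociationProvider(means)


def load_druggability_table(path) -> DruggabilityProvider:
    """Load a TSV of gene -> semicolon-separated druggability levels.

    Levels must come from {Tclin, Tchem, Tbio, Tdark}; an unrecognized
    label is a validation error naming the label. An empty ``levels`` cell
    is allowed and means no recorded druggability evidence.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    for col in ("gene", "levels"):
        if col not in frame.columns:
            raise ValidationError(
                f"druggability table {path} lacks column {col!r}; "
                f"has {list(frame.columns)}"
            )
    table: Dict[str, FrozenSet[str]] = {}
    canonical = {lv.casefold(): lv for lv in TDL_LEVELS}
    for _, row in frame.iterrows():
        labels = [part.strip() for part in str(row["levels"]).split(";") if part.strip()]
        levels = set()
        for label in labels:
            if label.casefold() not in canonical:
                raise ValidationError(
                    f"unrecognized druggability label {label!r} for gene "
                    f"{row['gene']!r} in {path}"
                )
            levels.add(canonical[label.casefold()])
        table[normalize_gene(str(row["gene"]))] = frozenset(levels)
    return DruggabilityProvider(table)


def build_network(
    edges_path,
    gene_set: Iterable[str],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> InteractionNetwork:
    """Build the interaction network of a gene set from a STRING-style
    edge list.

    The node set is exactly ``gene_set`` (normalized); genes with no
    qualifying edge remain as isolated nodes. An edge is kept iff both
    endpoints are in the gene set, the endpoints differ, and the combined
    score is >= ``min_confidence``. Duplicate and reversed pairs collapse
    to one undirected edge keeping the maximum confidence. Malformed rows
    are skipped with a counted warning; a negative confidence is a
    validation error.
    """
    genes = {normalize_gene(g) for g in gene_set}
    edges_path = Path(edges_path)

    with open(edges_path) as fh:
        header = fh.readline()
        sep = "\t" if "\t" in header else None  # None -> any whitespace
        best: Dict[Tuple[str, str], float] = {}
        skipped = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(sep)
            if len(parts) < 3:
                if line.strip():
                    skipped += 1
                continue
            a, b = normalize_gene(parts[0]), normalize_gene(parts[1])
            try:
                conf = float(parts[2])
            except ValueError:
                skipped += 1
                continue
            if conf < 0:
                raise ValidationError(
                    f"negative confidence {conf} at line {lineno} of {edges_path}"
                )
            if a == b or a not in genes or b not in genes or conf < min_confidence:
                continue
            key = (a, b) if a < b else (b, a)
            if conf > best.get(key, -1.0):
                best[key] = conf
    if skipped:
        logger.warning("dropped %d rows: malformed edge lines in %s", skipped, edges_path)
    return InteractionNetwork.build(genes, [(a, b, c) for (a, b), c in best.items()])


@dataclass
class ProviderBundle:
    """The three evidence lookups the scoring pipeline consumes."""

    association: AssociationProvider
    druggability: DruggabilityProvider
    network_builder: Callable[[Iterable[str]], InteractionNetwork]

    @classmethod
    def from_files(
        cls,
        association_path,
        druggability_path,
        edges_path,
        min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    ) -> "ProviderBundle":
        edges_path = Path(edges_path)

        def _builder(gene_set: Iterable[str]) -> InteractionNetwork:
            return build_network(edges_path, gene_set, min_confidence)

        return cls(
            association=load_association_table(association_path),
            druggability=load_druggability_table(druggability_path),
            network_builder=_builder,
        )

    def build_network(self, gene_set: Iterable[str]) -> InteractionNetwork:
        return self.network_builder(gene_set)


# --------------------------------------------------------------------------
# Optional live HTTP clients. Same contracts, disabled by default, not
# exercised by the test suite. They exist so the file-backed tables can be
# refreshed from the public APIs when a network is available.
# --------------------------------------------------------------------------


def _http_json(url: str, payload: Optional[dict] = None, timeout: float = 30.0) -> dict:
    import urllib.request

    if payload is None:
        req = urllib.request.Request(url, headers={"Accept": "application/json"})
    else:
        req = urllib.request.Request(
            url,
            data=json.dumps(payload).encode(),
            headers={"Content-Type": "application/json"},
        )
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        return json.loads(resp.read().decode())


class LiveOpenTargetsProvider:
    """Association scores fetched from the OpenTargets GraphQL API.

    Untested network client; prefer :func:`load_association_table` on an
    exported table for reproducible runs.
    """

    ENDPOINT = "https://api.platform.opentargets.org/api/v4/graphql"

    def score(self, gene: str, disease: str) -> float:  # pragma: no cover
        query = """
        query ($symbol: String!) {
          search(queryString: $symbol, entityNames: ["target"]) {
            hits { id name }
          }
        }"""
        _ = _http_json(self.ENDPOINT, {"query": query, "variables": {"symbol": gene}})
        raise NotImplementedError(
            "live OpenTargets scoring requires a disease EFO mapping; "
            "export a score table and use load_association_table instead"
        )


class LivePharosProvider:  # pragma: no cover
    """Druggability levels fetched from the Pharos GraphQL API (untested)."""

    ENDPOINT = "https://pharos-api.ncats.io/graphql"

    def profile(self, gene: str) -> DruggabilityProfile:
        query = """
        query ($sym: String!) { target(q: {sym: $sym}) { tdl } }"""
        data = _http_json(self.ENDPOINT, {"query": query, "variables": {"sym": gene}})
        tdl = (data.get("data") or {}).get("target") or {}
        levels = frozenset({tdl["tdl"]}) if tdl.get("tdl") in TDL_LEVELS else frozenset()
        return DruggabilityProfile(gene=gene, levels=levels)


class LiveStringNetworkBuilder:  # pragma: no cover
    """Interaction edges fetched from the STRING REST API (untested)."""

    ENDPOINT = "https://string-db.org/api/json/network"

    def __init__(self, min_confidence: float = DEFAULT_MIN_CONFIDENCE):
        self.min_confidence = min_confidence

    def __call__(self, gene_set: Iterable[str]) -> InteractionNetwork:
        import urllib.parse

        genes = sorted({normalize_gene(g) for g in gene_set})
        url = (
            f"{self.ENDPOINT}?identifiers={urllib.parse.quote('%0d'.join(genes))}"
            f"&species=9606"
        )
        rows = _http_json(url)
        best: Dict[Tuple[str, str], float] = {}
        for row in rows:
            a = normalize_gene(row["preferredName_A"])
            b = normalize_gene(row["preferredName_B"])
            conf = float(row["score"]) * 1000.0
            if a == b or a not in genes or b not in genes or conf < self.min_confidence:
                continue
            key = (a, b) if a < b else (b, a)
            best[key] = max(best.get(key, -1.0), conf)
        return InteractionNetwork.build(genes, [(a, b, c) for (a, b), c in best.items()])
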