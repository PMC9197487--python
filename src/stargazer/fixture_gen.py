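"""Deterministic synthetic-data generator for the whole pipeline.

Writes the five input files (PheWAS CSV, GWAS TSV, association-score
table, druggability table, interaction edge list) with controllable
structure, plus a ground-truth file holding feature vectors and aggregate
scores computed by straight-line arithmetic that shares no code with the
scoring pipeline. Tests compare pipeline output against that independent
arithmetic, so the ground truth is a true oracle, not a regression
snapshot.

The generated data emulates the shape of the real sources — odds ratios
drawn log-normally per allele class, a tunable fraction of variants shared
between the two catalogs, sparse association scores, partial druggability
coverage, a random interaction graph with sub-threshold edges — not their
biology: there is no linkage structure, no study heterogeneity and no
realistic trait vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .core_model import ValidationError

__all__ = ["FixtureSpec", "generate_fixture", "load_insomnia_reference"]

#: Defaults used by the ground-truth computation; they match the pipeline
#: defaults (inclusive p <= 0.05 filter, STRING medium-confidence edges).
GROUND_TRUTH_ALPHA = 0.05
GROUND_TRUTH_MIN_CONFIDENCE = 400.0

_CONTEXTS = ("ALL", "RISK", "PROTECTIVE")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_genes, n_phenotypes, variants_per_gene : int
        Size of the gene/trait universe (all >= 1).
    risk_fraction : float
        Probability that a variant is a risk allele (OR in (1, 5]); the
        rest are protective (OR in [0.2, 1)).
    overlap_fraction : float
        Probability that a variant also appears in the GWAS catalog (with
        an independently drawn OR of the same allele class and the same
        p-value, so catalog overlap is decided here and only here).
    edge_density : float
        Probability that an unordered gene pair has an interaction edge;
        confidences are drawn in [150, 999) so some fall below the default
        400 cutoff.
    seed : int
        Seed for the single random generator; identical specs produce
        byte-identical files.
    """

    n_genes: int = 20
    n_phenotypes: int = 3
    variants_per_gene: int = 3
    risk_fraction: float = 0.6
    overlap_fraction: float = 0.3
    edge_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_phenotypes < 1 or self.variants_per_gene < 1:
            raise ValidationError("n_genes, n_phenotypes and variants_per_gene must be >= 1")
        for name in ("risk_fraction", "overlap_fraction", "edge_density"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def _draw_or(rng: np.random.Generator, risk: bool) -> float:
    if risk:
        return float(min(1.0 + rng.lognormal(mean=-0.3, sigma=0.8), 5.0))
    return float(min(0.9999, max(0.2, 1.0 - rng.lognormal(mean=-1.3, sigma=0.6))))


def _draw_p(rng: np.random.Generator) -> float:
    # 80% of records survive the default 0.05 threshold.
    if rng.random() < 0.8:
        return float(1e-4 + rng.random() * (GROUND_TRUTH_ALPHA - 1e-4))
    return float(0.051 + rng.random() * 0.45)


def generate_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write all input files plus ground truth; return the manifest.

    Files written to ``out_dir``: ``phewas.csv``, ``gwas.tsv``,
    ``associations.tsv``, ``druggability.tsv``, ``edges.tsv``,
    ``ground_truth.json`` and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = [f"GENE{i:03d}" for i in range(spec.n_genes)]
    traits = [f"phenotype {j:02d}" for j in range(spec.n_phenotypes)]

    # ---- association records -------------------------------------------
    # Each row: (variant, gene, trait_index, odds_ratio, p_value, study).
    phewas_rows: List[Tuple[str, str, int, float, float, str]] = []
    gwas_rows: List[Tuple[str, str, int, float, float, str]] = []
    v = 0
    for gi, gene in enumerate(genes):
        for k in range(spec.variants_per_gene):
            variant = f"rs{100000 + v}"
            ti = (gi * spec.variants_per_gene + k) % spec.n_phenotypes
            risk = bool(rng.random() < spec.risk_fraction)
            odds_ratio = _draw_or(rng, risk)
            p_value = _draw_p(rng)
            phewas_rows.append((variant, gene, ti, odds_ratio, p_value, f"phs{v:05d}"))
            if rng.random() < spec.overlap_fraction:
                gwas_or = _draw_or(rng, risk)
                gwas_rows.append((variant, gene, ti, gwas_or, p_value, f"GCST{v:05d}"))
            v += 1

    # ---- association scores (sparse, occasional duplicates) ------------
    assoc_rows: List[Tuple[str, str, float]] = []
    for gene in genes:
        for ti, trait in enumerate(traits):
            if rng.random() < 0.6:
                assoc_rows.append((gene, trait, float(rng.random())))
                if rng.random() < 0.2:
                    assoc_rows.append((gene, trait, float(rng.random())))

    # ---- druggability (partial coverage) -------------------------------
    drugg_rows: List[Tuple[str, str]] = []
    drugg_levels: Dict[str, Set[str]] = {}
    for gene in genes:
        if rng.random() < 0.85:
            levels = {
                level
                for level, prob in (
                    ("Tclin", 0.2),
                    ("Tchem", 0.3),
                    ("Tbio", 0.6),
                    ("Tdark", 0.3),
                )
                if rng.random() < prob
            }
            drugg_rows.append((gene, ";".join(sorted(levels))))
            drugg_levels[gene] = levels

    # ---- interaction edges (plus noise the loader must ignore) ---------
    edge_rows: List[Tuple[str, str, int]] = []
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            if rng.random() < spec.edge_density:
                conf = int(150 + rng.random() * 849)
                edge_rows.append((genes[i], genes[j], conf))
                if rng.random() < 0.15:  # reversed duplicate, lower score
                    edge_rows.append((genes[j], genes[i], max(conf - 100, 0)))
    edge_rows.append((genes[0], genes[0], 999))  # self-loop, must be dropped

    # ---- write files ----------------------------------------------------
    paths = {name: out_dir / name for name in (
        "phewas.csv", "gwas.tsv", "associations.tsv", "druggability.tsv",
        "edges.tsv", "ground_truth.json", "manifest.json",
    )}
    with open(paths["phewas.csv"], "w", newline="") as fh:
        fh.write("snp,gene_name,phewas phenotype,odds-ratio,p,study\n")
        for variant, gene, ti, odds_ratio, p_value, study in phewas_rows:
            fh.write(f"{variant},{gene},{traits[ti]},{odds_ratio!r},{p_value!r},{study}\n")
    with open(paths["gwas.tsv"], "w", newline="") as fh:
        fh.write("SNPS\tMAPPED_GENE\tDISEASE/TRAIT\tOR or BETA\tP-VALUE\tSTUDY ACCESSION\n")
        for variant, gene, ti, odds_ratio, p_value, study in gwas_rows:
            fh.write(
                f"{variant}\t{gene}\t{traits[ti].upper()}\t{odds_ratio!r}\t{p_value!r}\t{study}\n"
            )
    with open(paths["associations.tsv"], "w", newline="") as fh:
        fh.write("gene\tdisease\tscore\n")
        for gene, trait, score in assoc_rows:
            fh.write(f"{gene}\t{trait.title()}\t{score!r}\n")
    with open(paths["druggability.tsv"], "w", newline="") as fh:
        fh.write("gene\tlevels\n")
        for gene, levels in drugg_rows:
            fh.write(f"{gene}\t{levels}\n")
    with open(paths["edges.tsv"], "w", newline="") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, conf in edge_rows:
            fh.write(f"{a}\t{b}\t{conf}\n")

    ground_truth = _ground_truth(
        traits, phewas_rows, gwas_rows, assoc_rows, drugg_levels, edge_rows
    )
    with open(paths["ground_truth.json"], "w", newline="") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "spec": asdict(spec),
        "files": {
            "phewas": "phewas.csv",
            "gwas": "gwas.tsv",
            "associations": "associations.tsv",
            "druggability": "druggability.tsv",
            "edges": "edges.tsv",
            "ground_truth": "ground_truth.json",
        },
        "alpha": GROUND_TRUTH_ALPHA,
        "min_confidence": GROUND_TRUTH_MIN_CONFIDENCE,
        "phenotypes": traits,
        "n_phewas_rows": len(phewas_rows),
        "n_gwas_rows": len(gwas_rows),
        "n_edge_rows": len(edge_rows),
    }
    with open(paths["manifest.json"], "w", newline="") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# --------------------------------------------------------------------------
# Independent ground-truth arithmetic. Deliberately repeats the scoring
# rules in plain loops over the in-memory row tuples, without importing
# anything from the scoring modules, so that a defect there cannot hide in
# a shared helper.
# --------------------------------------------------------------------------


def _ground_truth(traits, phewas_rows, gwas_rows, assoc_rows, drugg_levels, edge_rows):
    result = {
        "alpha": GROUND_TRUTH_ALPHA,
        "min_confidence": GROUND_TRUTH_MIN_CONFIDENCE,
        "phenotypes": {},
    }
    for ti, trait in enumerate(traits):
        per_context = {}
        for context in _CONTEXTS:
            # Post-filter, context-compatible rows for this trait, in file
            # order (PheWAS rows before GWAS rows).
            def keep(row):
                _, _, row_ti, odds_ratio, p_value, _ = row
                if row_ti != ti or p_value > GROUND_TRUTH_ALPHA:
                    return False
                is_risk = odds_ratio >= 1.0
                if context == "RISK":
                    return is_risk
                if context == "PROTECTIVE":
                    return not is_risk
                return True

            ph = [row for row in phewas_rows if keep(row)]
            gw = [row for row in gwas_rows if keep(row)]
            if not ph and not gw:
                per_context[context] = {}
                continue

            magnitudes: Dict[str, List[float]] = {}
            for _, gene, _, odds_ratio, _, _ in [*ph, *gw]:
                value = odds_ratio if odds_ratio >= 1.0 else 1.0 - odds_ratio
                magnitudes.setdefault(gene, []).append(value)
            means = {g: sum(vals) / len(vals) for g, vals in magnitudes.items()}
            top = max(means.values())
            or_scores = {g: (m / top if top > 0.0 else 0.0) for g, m in means.items()}

            gene_set = list(magnitudes.keys())

            raw_assoc: Dict[str, List[float]] = {}
            for gene, row_trait, score in assoc_rows:
                if row_trait == trait and gene in magnitudes:
                    raw_assoc.setdefault(gene, []).append(score)
            assoc_mean = {
                g: (sum(raw_assoc[g]) / len(raw_assoc[g]) if g in raw_assoc else 0.0)
                for g in gene_set
            }
            top = max(assoc_mean.values())
            ot_scores = {
                g: (s / top if top > 0.0 else 0.0) for g, s in assoc_mean.items()
            }

            ph_genes = {row[1] for row in ph}
            gw_genes = {row[1] for row in gw}

            counts = {
                g: float(len(drugg_levels.get(g, set()) - {"Tdark"})) for g in gene_set
            }
            top = max(counts.values())
            drugg_scores = {
                g: (c / top if top > 0.0 else 0.0) for g, c in counts.items()
            }

            neighbors: Dict[str, Set[str]] = {g: set() for g in gene_set}
            for a, b, conf in edge_rows:
                if (
                    a != b
                    and a in neighbors
                    and b in neighbors
                    and conf >= GROUND_TRUTH_MIN_CONFIDENCE
                ):
                    neighbors[a].add(b)
                    neighbors[b].add(a)
            degrees = {g: float(len(ns)) for g, ns in neighbors.items()}
            top = max(degrees.values())
            degree_scores = {
                g: (d / top if top > 0.0 else 0.0) for g, d in degrees.items()
            }

            table = {}
            for g in gene_set:
                fv = (
                    or_scores[g],
                    ot_scores[g],
                    1.0 if (g in ph_genes and g in gw_genes) else 0.0,
                    drugg_scores[g],
                    degree_scores[g],
                )
                table[g] = {
                    "or_score": fv[0],
                    "opentargets_score": fv[1],
                    "intersection_indicator": fv[2],
                    "druggability_score": fv[3],
                    "network_degree_score": fv[4],
                    "stargazer_score": sum(fv) / 5.0,
                }
            per_context[context] = table
        result["phenotypes"][trait] = per_context
    return result


def load_insomnia_reference() -> pd.DataFrame:
    """The published insomnia top-30 prioritization table bundled as
    package data.

    Columns: Gene Name, StarGazer Score, Odds-Ratio, OpenTargets
    Associations, Indicator Phe/GWAS, Druggability Score, Network Degree
    Score. The five feature columns serve as precomputed input vectors for
    regression-testing the aggregation against printed scores.
    """
    with resources.files("stargazer.data").joinpath("insomnia_top30.csv").open() as fh:
        return pd.read_csv(fh)
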