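"""Shared fixtures: a tiny hand-checkable dataset and generated datasets.

``hand_fixture`` is a three-gene insomnia-style dataset whose expected
feature vectors were worked out by independent straight-line arithmetic in
``expected_all`` / ``expected_risk`` / ``expected_protective`` below; the
tests compare pipeline output against those numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from stargazer import (
    Catalog,
    ProviderBundle,
    Source,
    read_catalog,
)

HAND_PHEWAS = """snp,gene_name,phewas phenotype,odds-ratio,p,study
rs1,AAA,insomnia,2.0,0.01,s1
rs2,AAA,insomnia,3.0,0.02,s2
rs3,BBB,insomnia,0.5,0.01,s3
rs4,CCC,insomnia,1.25,0.04,s4
rs5,CCC,insomnia,1.5,0.2,s5
"""

HAND_GWAS = (
    "SNPS\tMAPPED_GENE\tDISEASE/TRAIT\tOR or BETA\tP-VALUE\tSTUDY ACCESSION\n"
    "rs1\tAAA\tInsomnia\t4.0\t0.03\tg1\n"
    "rs6\tBBB\tInsomnia\t0.9\t0.04\tg2\n"
)

HAND_ASSOCIATIONS = "gene\tdisease\tscore\nAAA\tInsomnia\t0.6\nCCC\tinsomnia\t0.3\n"

HAND_DRUGGABILITY = "gene\tlevels\nAAA\tTclin;Tbio;Tdark\nBBB\tTbio\nCCC\t\n"

# AAA-CCC sits below the default 400 cutoff; BBB-AAA duplicates AAA-BBB.
HAND_EDGES = (
    "protein1\tprotein2\tcombined_score\n"
    "AAA\tBBB\t900\n"
    "BBB\tAAA\t700\n"
    "BBB\tCCC\t500\n"
    "AAA\tCCC\t300\n"
)


def _write_hand_files(root: Path) -> dict:
    paths = {
        "phewas": root / "phewas.csv",
        "gwas": root / "gwas.tsv",
        "associations": root / "associations.tsv",
        "druggability": root / "druggability.tsv",
        "edges": root / "edges.tsv",
    }
    paths["phewas"].write_text(HAND_PHEWAS)
    paths["gwas"].write_text(HAND_GWAS)
    paths["associations"].write_text(HAND_ASSOCIATIONS)
    paths["druggability"].write_text(HAND_DRUGGABILITY)
    paths["edges"].write_text(HAND_EDGES)
    return paths


class HandFixture:
    """Three-gene dataset with independently hand-computed expectations."""

    trait = "Insomnia"
    alpha = 0.05

    # ALL context. Magnitudes: AAA [2, 3, 4] -> mean 3; BBB [1-0.5, 1-0.9]
    # -> mean 0.3; CCC [1.25] (rs5 fails the p-filter). Max mean 3.
    # OpenTargets raw: AAA 0.6, BBB 0 (absent), CCC 0.3; max 0.6.
    # Druggability counts: AAA 2 (Tdark ignored), BBB 1, CCC 0.
    # Edges >= 400 within {AAA,BBB,CCC}: AAA-BBB, BBB-CCC -> degrees 1,2,1.
    # AAA and BBB appear in both catalogs, CCC only in PheWAS.
    expected_all = {
        "AAA": ((1.0, 1.0, 1.0, 1.0, 0.5), 4.5 / 5),
        "BBB": ((0.3 / 3.0, 0.0, 1.0, 0.5, 1.0), (0.1 + 0.0 + 1.0 + 0.5 + 1.0) / 5),
        "CCC": ((1.25 / 3.0, 0.5, 0.0, 0.0, 0.5), (1.25 / 3.0 + 0.5 + 0.5) / 5),
    }

    # RISK context: gene set {AAA, CCC}; network has no qualifying edge
    # (AAA-CCC scores 300 < 400), so degree scores are 0.
    expected_risk = {
        "AAA": ((1.0, 1.0, 1.0, 1.0, 0.0), 4.0 / 5),
        "CCC": ((1.25 / 3.0, 0.5, 0.0, 0.0, 0.0), (1.25 / 3.0 + 0.5) / 5),
    }

    # PROTECTIVE context: BBB alone; self-normalized OR score, all-zero
    # OpenTargets, single isolated node.
    expected_protective = {
        "BBB": ((1.0, 0.0, 1.0, 1.0, 0.0), 3.0 / 5),
    }

    def __init__(self, root: Path):
        self.root = root
        self.paths = _write_hand_files(root)
        self.phewas: Catalog = read_catalog(self.paths["phewas"], Source.PHEWAS)
        self.gwas: Catalog = read_catalog(self.paths["gwas"], Source.GWAS)
        self.providers = ProviderBundle.from_files(
            self.paths["associations"],
            self.paths["druggability"],
            self.paths["edges"],
        )


@pytest.fixture(scope="session")
def hand_fixture(tmp_path_factory) -> HandFixture:
    return HandFixture(tmp_path_factory.mktemp("hand"))


@pytest.fixture(scope="session")
def generated_fixture(tmp_path_factory):
    """A mid-size generated dataset with its ground truth, loaded once."""
    from stargazer import FixtureSpec, generate_fixture

    root = tmp_path_factory.mktemp("generated")
    manifest = generate_fixture(FixtureSpec(n_genes=15, seed=11), root)
    phewas = read_catalog(root / "phewas.csv", Source.PHEWAS)
    gwas = read_catalog(root / "gwas.tsv", Source.GWAS)
    providers = ProviderBundle.from_files(
        root / "associations.tsv", root / "druggability.tsv", root / "edges.tsv"
    )
    with open(root / "ground_truth.json") as fh:
        ground_truth = json.load(fh)
    return {
        "root": root,
        "manifest": manifest,
        "phewas": phewas,
        "gwas": gwas,
        "providers": providers,
        "ground_truth": ground_truth,
    }
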