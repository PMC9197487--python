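"""Aggregation, ranking, exploration views and their invariants."""

import pytest

from stargazer import (
    AssociationRecord,
    Catalog,
    Context,
    FeatureVector,
    RANKED_TABLE_COLUMNS,
    Source,
    SourceMode,
    ValidationError,
    aggregate,
    gene_view,
    load_insomnia_reference,
    phenotype_view,
    ppi_view,
    prioritize,
    variant_view,
)


def _fv(*components):
    return FeatureVector(*components)


@pytest.mark.parametrize(
    "components,expected",
    [
        ((0.725, 0.000, 0.000, 1.000, 0.556), 0.456),  # published HLA-DRB1 row
        ((0.000, 0.150, 0.000, 0.500, 0.667), 0.263),  # published DRD2 row
        ((1.0, 1.0, 1.0, 1.0, 1.0), 1.0),  # stated maximum
        ((0.0, 0.0, 0.0, 0.0, 0.0), 0.0),
    ],
)
def test_aggregate_is_mean_of_five(components, expected):
    assert round(aggregate(_fv(*components)), 3) == expected


def test_aggregate_reproduces_all_published_insomnia_rows():
    """Mean of the five printed feature columns matches the printed score
    within the precision the published table supports.

    Each printed feature is rounded to 3 decimals, so it is within 0.0005
    of its true value and their mean inherits that bound; the printed
    aggregate carries another 0.0005 of rounding. The tightest bound the
    printed numbers guarantee is therefore ±0.001.
    """
    table = load_insomnia_reference()
    assert list(table.columns) == list(RANKED_TABLE_COLUMNS)
    for row in table.itertuples(index=False):
        gene, printed, *features = row
        assert aggregate(_fv(*features)) == pytest.approx(printed, abs=1e-3), gene


def test_aggregate_rejects_out_of_range_components():
    good = _fv(0.5, 0.5, 1.0, 0.5, 0.5)
    bad = FeatureVector.__new__(FeatureVector)  # bypass constructor checks
    object.__setattr__(bad, "or_score", 1.5)
    for name in ("opentargets_score", "intersection_indicator",
                 "druggability_score", "network_degree_score"):
        object.__setattr__(bad, name, 0.0)
    assert aggregate(good) == pytest.approx(0.6)
    with pytest.raises(ValidationError):
        aggregate(bad)


def test_prioritize_matches_hand_computed_tables(hand_fixture):
    tables = prioritize(
        hand_fixture.trait,
        hand_fixture.phewas,
        hand_fixture.gwas,
        hand_fixture.providers,
        alpha=hand_fixture.alpha,
    )
    for context, expected in (
        (Context.ALL, hand_fixture.expected_all),
        (Context.RISK, hand_fixture.expected_risk),
        (Context.PROTECTIVE, hand_fixture.expected_protective),
    ):
        table = tables[context]
        assert table.genes() == set(expected)
        scores = [r.stargazer_score for r in table.rows]
        assert scores == sorted(scores, reverse=True)
        for row in table.rows:
            exp_features, exp_score = expected[row.gene]
            assert row.features.as_tuple() == pytest.approx(exp_features, abs=1e-15)
            assert row.stargazer_score == pytest.approx(exp_score, abs=1e-15)


def test_risk_and_protective_gene_sets_partition_all(hand_fixture):
    tables = prioritize(
        hand_fixture.trait,
        hand_fixture.phewas,
        hand_fixture.gwas,
        hand_fixture.providers,
    )
    assert (
        tables[Context.RISK].genes() | tables[Context.PROTECTIVE].genes()
        == tables[Context.ALL].genes()
    )


def test_unknown_phenotype_yields_empty_tables(hand_fixture):
    tables = prioritize(
        "narcolepsy", hand_fixture.phewas, hand_fixture.gwas, hand_fixture.providers
    )
    assert all(len(t) == 0 for t in tables.values())


def test_tied_genes_rank_alphabetically():
    records = [
        AssociationRecord("rs1", "ZZZ", "insomnia", 2.0, 0.01, Source.PHEWAS),
        AssociationRecord("rs2", "AAA", "insomnia", 2.0, 0.01, Source.PHEWAS),
    ]
    phewas = Catalog(records=records, source=Source.PHEWAS)
    gwas = Catalog(records=[], source=Source.GWAS)

    class _NoEvidence:
        class association:
            @staticmethod
            def score(gene, disease):
                return 0.0

        class druggability:
            @staticmethod
            def profile(gene):
                from stargazer import DruggabilityProfile

                return DruggabilityProfile(gene, frozenset())

        @staticmethod
        def build_network(genes):
            from stargazer import InteractionNetwork

            return InteractionNetwork.build(genes)

    tables = prioritize("insomnia", phewas, gwas, _NoEvidence)
    genes = [r.gene for r in tables[Context.ALL].rows]
    assert genes == ["AAA", "ZZZ"]  # identical vectors, alphabetical order


def test_ranked_csv_is_byte_reproducible(hand_fixture, tmp_path):
    outputs = []
    for run in range(2):
        tables = prioritize(
            hand_fixture.trait,
            hand_fixture.phewas,
            hand_fixture.gwas,
            hand_fixture.providers,
        )
        target = tmp_path / f"run{run}.csv"
        tables[Context.ALL].to_csv(target)
        outputs.append(target.read_bytes())
    assert outputs[0] == outputs[1]
    header = outputs[0].decode().splitlines()[0]
    assert header == ",".join(RANKED_TABLE_COLUMNS)


def test_gene_view_sorted_by_odds_ratio(hand_fixture):
    view = gene_view("aaa", hand_fixture.phewas, hand_fixture.gwas, alpha=0.05)
    assert [row.odds_ratio for row in view.rows] == [4.0, 3.0, 2.0]
    assert {row.source for row in view.rows} == {"PHEWAS", "GWAS"}
    assert gene_view("NOPE", hand_fixture.phewas, hand_fixture.gwas).rows == []


def test_gene_view_rows_shrink_with_alpha(hand_fixture):
    loose = gene_view("CCC", hand_fixture.phewas, hand_fixture.gwas, alpha=0.5)
    tight = gene_view("CCC", hand_fixture.phewas, hand_fixture.gwas, alpha=0.05)
    loose_keys = {(r.variant_id, r.phenotype) for r in loose.rows}
    tight_keys = {(r.variant_id, r.phenotype) for r in tight.rows}
    assert tight_keys < loose_keys


def test_variant_view_carries_source_tags(hand_fixture):
    view = variant_view("rs1", hand_fixture.phewas, hand_fixture.gwas)
    assert [(r.source, r.odds_ratio) for r in view.rows] == [
        ("GWAS", 4.0),
        ("PHEWAS", 2.0),
    ]
    assert all(r.allele_class == "RISK" for r in view.rows)
    assert variant_view("rs999", hand_fixture.phewas, hand_fixture.gwas).rows == []


def test_phenotype_view_union_concatenates_sources(hand_fixture):
    union = phenotype_view(
        "insomnia", hand_fixture.phewas, hand_fixture.gwas, hand_fixture.providers,
        source_mode=SourceMode.UNION,
    )
    ph = phenotype_view(
        "insomnia", hand_fixture.phewas, hand_fixture.gwas, hand_fixture.providers,
        source_mode=SourceMode.PHEWAS,
    )
    gw = phenotype_view(
        "insomnia", hand_fixture.phewas, hand_fixture.gwas, hand_fixture.providers,
        source_mode=SourceMode.GWAS,
    )
    assert len(union.rows) == len(ph.rows) + len(gw.rows)


def test_phenotype_view_intersection_matches_on_rsid(hand_fixture):
    inter = phenotype_view(
        "insomnia", hand_fixture.phewas, hand_fixture.gwas, hand_fixture.providers,
        source_mode=SourceMode.INTERSECTION,
    )
    # rs1 is the only variant with post-filter records in both catalogs
    assert {row[0] for row in inter.rows} == {"rs1"}
    assert len(inter.rows) == 2  # the PheWAS and the GWAS record for rs1


def test_phenotype_view_druggability_fractions():
    records = [
        AssociationRecord(f"rs{i}", g, "asthma", 1.5, 0.01, Source.PHEWAS)
        for i, g in enumerate(["AAA", "BBB", "CCC", "DDD"])
    ]
    phewas = Catalog(records=records, source=Source.PHEWAS)
    gwas = Catalog(records=[], source=Source.GWAS)

    class _OneTclin:
        class druggability:
            @staticmethod
            def profile(gene):
                from stargazer import DruggabilityProfile

                levels = {"Tclin"} if gene == "AAA" else set()
                return DruggabilityProfile(gene, frozenset(levels))

    view = phenotype_view("asthma", phewas, gwas, _OneTclin, source_mode=SourceMode.PHEWAS)
    assert view.druggability_fractions["Tclin"] == pytest.approx(25.0)
    assert view.druggability_fractions["None"] == pytest.approx(75.0)
    assert "Tclin: 25.00%" in view.format_fractions()


def test_phenotype_view_rejects_unknown_mode(hand_fixture):
    with pytest.raises(ValidationError):
        phenotype_view(
            "insomnia", hand_fixture.phewas, hand_fixture.gwas,
            hand_fixture.providers, source_mode="BOTH",
        )


def test_ppi_view_degree_tables(hand_fixture):
    view = ppi_view(
        "insomnia", hand_fixture.phewas, hand_fixture.gwas, hand_fixture.providers
    )
    # ALL network: path AAA - BBB - CCC (AAA-CCC fails the 400 cutoff)
    all_table = {gene: (deg, ratio) for gene, deg, ratio in view.degree_tables[Context.ALL]}
    assert all_table == {"AAA": (1, 0.5), "BBB": (2, 1.0), "CCC": (1, 0.5)}
    # RISK genes {AAA, CCC} have no qualifying edge between them
    assert view.networks[Context.RISK].n_edges == 0
    # PROTECTIVE set is {BBB} alone
    assert view.networks[Context.PROTECTIVE].nodes == {"BBB"}
    assert (
        view.networks[Context.ALL].nodes
        == view.networks[Context.RISK].nodes | view.networks[Context.PROTECTIVE].nodes
    )


def test_ranking_is_permutation_of_gene_set(generated_fixture):
    trait = generated_fixture["manifest"]["phenotypes"][0]
    tables = prioritize(
        trait,
        generated_fixture["phewas"],
        generated_fixture["gwas"],
        generated_fixture["providers"],
    )
    expected_genes = set(generated_fixture["ground_truth"]["phenotypes"][trait]["ALL"])
    assert tables[Context.ALL].genes() == expected_genes
    assert len(tables[Context.ALL].rows) == len(expected_genes)
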