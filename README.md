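# stargazer-prioritizer

Multi-evidence drug-target prioritization. For a phenotype of interest,
the package integrates four kinds of evidence about each associated gene —
PheWAS/GWAS odds ratios, an OpenTargets-style gene–disease association
score, Pharos-style target development levels (druggability), and degree
centrality in a STRING-style protein–protein interaction network — into
five normalized feature scores and one aggregate *StarGazer score* used to
rank candidate targets for drug discovery and repositioning. It is aimed
at computational biologists doing exploratory target triage across many
phenotypes at once.

## The scoring model

For the gene set *G* of a phenotype (every gene with an association
surviving the significance filter *p* ≤ α, default α = 0.05), five
features are computed per gene *g* and max-normalized within *G*:

1. **Odds-ratio score.** Each association contributes a magnitude: the
   odds ratio OR itself for risk alleles (OR ≥ 1), and 1 − OR for
   protective alleles (OR < 1, where a smaller ratio means a stronger
   protective association). Magnitudes from multiple studies of the same
   gene are averaged, then each gene's mean is divided by the largest mean
   in *G*.
2. **OpenTargets score.** The raw gene–disease association score
   (∈ [0, 1]) divided by the largest raw score in *G*.
3. **Intersection indicator.** 1 if *g* has qualifying associations in
   both the PheWAS and the GWAS catalog for this phenotype, else 0.
4. **Druggability score.** The number of distinct target development
   levels of *g*, counting Tclin, Tchem and Tbio but not Tdark (so
   {Tbio, Tclin, Tdark} counts 2), divided by the largest count in *G*.
5. **Network degree score.** deg(*g*) / max<sub>*G*</sub> deg in the
   interaction network built over *G* (edges kept at combined score ≥ 400
   by default).

The aggregate score is the arithmetic mean of the five features,

&nbsp;&nbsp;&nbsp;&nbsp;S(*g*) = (f₁ + f₂ + f₃ + f₄ + f₅) / 5 ∈ [0, 1],

and three independently normalized ranked tables are produced per
phenotype: all alleles, risk alleles only, protective alleles only.

## Worked example

Generate a deterministic synthetic dataset and rank targets for one of
its phenotypes:

```bash
stargazer simulate --seed 7 --n-genes 8 --out demo/
stargazer prioritize --phenotype "phenotype 00" \
    --phewas demo/phewas.csv --gwas demo/gwas.tsv \
    --associations demo/associations.tsv \
    --druggability demo/druggability.tsv --edges demo/edges.tsv \
    --out demo/ranked/
head -5 demo/ranked/prioritization_all.csv
```

prints

```text
Gene Name,StarGazer Score,Odds-Ratio,OpenTargets Associations,Indicator Phe/GWAS,Druggability Score,Network Degree Score
GENE002,0.737,0.997,0.690,1.000,1.000,0.000
GENE003,0.733,1.000,0.000,1.000,0.667,1.000
GENE004,0.654,0.937,0.000,1.000,0.333,1.000
GENE001,0.555,0.776,1.000,0.000,0.000,1.000
```

Reading the top row: GENE002's mean association magnitude is 99.7% of the
strongest in the set, its association score is 69% of the best, it has
qualifying variants in both catalogs (indicator 1), it carries the most
druggability levels in the set (score 1), and it is isolated in the
interaction network (degree score 0); the mean of those five numbers is
its aggregate score 0.737. The same command also writes the risk-only and
protective-only tables, each renormalized over its own gene set.

The other exploration modes work the same way from the shell: `gene` and
`variant` list all phenotype associations of one gene or rsID ranked by
odds ratio; `phewas`, `gwas`, `union` and `intersection` list a
phenotype's associations per source (intersection matches variants by
rsID across both catalogs) together with per-gene druggability levels;
`ppi` writes the degree tables of the interaction networks over the
all/risk/protective gene sets. Every mode accepts `--alpha` to tighten or
relax the significance filter and writes plain CSV.

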