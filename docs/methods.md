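# Methods

## Scope and model

The package ranks candidate drug targets per phenotype by combining four
evidence sources into five per-gene feature scores and their mean. The
evidence sources are file-backed tables in the dialects of their public
counterparts: a PheWAS-catalog-style CSV and a GWAS-catalog-style TSV of
variant–phenotype associations (rsID, gene, trait, odds ratio, p-value,
study), an OpenTargets-style gene–disease association score table, a
Pharos-style table of target development levels (TDL: Tclin > Tchem >
Tbio > Tdark), and a STRING-style interaction edge list with combined
scores on the 0–1000 scale. Live HTTP clients for the public APIs exist
behind the same provider contracts but are disabled by default and never
used by the tests; reproducible runs use exported tables.

The model's central assumptions, inherited from its design:

- **Evidence is gene-centric.** Variants are the unit of association
  evidence but scoring happens per gene; multi-gene mapped variants
  contribute one record per gene.
- **Odds-ratio magnitudes.** A risk association (OR ≥ 1, the boundary
  counted as risk) contributes OR; a protective association (OR < 1)
  contributes 1 − OR, so that a smaller ratio means a larger magnitude.
  The protective magnitude is capped at 1 by construction while risk
  magnitudes are unbounded; the all-alleles table mixes the two scales.
  This asymmetry is inherent to the scoring rule, not an implementation
  artifact.
- **Equal feature weight.** Each of the five features is max-normalized
  to [0, 1] within the current gene set and the aggregate is their
  arithmetic mean, so each feature contributes at most 0.2. The division
  by five is required for the stated maximum score of 1 and is confirmed
  by the published per-row arithmetic.
- **Context stratification.** Three tables are computed per phenotype —
  all alleles, risk only, protective only — each with its own gene set
  and its own normalization denominators. The gene-level PheWAS/GWAS
  intersection indicator is likewise evaluated within the context's
  record sets. (The variant-level intersection used by the exploration
  mode matches rsIDs across catalogs instead; the two intentionally
  differ in granularity.)

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `alpha` | significance filter, keep records with p ≤ α (inclusive) | 0.05 | the convention used throughout the published analyses; boundary inclusion is our choice where unstated |
| `min_confidence` | minimum combined score for an interaction edge | 400 | STRING's "medium confidence" convention; the source analysis names no cutoff |
| TDL counting | levels counted toward druggability | Tclin, Tchem, Tbio (not Tdark) | Tdark encodes absence of knowledge, not druggability |
| tie-break | equal aggregate scores | gene symbol ascending | determinism; unstated upstream |

Gene symbols are uppercased and trimmed on ingest and joined exactly
thereafter; trait labels are matched case-insensitively after trimming
and collapsing internal whitespace. No fuzzy trait matching is attempted:
"Type II diabetes" and "Type 2 diabetes" remain distinct phenotypes.

## Numerical choices and degenerate inputs

- Max-normalization divides by the largest value in the gene set; if a
  feature is identically zero over the set, every gene scores 0 for it
  (never NaN), keeping all components in [0, 1] and the aggregate safe.
- Duplicate (gene, disease) association rows are averaged, mirroring the
  averaging of odds ratios over multiple studies of one gene.
- Duplicate or reversed interaction edges collapse to one undirected edge
  keeping the maximum confidence; self-loops are rejected.
- Unknown genes are total lookups: association score 0, empty level set,
  isolated node. Rows with unparseable odds ratios or p-values — and GWAS
  effect values ≤ 0, which are beta coefficients rather than odds ratios —
  are dropped with a counted warning.
- Scores are kept at full float precision internally and rendered to
  3 decimals in CSV output; CSV writing is byte-reproducible (fixed
  formats, `\n` line endings).

## Synthetic data and what it shows

`fixture_gen` generates all five input files deterministically from a
seed: odds ratios drawn log-normally per allele class (risk in (1, 5],
protective in [0.2, 1)), p-values mixed so about 80% of records survive
α = 0.05, a tunable fraction of variants present in both catalogs (the
GWAS copy keeps the same p-value and allele class so catalog overlap is
controlled by exactly one knob), sparse association scores with
occasional duplicate rows, partial druggability coverage, and a random
interaction graph including sub-threshold and reversed-duplicate edges
that the loaders must handle. Alongside the inputs it writes a
ground-truth file with feature vectors and aggregate scores computed by
straight-line arithmetic that deliberately shares no code with the
scoring modules, so pipeline-vs-ground-truth comparisons are true oracle
tests (they agree to within 1e-12 across seeds and gene-set sizes in the
suite; in practice they agree exactly).

The generator emulates the *shape* of the real sources, not their
biology: no linkage disequilibrium, no allele frequencies, no study
heterogeneity or realistic trait vocabulary. Passing tests demonstrate
that the arithmetic and the plumbing are correct, not that the ranking is
biologically validated on live catalogs.

Test problem sizes — datasets of 3–50 genes and a few phenotypes, twenty
seeds for the oracle sweep — were chosen as the smallest sets that
exercise every code path (both allele classes, both catalogs, isolated
and connected genes, degenerate all-zero features) while keeping the
suite quick to run.

## Known limitations

- The published prioritization table is reproduced from its printed
  feature columns, which are rounded to 3 decimals; the tightest
  guarantee printed data supports for the recomputed mean is ±0.001, and
  one row (HLA-DQB1) indeed lands 0.0006 from its printed score.
- Trait-vocabulary harmonization across sources is string normalization
  only; clinical-vocabulary mapping (ICD, EFO) is out of scope.
- Druggability uses one source and reflects the current landscape only;
  the network feature uses raw degree, not any diffusion or centrality
  measure beyond it.
- Catalog p-values are filtered as reported, with no multiple-testing
  correction, matching the upstream design.
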