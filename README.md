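# preydna

Decontamination and diet statistics for COI-metabarcoding prey data from
predator feces.

The package turns raw ASV-by-sample read-count matrices (two primer sets,
two technical replicates each, with extraction/PCR blanks and a
mock-community sample) into per-individual prey presence/absence, then
runs the full suite of sex-difference diet statistics on the result. A
synthetic-data generator with known ground truth makes every stage
testable end to end without external data.

## Components

| module | what it does |
|---|---|
| `preydna.data_model` | domain types, TSV readers/writers, validation |
| `preydna.synthetic_data` | seeded generator for complete synthetic experiments + ground truth |
| `preydna.decontamination` | the filter cascade: negative-control filter, confidence-threshold taxonomy resolution, ASV→taxon collapse, replicate-consistency filter, non-target removal, mock-calibrated tag-jump estimation/filter, primer-set merge, exclusions, presence conversion |
| `preydna.prevalence_stats` | Clopper–Pearson intervals, two-sided Fisher tests (minimum-likelihood rule), Holm–Bonferroni, order-level prevalence with CI-overlap flags, richness, tie-corrected Mann–Whitney, BCa bootstrap |
| `preydna.community_stats` | presence/absence Bray–Curtis, one-way PERMANOVA, multivariate dispersion homogeneity, accumulation curves, hypergeometric rarefaction, assemblage randomization test |
| `preydna.cli` | `preydna simulate | clean | prevalence | community | all` |

## CLI

Generate a synthetic experiment, clean it, and run all statistics:

```sh
preydna all --simulate --seed 7 --out run/
```

This writes `run/simulated/` (count tables, taxonomy, metadata, ground
truth), `run/cleaned/presence.tsv`, `run/report.json` (per-stage read
tracking and estimated tag-jump rates), `run/table1.tsv` (prevalence/CI/
Fisher/Holm table), `run/community.json` (mean Bray–Curtis with BCa CI,
PERMANOVA, dispersion, richness, assemblage test), accumulation curves as
long-format TSV, and a `manifest.json` that reproduces the run
bit-identically.

Individual stages:

```sh
preydna simulate --config sim.yaml --out data/ --seed 1
preydna clean --in data/ --config filter.yaml --out cleaned/ --report report.json
preydna prevalence --presence cleaned/presence.tsv --meta cleaned/metadata.tsv \
    --taxonomy data/taxonomy.tsv --top 10 --out table1.tsv
preydna community --presence cleaned/presence.tsv --meta cleaned/metadata.tsv \
    --permutations 10000 --ecotest-iterations 200 --randomizations 1000 \
    --seed 1 --out community.json
```

All configuration is YAML; statistical defaults are alpha = 0.05, 10,000
PERMANOVA permutations, 200 assemblage-test iterations, 1,000 accumulation
randomizations.

## Input formats

Tab-separated UTF-8 text:

- `counts.<primer>.<rep>.tsv` — `asv_id` column then one integer column
  per sample.
- `taxonomy.tsv` — per ASV: `<rank>_label` and `<rank>_conf` for
  kingdom…species, plus `is_mock`.
- `metadata.tsv` — `sample_id, role, sex, primer_set, replicate` with
  role ∈ {specimen, negative_control, mock}; sex is `NA` unless the row
  is a specimen.

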