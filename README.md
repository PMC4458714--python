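# apmskit

Tools for AP-MS (affinity-purification mass-spectrometry) interactor
discovery from spectral counts, together with genomic interval correlation
statistics, driven end-to-end by a synthetic-data generator so every stage
runs without external downloads.

The pipeline stages, each a module with a matching CLI sub-command:

| module      | role |
|-------------|------|
| `decoydb`   | concatenated target + contaminant + reversed-decoy search databases; tryptic digestion semantics |
| `psmfilter` | linear-discriminant scoring of PSMs, per-class (charge × tryptic termini × modification) target/decoy histograms, score thresholds at a requested peptide FDR |
| `protinfer` | peptide-to-protein mapping, redundant-protein grouping, parsimony subset removal, two-peptide rule, protein-level FDR from decoys |
| `counts`    | unique/shared spectral-count tallies and proportional shared-peptide splitting into corrected counts |
| `diffinter` | beta-binomial likelihood-ratio test of bait vs pooled controls with Benjamini–Hochberg adjustment; bait-normalized treatment-effect classification with optional expression-ratio correction |
| `intervals` | BED interval merging, coverage fractions, Jaccard/projection tests, absolute/relative midpoint-distance statistics with relocation permutation nulls, partition annotation |
| `synthgen`  | deterministic synthetic FASTA / PSM / count / interval inputs with hidden-truth sidecars |

## CLI

All commands hang off one entry point:

```sh
# generate a full synthetic fixture set
apmskit synthgen all --seed 7 --outdir fixtures/

# build a search database with reversed decoys
apmskit decoydb build --organism org.fasta --contaminants cont.fasta \
    --out db.fasta --prefix REV_

# filter PSMs to 1% peptide FDR, with a per-class threshold report
apmskit psmfilter run --psms fixtures/psms.tsv --fdr 0.01 \
    --out confident.tsv --report classes.tsv

# infer protein groups from the confident PSMs
apmskit protinfer run --psms confident.tsv --db fixtures/search_db.fasta \
    --out groups.tsv

# call confident interactors (bait vs pooled controls, BH FDR < 0.2)
apmskit diffinter call --counts fixtures/counts.tsv \
    --meta fixtures/counts_meta.json --fdr 0.2 --out interactors.tsv

# classify treatment effects after bait normalization
apmskit diffinter treat --counts fixtures/counts.tsv \
    --meta fixtures/counts_meta.json --treatment rnase --alpha 0.05 \
    --out rnase_effects.tsv

# interval correlation report and partition annotation
apmskit intervals corr --query fixtures/query.bed --ref fixtures/reference.bed \
    --genome fixtures/chrom_sizes.tsv --nperm 999 --seed 7 --out report.json
apmskit intervals annotate --sites sites.bed --partition states.bed
```

## Conventions

* Genomic intervals are 0-based half-open (BED); adjacent intervals merge
  by default.
* Permutation tests require an explicit seed and never report p = 0
  (rendered as `< 1/(n_perm+1)`).
* Corrected spectral counts are kept as reals and rounded half-up only
  where a count likelihood needs integers.
* All simulation utilities are deterministic given a seed; per-generator
  RNG streams are derived from the master seed by fixed offsets.
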