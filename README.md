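# crossgwas

Cross-species GWAS integration pipeline: mixed-model association of a
quantitative phenotype (airway-responsiveness slope) across inbred mouse
strains, gene-window mapping of mouse hits onto human orthologs, screening
of human GWAS summary statistics, and direction-aware replication
meta-analysis. A seeded synthetic-data generator produces every input kind
with known ground truth, so the whole pipeline is testable offline.

## Modules

| module        | what it does |
|---------------|--------------|
| `synthetic`   | haplotype-block inbred strain panels, dose–response phenotypes with a kinship-structured genetic component, multi-study human summary statistics with AR(1) local correlation, homology maps, JSON truth records |
| `phenotype`   | per-animal OLS slope of resistance vs log10(methacholine dose); per-strain mean/SEM summaries; fold change |
| `emma`        | monomorphic/singleton SNP filtering, IBS kinship, single-variance-component REML (grid + bracketed refinement over ln δ), per-SNP GLS t-tests (exact or null-δ approximate mode), Bonferroni threshold, genomic inflation factor |
| `homology`    | gene-window annotation of association hits (1-based inclusive coordinates, boundary-inclusive windows), mouse→human ortholog mapping with dropped-gene reporting, span arithmetic |
| `integration` | union-over-ancestry-streams candidate screening, minor-allele-count filter, genotype/phenotype concordance (point-biserial + rank-sum), regional multi-SNP support counts |
| `meta`        | allele harmonization (incl. strand complement and A/T–C/G ambiguity flags), direction-aware one-sided p conversion, Fisher's combined probability method (log-scale, underflow-safe), sample-size-weighted z meta-analysis, replication report tables |

## Command line

```bash
# write a fully simulated fixture set (ground truth in truth.json)
crossgwas simulate --out fixtures --seed 4 --n-strains 31 --n-snps 2000 \
    --causal 1050:0.8 --study EVE:12000:combined --study SLLI:1200:combined

# phenotype: per-strain slope summaries from dose-response readings
crossgwas pheno --dose-response fixtures/dose_response.tsv --out strains.tsv

# mixed-model association on strain mean slopes
crossgwas assoc --pheno strains.tsv --geno fixtures/genotypes.tsv \
    --out assoc.tsv --mode exact

# ortholog mapping + human summary-statistic screen
crossgwas integrate --mouse-assoc assoc.tsv \
    --human-stats fixtures/summary_stats.tsv \
    --homology fixtures/homology_map.tsv \
    --out candidates.tsv --window 50000 --pmouse 0.001 --phuman 0.001

# direction-aware replication table with Fisher combined p-values
crossgwas meta --stats fixtures/summary_stats.tsv --reference EVE \
    --snps snps.txt --out table.tsv
```

All interchange formats are plain TSV (see `crossgwas/io.py`); genotype
calls use the inbred additive coding {0, 2} with `NA` for missing, and all
coordinates are 1-based inclusive.

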