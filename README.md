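# notchtrunc

Tested, reusable downstream analysis for NOTCH1-class truncating
rearrangements: post-calling variant quality filters, rule-based structural
variant (SV) consequence annotation against a gene/domain model, the
intracellular/extracellular (ICD/ECD) exon-coverage ratio, single-nucleus QC
with doublet-cluster removal and an endothelial-normalized
target/NRARP expression-ratio statistic, and bulk cross-cohort comparisons
(TMM + log-CPM). Everything runs on synthetic data with planted,
recoverable truth — no restricted-access sequencing data required.

## Modules

| module | what it does |
| --- | --- |
| `notchtrunc.synthetic_data` | generates every pipeline input (gene model, SV call sets, exon coverage, single-nucleus counts) with known planted effects; serializes to GFF3/BEDPE/TSV/MTX |
| `notchtrunc.variant_filters` | pass/fail quality rules: substitutions need ASMD ≥ 140 and CLPM = 0; indels need quality ≥ 300; rearrangements need an assembly score or ≥ 4 (tumour) / ≥ 25 (normal) supporting reads |
| `notchtrunc.sv_consequence` | breakend location, activating-truncation classification (transmembrane exon spared → gamma-secretase candidate; bracketed by an inversion → unknown → transcription-complex candidate), negative-regulator promoter/whole-gene disruption, rule-based driver calling (hotspots, recessive footprints, focal CN < 1 Mb with CN > 4 diploid / > 8 tetraploid) |
| `notchtrunc.domain_expression` | per-exon normalized coverage, ICD (exons 29–34) / ECD (exons 1–27) ratio, rank-sum group comparisons with BH adjustment |
| `notchtrunc.single_nucleus` | QC (1000 ≤ genes ≤ 7500, mito < 10%), doublet-cluster removal (over-cluster, drop clusters with mean score > 0.1), ln(1 + 10⁴·c/total) normalization, co-expression gating, marker tables (≥ 10% detection, log2FC ≥ 0.2, Bonferroni ≤ 0.05), per-nucleus target/NRARP ratios normalized by per-sample endothelial medians, rank-sum + BH group tests |
| `notchtrunc.bulk_stats` | TMM scaling factors (30%/5% trims, inverse-variance weights), log-CPM, cohort comparisons, rank-based DE with intersection across data sets |
| `notchtrunc.stats` | shared rank-sum test (exact permutation for small groups, tie-corrected normal approximation otherwise), Benjamini–Hochberg, Bonferroni |

## CLI

```sh
notchtrunc simulate --scenario case1 --seed 7 --out fixtures/        # also: case2, decoys, artifacts, counts, coverage, all
notchtrunc filter-variants --in fixtures/variants.tsv --report report.tsv
notchtrunc sv-annotate --model fixtures/model.gff3 --sv fixtures/sv.bedpe --out calls.tsv
notchtrunc domain-ratio --coverage fixtures/coverage.tsv --out ratios.tsv
notchtrunc sn-qc --counts fixtures/ --out filtered/
notchtrunc sn-ratio --counts fixtures/ --targets HEYL,HEY1,HEY2,HES1,HES4,HES5 \
    --denominator NRARP --reference endothelial --out tests.tsv
notchtrunc bulk-compare --counts c.tsv --cohorts l.tsv --gene NOTCH1 --index-cohort reninoma --out out.tsv
```

## Conventions

- Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts
  to 1-based inclusive at the boundary, BEDPE stays 0-based half-open.
- Exons are transcript-ordered (exon 1 = transcript 5′ end); on the minus
  strand genomic starts decrease with exon index. Intron *k* lies between
  exons *k* and *k*+1.
- Promoter windows default to 2 kb upstream of the TSS in transcript
  orientation (configurable).
- The domain ratio uses unweighted per-exon means by default; a pooled
  (length-weighted) mode is available via `pooled=True` / `--pooled`.
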