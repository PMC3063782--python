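# promark

Integrative analysis of a promoter histone mark (H3K4me3-style ChIP-seq)
against gene expression (RNA-seq), built around the enrichment architecture
seen at active transcription start sites: a smaller pre-TSS peak, a
nucleosome-free dip just upstream of the TSS (near −100 bp), and a dominant
post-TSS peak near +400 bp that grows higher and broader at strongly induced
genes under treatment.

The package is aimed at epigenomics analysts who want a small, fully tested,
end-to-end reference pipeline — including a synthetic-data generator that
plants this architecture, so every stage is verifiable against known truth
without external data.

## What it computes

Starting from aligned single-end tags (BED6 or minimal SAM) and a
refFlat-style gene table:

1. **Tag processing** — multi-mappers removed, duplicates (same chromosome,
   5′ position, strand) collapsed, then the larger of each library pair is
   randomly sub-sampled so treatment and control enter the caller at equal
   depth.
2. **Peak calling** — the genome is tiled into 100 bp consolidating windows;
   per window a one-sided Poisson tail test compares the treatment tag count
   against the depth-scaled input rate λ = max(scaled input count, global
   input mean per window). Significant windows within one window-width merge
   into candidate regions, and a region is a *qualified peak* iff

   * region tag count ≥ 40,
   * log2((T + 1)/(C + 1)) ≥ 1.0 (T, C = region treatment / scaled input tallies),
   * region-level Poisson p < 0.05.

   The overall error rate is estimated empirically by swapping treatment and
   input and re-calling: FDR = swapped peaks / forward peaks.
3. **Peak comparison** — peak lists from two conditions are chained by ≥1 bp
   overlap into union ("combined") regions; fold change per region is
   re-tallied from the depth-matched tag libraries, fold = (T + 1)/(C + 1).
   Regions are annotated to every gene whose TSS ± 5,000 bp window they
   overlap, keeping the highest fold per gene.
4. **RNA quantification** — reads are counted against each gene's exon
   union (ambiguous and intergenic reads discarded and tallied), normalized
   as RPKM = count / (exon kb) / (mapped reads / 10⁶); genes with treated
   RPKM > 1.5 are ranked by fold induction = RPKM_t / (RPKM_c + pseudo),
   with pseudo the RPKM of a single read; the top 50 are reported.
5. **Metagene profiling** — per 100 bp bin across TSS ± 5,000 bp, the number
   of tag *base pairs* overlapping the bin is summed over a gene set,
   strand-oriented so +x always points downstream of transcription; profile
   pairs are compared by peak height ratio and width at half maximum.

## Worked example

Run the whole pipeline on a reduced synthetic scenario (20 genes on 2 Mb,
45k ChIP tags per condition, 40k input tags):

```python
from promark import PipelineConfig, SyntheticGenomeSpec, run_pipeline

cfg = PipelineConfig(
    outdir="demo", seed=3,
    genome=SyntheticGenomeSpec(chrom_sizes={"chr1": 2_000_000}, n_genes=20),
    n_treat_tags=45_000, n_control_tags=45_000, n_input_tags=40_000,
    rna_library_size=2_000_000, n_top=10, n_highcov_induced=2,
)
res = run_pipeline(cfg)
print(res.truth.marquee)
print(open("demo/integrated_table.tsv").read())
```

prints the planted marquee inductions

```
{'gene0002': 54.64, 'gene0004': 24.6, 'gene0006': 12.97, 'gene0008': 9.2}
```

and the integrated table (genes ranked by estimated expression fold, joined
with the best within-TSS-span peak fold):

```
gene	rank	peak_fold	expression_fold
gene0002	1	2.20	40.33
gene0004	2	2.84	25.96
gene0006	3	2.13	9.00
gene0008	4	3.00	6.77
gene0012	5	2.13	3.10
gene0010	6	2.39	3.04
gene0000	7	1.32	1.52
...
```

The four marquee genes occupy the top four ranks in planted order (their
estimated folds are noisy at this reduced depth — gene0002's planted 54.64
comes back as 40.33 because its control library holds only a handful of
reads), the planted 2× ChIP enrichment boost shows up as peak folds above 2,
and the rest of the table hovers at fold ≈ 1. This run calls 24 treated and
20 control peaks (23 combined regions) with a sample-swap FDR of 0.0 in both
conditions; `demo/` also receives library bookkeeping, peak BEDs, matched
regions, expression and profile TSVs, and `report.json`.

The same pipeline is exposed on the command line (`promark run-all`,
plus per-stage subcommands `simulate`, `filter`, `callpeaks`, `compare`,
`quantify`, `integrate`, `profile` that communicate only through files).

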