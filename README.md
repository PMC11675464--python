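# qtlome

Quality control, genome-window density, and enrichment analysis of livestock
QTL annotation catalogs.

## The problem

Public QTL databases (AnimalQTLdb-style catalogs) accumulate hundreds of
thousands of quantitative trait locus annotations for cattle, pigs, sheep and
chickens — intervals on a reference genome, each tied to a phenotypic trait
(organized as class → type → trait) and to the study that reported it.  The
raw catalogs are noisy: annotations are duplicated across submissions, some
lack coordinates or carry impossible ones, and interval lengths range from a
single base to hundreds of megabases.  Before any question about the genomic
*distribution* of QTL can be asked — are QTL where the genes are? which
windows hold more QTL than their gene content predicts? which regions are
hotspots for a specific trait? — the catalog has to be cleaned, merged, and
standardized, and the statistical machinery has to be calibrated.

`qtlome` implements that full workflow for researchers in livestock genomics,
together with a synthetic-catalog generator with known ground truth, so every
stage is testable without external downloads.

## The method

1. **Quality control** (`qtlome.qc_merge`) — remove annotations without
   coordinates, with anomalous positions (start ≥ end, start < 0), outside
   chromosome bounds, or longer than 10 Mbp; collapse exact duplicates
   (same position, trait and study); merge same-study/same-trait annotations
   that overlap ≥ 1 bp or lie < 500 kbp apart, replacing clusters whose span
   exceeds 1 Mbp by their densest 1 Mbp windows (covering ≥ 30% of the span);
   finally standardize every interval into the 250 kbp – 1 Mbp band around
   its midpoint.  A ledger accounts for every input record, and the cascade
   is idempotent.
2. **Windows and density** (`qtlome.windowing`) — tile each chromosome at
   0.25/1/2.5/5 Mbp, assign each QTL/gene/SNP to the window holding its
   midpoint (counts always sum to catalog totals), and report per-chromosome
   median densities and the fraction of the genome covered by the union of
   QTL intervals.
3. **Correlations** (`qtlome.correlation_stats`) — Pearson correlations with
   seeded permutation p-values (n = 1000, two-sided,
   p = (1 + #{|r*| ≥ |r|}) / (n+1)): per chromosome, r(QTL, genes) and
   r(QTL, chromosome size); per window within each chromosome, r at every
   scale, summarized by the mean of per-chromosome correlations r̄
   (chromosomes with < 10 windows excluded); and r between window QTL counts
   and the distinct studies/traits per window (pleiotropy signal).
4. **Enrichment** (`qtlome.enrichment_stats`) — exact two-sided binomial
   tests per chromosome (n = total QTL, p = chromosome length / genome
   length, expectation n·p) and per 1 Mbp window (p = genes in window /
   total genes); hypergeometric upper-tail tests per (window, trait label)
   pair, with q−1/m/n/k parameterized as: labelled QTL in the window, all
   QTL in the window, the rest of the catalog, and the label's catalog
   total.  All families are Benjamini–Hochberg adjusted.
5. **Overlap resampling** (`qtlome.overlap_permutation`) — unique QTL are
   reduced to 250 kbp midpoint-centered intervals and their overlap count
   with a gene set of interest (major genes, top-30 reported candidate
   genes) is compared with 1000 resampled gene sets or random length-matched
   genomic segments; p = (1 + #{null ≥ observed}) / (n+1), with a z-score
   against the null distribution.
6. **Synthetic catalogs** (`qtlome.simulate`) — multi-chromosome genomes
   with inhomogeneous gene density, a study/trait hierarchy, a QTL placement
   mixture (uniform / gene-proportional / planted hotspot windows with
   fold-enrichment λ), SNP-type point records, and injected duplicates,
   coordinate anomalies and over-long intervals at known rates.

## Worked example

```python
from qtlome import (SimConfig, Hotspot, simulate_genome, simulate_qtl_records,
                    run_qc, make_grid, count_features, genome_coverage,
                    window_enrichment, trait_window_enrichment)

cfg = SimConfig(seed=42, n_chromosomes=4,
                chromosome_lengths=[12_000_000, 9_000_000, 6_000_000, 4_000_000],
                n_genes=800, n_qtl=1200,
                hotspots=(Hotspot("chr1", 3_000_000, 5.0, trait_label="trait_001"),))
assembly, genes = simulate_genome(cfg)
_, catalog, truth = simulate_qtl_records(cfg, assembly, genes)

clean, ledger, _ = run_qc(catalog, assembly)
print(f"records in: {ledger.input_total}, out: {ledger.output_total}")
print(f"duplicates removed: {ledger.duplicate}, merged away: {ledger.merged_away}")

grid = count_features(make_grid(assembly, 1_000_000), clean, genes)
print(f"genome coverage: {100 * genome_coverage(clean, assembly).fraction:.1f}%")

tests, _ = window_enrichment(grid)
for t in tests:
    if t.direction == "enriched" and t.p_adj < 0.05:
        print(f"enriched window {t.unit}: observed {t.observed}, "
              f"expected {t.expected:.1f}, BH p = {t.p_adj:.2e}")

for t in trait_window_enrichment(grid, clean, level="trait"):
    if t.window == "chr1:3000000-4000000" and t.p_adj < 0.05:
        print(f"trait hotspot {t.window} [{t.trait_label}]: "
              f"{t.q_obs}/{t.m} QTL, BH p = {t.p_adj:.2e}")
```

prints

```
records in: 1380, out: 1032
duplicates removed: 120, merged away: 168
genome coverage: 99.7%
enriched window chr1:3000000-4000000: observed 59, expected 19.3, BH p = 4.91e-12
trait hotspot chr1:3000000-4000000 [trait_001]: 41/59 QTL, BH p = 7.06e-20
```

The generator planted a 5× hotspot on chr1 at 3–4 Mbp, forcing the trait
label `trait_001` on its hotspot draws; the window binomial test recovers
the window (59 QTL observed against a gene-share expectation of 19.3), and
the hypergeometric trait test recovers the label concentration (41 of the
window's 59 QTL carry the planted trait).  The QC ledger recovers the 120
injected duplicate records exactly.

## Command line

```sh
qtlome simulate -c sim.yaml --out bundle/     # emit a synthetic input bundle
qtlome all -c run.yaml                        # QC → windows → correlations →
                                              # enrichment → traits → overlap
```

Each stage writes plain TSV tables plus a JSON manifest with input hashes and
the QC ledger; re-running an identical configuration is byte-identical.

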