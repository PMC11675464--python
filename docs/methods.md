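# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, the numerical conventions, and the limits of what the
synthetic-data experiments can show.

## Coordinate conventions

All coordinates are 0-based half-open internally (`length = end − start`),
converted from/to the GFF convention (1-based inclusive) only at I/O.  QTL
records missing coordinates are parsed and *flagged*, never silently
dropped: the QC ledger is the single place where records leave the analysis,
and it must account for every input record
(`input = output + Σ removals + net merge reduction`).

The attribute keys of the QTL GFF dialect (which key carries the trait name,
trait class/type, study identifier, associated gene) are not formally
standardized across catalog exports, so the key map is configurable
(`read_qtl_gff(attr_map=...)`); defaults follow the common AnimalQTLdb
export (`trait`, `trait_type`, `trait_class`, `PUBMED_ID`, `gene_ID`), and
unrecognized keys are preserved in a passthrough map.

## Quality control

Thresholds (all configurable in `QCConfig`):

| parameter          | default  | meaning                                        |
|--------------------|----------|------------------------------------------------|
| `max_qtl_length`   | 10 Mbp   | longer annotations are discarded as uninformative intervals |
| `merge_gap`        | 500 kbp  | same-study/same-trait records closer than this chain together (strict `<`) |
| `merge_span_cap`   | 1 Mbp    | a chained cluster collapses to one record only up to this span |
| `min_std_length`   | 250 kbp  | point records (SNP associations) expand to this length |
| `max_std_length`   | 1 Mbp    | over-long residuals trim to this length        |
| `min_span_coverage`| 0.30     | densest-window fallback must cover this share of a long cluster span |

Removal rules fire in a fixed order (missing coordinates → anomalous
position → out of bounds → over-length → duplicate → merged), and the first
matching rule wins, so ledger categories are disjoint by construction.

The duplicate key is (chromosome, start, end, trait name, study id) —
annotations of the same interval for *different* traits or from different
studies are biologically distinct and are kept.  A `position`-only key is
available (`dedup_key="position"`) for counting unique intervals
irrespective of trait.

**Densest-window fallback.**  When a merged cluster spans more than
`merge_span_cap`, candidate 1 Mbp tiles are anchored at the span start with
a 500 kbp step; each is scored by the number of member midpoints it holds;
tiles are chosen greedily by descending score (ties: leftmost), skipping
overlaps, until the selected length reaches 30% of the span.  The tiling
anchor, step, midpoint scoring, and greedy selection are this package's
construction — the window size and coverage floor are the method's fixed
points, but the placement rule is a design choice, and ties are resolved by
coordinates rather than input order so the cascade is order-independent.

**Idempotence via a fixed point.**  Expansion of a short record to 250 kbp
can shrink the gap between two same-study/same-trait records from ≥ 500 kbp
to below the merge threshold, so a single merge→standardize pass is not a
projection.  The cascade therefore iterates merge→standardize until the
record list stops changing.  The loop terminates: after the first pass every
group member is a standardized interval, and any re-chaining of k ≥ 2 such
records replaces them with at most ⌈0.45k − 0.15⌉ < k windows, so the
record count strictly decreases.  The fixed point makes the full cascade
exactly idempotent, which is what lets re-analysis of an already published
cleaned catalog be a no-op.

## Windows and counting

Chromosomes are tiled gap-free at 0.25/1/2.5/5 Mbp; the final window may be
partial and is flagged.  Every feature is counted in exactly **one** window
— the one containing its midpoint — rather than in every window it touches.
This makes window counts sum to the catalog total at every scale, which the
hypergeometric trait test requires (its counts are draws from one finite
population), and makes counts at nested scales aggregate exactly.  The
alternative (any-overlap counting) would inflate counts for long QTL in
proportion to their length.

Medians use the conventional mean-of-central-pair rule.  Genome coverage is
the length of the union of QTL intervals divided by assembly length.

## Correlations

Pearson correlations throughout.  p-values come from a one-vector
permutation test with a two-sided tail and the add-one correction
`p = (1 + #{|r*| ≥ |r|}) / (n_perm + 1)` (default n_perm = 1000), so p is
never 0 and is reproducible under the configured seed; per-test seeds are
derived from one global seed by hashing the test label (CRC-32), keeping
streams uncorrelated across tests while remaining a pure function of
(seed, label).

Constant count vectors make the correlation undefined; such cells are
*excluded* (and marked) rather than recorded as r = 0, because zeros would
bias the per-scale mean r̄ toward the null.  Chromosomes with fewer than 10
windows at a scale are excluded for the same stability reason.

## Enrichment

*Chromosome level*: QTL count ~ Binomial(n, p) with p the chromosome's
genome-length share; the exact test is two-tailed (the pmf-comparison
definition with the standard 1 + 1e−7 relative tolerance), so depletion —
characteristic of sex chromosomes in real catalogs — is detected alongside
enrichment.  Expectation is exactly n·p.

*Window level*: p is the window's share of genes, so a window is judged
against its local gene content, not its length.  Windows with zero genes
have an undefined null and are skipped and reported; substituting a
pseudo-count floor would silently change the null hypothesis.  Partial
windows are tested by default (their gene share shrinks with them, so the
null adapts); a `min_window_fraction` parameter can exclude them.

*Trait level*: for a label with k catalog QTL and a window with m QTL out
of N total, the labelled count in the window is hypergeometric;
P(X ≥ q) is the upper tail (enrichment only — depletion of a sparse label
in a small window carries no information).  Tests are emitted only for
(window, label) pairs with q ≥ 1.

*Multiple testing*: Benjamini–Hochberg throughout.  Families: one family
per assembly for chromosome tests and for window tests; one family per
(level, label) across windows for the trait tests, matching how per-trait
Manhattan panels are read.  `bh_family="global"` pools all trait tests
instead; per-label is the default because label families differ in size by
orders of magnitude and pooling lets dense labels dominate the adjustment.

## Overlap resampling

Unique QTL are standardized to 250 kbp midpoint-centered intervals (shifted
inward at chromosome ends so lengths stay exact).  The statistic is the
number of QTL intervals touching ≥ 1 bp of the gene set; each QTL counts
once however many genes it touches.  Null modes: `random_genes` draws
same-size gene subsets from the annotation (preserves gene length and
clustering structure; the default), `random_segments` places length-matched
segments uniformly on the assembly, redrawing placements that would run past
a chromosome end.  The enrichment alternative is one-tailed upper with the
add-one correction; depletion is available via `alternative="less"`.

## Synthetic catalogs

The generator emulates the structure the pipeline assumes, at desk scale:

* chromosome lengths log-normal (default median 16 Mbp, σ = 0.35, 8
  chromosomes) or fixed lists; real livestock genomes are two orders of
  magnitude larger, so defaults trade size for run time while keeping
  dozens of 1 Mbp windows per chromosome;
* genes placed by a piecewise-constant inhomogeneous intensity (log-normal
  segment multipliers, σ = 0.6) to mimic non-uniform gene density;
* QTL placement is a mixture: uniform-by-length, gene-proportional (the QTL
  midpoint is set to a random gene's midpoint, so when this component has
  all the mass, window counts are exactly multinomial with the gene-share
  law — the window binomial test's null), and hotspot (mass f_hot spread
  over the planted windows proportional to their fold-enrichment λ);
* 79% of QTL are 1 bp SNP-type records (the dominant record type in real
  catalogs); the rest have log-uniform lengths in 5 kbp – 5 Mbp;
* a Zipf-weighted study and trait assignment (exponent 0.8) reproduces the
  few-studies-report-most-QTL skew; a trait hierarchy assigns each trait to
  a type and class; hotspots may force a trait label on their draws,
  planting a recoverable (window, trait) signal;
* defects are injected as corrupted *copies* appended to the clean records
  — exact duplicates (10%), coordinate anomalies (3%, cycling through
  missing coordinates, zero span, negative start, unknown chromosome,
  past-the-end), and over-long intervals (2%) — so the clean set remains
  the truth baseline and the QC ledger can be checked for exact recovery.

What the generator does **not** emulate: linkage disequilibrium (real QTL
from one GWAS peak are spatially autocorrelated beyond the duplicate/merge
structure), breed effects, assembly gaps, and the heavy-tailed interval
lengths of legacy linkage studies.  Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated generative
model, not the field validity of any specific biological finding.

## Experiment sizes

The automated experiments run at sizes chosen to make their statistical
assertions sharp: null calibration of the window binomial test pools ~6,000
windows from 300 replicate genomes (2,000 point QTL on 20 Mbp, pure
gene-proportional placement); overlap-test calibration uses 300 seeded runs
sized so the null overlap count disperses widely (sd ≈ 25) — with a tightly
tied discrete statistic the add-one permutation p-value is visibly
conservative, which would confound a calibration check; power experiments
use 100 replicates of a λ = 5 window hotspot (~1–2% of genes, 2,000 genome
QTL) and a λ = 3 trait hotspot (≥ 50 labelled QTL), both required to be
detected after BH at 0.05 in ≥ 90% of replicates.

## Known limitations

* The densest-window fallback is one admissible reading of "select the
  densest 1 Mbp windows covering ≥ 30% of the segment"; other anchorings
  (e.g. sliding per-bp windows) would select slightly different tiles.
* Window enrichment treats windows as independent; adjacent windows share
  QTL structure in real data, and no spatial autocorrelation correction is
  applied.
* The permutation correlation test permutes one vector with a two-sided
  tail; one-sided variants and permuting both vectors are not exposed.
* Exact binomial/hypergeometric p-values are computed in double precision;
  agreement with enumeration oracles is verified to 1e−10 for populations
  up to 200.
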