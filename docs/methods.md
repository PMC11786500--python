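# Methods

## Input model and the counting hierarchy

`scxci` consumes a per-read table of phased heterozygous chrX observations:
chromosome, 1-based position, observed base, haplotype label (H1/H2), cell
barcode, UMI, optional read id. Haplotype labels come from read-backed
phasing of a single sample; they are arbitrary per sample and carry no
parental-origin or cross-sample meaning. The table dialect is a 7-column
TSV with a mandatory `#` header, UTF-8, no quoting; `#` lines are comments.
SAM/BAM input can be converted with `ingest_alignments`, which emits one
record per aligned read base matching either phased allele at a supplied
het site (reads lacking CB/UB tags, unmapped reads, and third-allele bases
are counted and skipped).

Three nested counting layers are kept strictly separate, because droplet
scRNA-seq inflates molecules into PCR duplicates:

* **barcoding frequency** — raw reads at a position, a pure coverage
  measure; it includes reads whose UMI group is haplotype-conflicted;
* **X1 / X2** — UMI-collapsed molecule counts per allele; a (position,
  barcode, UMI) group counts only if its reads unanimously support one
  haplotype, otherwise it is discarded and tallied as a conflict — allele
  support must be unambiguous even where coverage is not;
* **number of barcodes** — distinct cells observed at the position,
  including cells whose only molecules were conflicted.

This ordering (reads > molecules > cells) is the only self-consistent
reading of the descriptive statistics such data produce, and the synthetic
generator reproduces it by construction.

## Skewing statistic and classification

Per position, skew = 100·max(X1, X2)/(X1+X2), defined on [50, 100] and
symmetric in the alleles. The four categories are half-open bins
[50,70), [70,80), [80,90) with the final bin [90,100] closed — a true
partition, verified exhaustively over all count pairs 3 ≤ X1, X2 ≤ 30.
Reported category percentages are rounded half-up to one decimal; the
"skewing or higher" and "severe or higher" aggregates are rounded from the
exact count ratios, not from the already-rounded per-category values.
Descriptive summaries use the sample SD (n−1) by default; the denominator
is exposed (`ddof`) since either convention appears in summary tables.

## Filter funnel

Positions enter the skewing analysis only if barcoding frequency ∈
[10, 1000], barcode count ∈ [3, 30] and X1 ≥ 3 and X2 ≥ 3. Every bound is
inclusive: published descriptive minima/maxima (minimum allele counts of
exactly 3, minimum frequency exactly 10, maximum barcode count exactly 30)
sit *on* these bounds, which forces the inclusive reading. The funnel
report tallies total reads, distinct barcodes, candidate and retained
positions; retention is monotone under tightening any threshold (property-
tested).

## Escape criterion

An escape candidate is a position whose entire signal comes from **one**
cell, with both alleles at ≥ 3 UMIs and coverage in [10, 1000] — i.e.
biallelic expression within a single cell, the operational single-cell
definition of escape from the inactive X. Because only one barcode is
involved, per-cell and per-position counts coincide and the test is applied
to the totals. Under default thresholds the escape set is provably disjoint
from the skewing set (1 barcode vs ≥ 3). Gene annotation is point-in-
interval against a user BED (position p overlaps [start, end) iff
start ≤ p−1 < end); no transcript models. A known-escape list (one symbol
per line) yields a per-gene cross-reference flag.

## Two-sample comparison

Haplotype labels are not comparable across unrelated individuals, so the
default 2×2 table at a shared position uses each sample's own (major,
minor) counts — it contrasts skew *magnitude*. The alternative
`haplotype_labels` orientation is available for samples with anchored
phasing. At X1 = X2 the (X1, X2) order is kept; the OR direction is
meaningless at perfect balance.

Statistics on the table:

* pooled two-proportion Z with two-sided normal p; degenerate tables
  (pooled proportion 0 or 1 — no variation) return z = 0, p = 1;
* Pearson χ², df 1, no Yates correction — chosen so χ² = Z² exactly
  (checked to 1e−9 on random tables); Yates would break the identity and
  is deliberately not applied;
* Haldane–Woolf OR: ½ added to every cell, Woolf SE of ln OR, Wald CI —
  finite and positive for any non-negative table, reciprocal under row
  swap;
* multiplicity corrections over the family of *all* shared positions:
  Bonferroni, Hochberg, Hommel, and FDR read as Benjamini–Hochberg (the
  standard interpretation of "false discovery method"; Benjamini–Yekutieli
  available as `fdr_by`). The corrections are delegated to
  `statsmodels.stats.multitest` and cross-validated in the test suite
  against brute-force step-up recursions and, for Hommel, full closed
  testing with Simes local tests over all subsets.

Direction of change is tallied by comparing the two samples' skew
percentages (case greater / less / equal, with a 1e−9 equality tolerance);
the tally always sums to the number of shared positions.

## Synthetic data generator

The generator emulates the data *structure* the pipeline consumes, with
known truth, at these defaults: 200 heterozygous positions and 20
homozygous decoys on a 155 Mb coordinate range; a pool of 200 cells with
16-mer barcodes and 10-mer UMIs (10x v2-like tags); a mean of 8 expressing
cells per position (matching observed per-position barcode counts of ~8–9
in real CD4+ data); 3 UMIs per cell-position and 1.8 reads per UMI,
reproducing the reads > molecules > cells hierarchy; mosaic fraction 0.7
(the typical mean skew of ~70% in such cohorts); escape rate 0.02; leak
rate 0.01 for wrong-haplotype molecules (phasing error / index hopping).

Counts are shifted Poisson, 1 + Pois(μ−1): support ≥ 1 with mean exactly
μ, keeping depth parameters directly interpretable. Each expressing cell
chooses its active haplotype independently per position (H1 with
probability π), which makes positions statistically independent so
cross-position standard errors are valid in recovery checks. Planted
escape positions are expressed in exactly one cell with ≥ 3 UMIs per
haplotype; homozygous decoys emit a single haplotype everywhere and must
die in the heterozygous filters.

What the generator does **not** model — and hence what passing tests do
not establish about real data: real XCI mosaicism is cell-global (one
inactive X per cell across all loci), so real positions are strongly
correlated; escape here is the operational single-cell biallelic
criterion, not biological escape across many cells; there are no alignment
or sequencing errors, no allele-mapping bias, no ambient RNA, no doublets,
and no XIST-based validation signal. Tests on synthetic data verify the
*machinery* (counting, filtering, classification, statistics), not
biological effect sizes.

## Numerical and design choices

* Rounding of reported percentages: half-up, one decimal (`decimal`
  module), matching descriptive-table conventions.
* Empty inputs: empty distributions are flagged `undefined` rather than
  dividing by zero; `describe` raises on empty input; comparison of
  disjoint samples returns an empty family with a warning.
* Determinism: one `numpy` `default_rng` seed drives a simulation;
  identical seeds give byte-identical fixtures; CLI reruns are
  byte-identical.
* Problem sizes in the recovery checks (120 positions × 500 cells for the
  mosaic-fraction check; 150 positions with 10% planted escapes and 30
  decoys for sensitivity/specificity) were chosen as comfortable desk-scale
  simulations with standard errors small enough to make the 3-SE criterion
  meaningful.
* Escape sensitivity is assessed among planted sites whose realized
  coverage lands in [10, 1000]: the criterion is conditional on depth by
  definition, and the generator's read-depth draw can legitimately leave a
  planted site under-covered.

## Known limitations

* The per-read table reconstructs a format whose original layout is not
  standardized; `ingest_alignments` covers conversion from SAM/BAM but
  upstream phasing itself is out of scope.
* Gene-level aggregation of per-SNP p-values is not provided; reports are
  per SNP, annotated by gene.
* Skew direction cannot be anchored to parental origin without pedigree or
  anchored phasing.
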