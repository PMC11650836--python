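# Methods

## Data model and coordinates

All cnr/bintest/cns intervals are 0-based half-open (BED convention); VCF
positions are 1-based; display loci in IGV links are 1-based inclusive
(`start+1-end`). Chromosomes sort in natural order (1–22, X, Y, MT, then
lexicographic); a leading `chr` is ignored for comparison and preserved on
output. Missing table cells are `.` or empty on read and written back empty.
Table floats are serialized at 6 decimal places, which makes
write→read→write byte-stable; the reference TSV instead uses full `repr`
precision so a round-tripped reference reproduces every statistic exactly.

## Exon identity

cnr files carry no exon annotation, only target labels. An "exon" here is
the ordinal of a bin within its (gene, chromosome) group after sorting by
start (ties by end); strand is ignored because the tables carry none.
Labels of the CNVkit target form `GENE_3` (final underscore + fully numeric
suffix) collapse to `GENE`; any other label is the gene verbatim. Labels
`Antitarget` and `-` mark background bins: they are excluded from exon
indexing and reference building but kept for scatter plots. The indexing is
invariant under input row permutation. This ordinal convention is a design
choice — it makes exons comparable across samples processed with the same
target set, but ordinals are not portable across different bed designs.

## Calling model

A bin's log2 coverage ratio is classified into exactly one category by four
cutoffs (defaults in parentheses):

- homozygous deletion: log2 < hom_del (−1.1)
- heterozygous deletion: hom_del ≤ log2 ≤ het_del (−0.4)
- duplication: log2 > dup (0.3)
- normal: otherwise; data grids additionally highlight bins below −0.65.

The deletion interval is closed at its right boundary (a value exactly at
the deletion cutoff still calls a deletion); duplication is strictly
greater, so the partition is exhaustive and never double-counts. Copy
number is round(2·2^log2), half-up, floored at 0, which anchors 0→2, −1→1,
0.585→3. The consecutive-run predicate deliberately keeps the strict form
(deletion: log2 < het_del), so a bin exactly at −0.4 is called het-del in
the grid but does not seed a run; the discrepancy is confined to a
measure-zero boundary.

## Cohort reference

For every (gene, chromosome, exon) observed in at least one sample the
reference stores: the fraction of samples calling het-del / hom-del / dup
(exclusive categories over the same denominator, so the four fractions
including normal sum to 1), and mean, median, sample SD (n−1 denominator, 0
for a single sample), quartiles by linear interpolation between order
statistics, min and max — for log2 and depth separately. Exons absent from
some samples use the reduced denominator, recorded as `n_samples`. The
frequency cutoffs reuse the calling thresholds so the boxplot view and the
frequency columns are mutually consistent. Sex chromosomes are not
stratified by sample sex; references built from mixed-sex cohorts will show
inflated spread on chrX/chrY.

## Bin-wise z-test

For each bin resolvable in the reference with σ_log2 > 0:
z = (log2 − μ_ref)/σ_ref, two-sided p from the standard normal, then
Benjamini–Hochberg step-up across all tested bins
(q(i) = p(i)·m/i after ascending sort, running minimum from the largest
rank, capped at 1, input order restored). A bin is significant when its
adjusted p ≤ α (default 0.05). This is a re-derivation of the single-bin
test concept against the cohort reference, not a reimplementation of any
caller's internals; p-values already present in a bintest file are consumed
as-is, and recomputation is an explicit separate operation. The normal model
assumes the cohort log2 values per exon are approximately Gaussian and the
tested sample is not in the reference — testing a sample against a
reference that contains it deflates z at true events (the event inflates
σ_ref), so leave-one-out or external references should be used.

## Presets and custom filters

Presets: total and bintest are identities on their inputs; homozygous
deletion keeps hom-del calls; the candidate presets intersect with a gene
panel by symbol (case-insensitive) — panels are symbol lists, so coordinate
overlap is not attempted; the consecutive presets return maximal runs of
strictly consecutive exon ordinals all satisfying the direction predicate,
discarding runs shorter than the user cutoff (default 2). Custom filters
(region overlap on half-open intervals, gene membership, minimum depth,
copy-number set, minimum |log2|, maximum in-house frequency) are a pure
conjunction, hence order-independent. The in-house frequency filter
thresholds the maximum of the three frequencies — a conservative
"any-event" notion of commonness; bins with no reference entry pass. For
the consecutive presets the custom filters are evaluated per bin and a run
survives only if every bin passes, which keeps runs intact instead of
fragmenting them.

## Trio mode

Parental cnr tables are left-joined onto the index sample on the exact key
(chromosome, start, end, gene symbol), so the output always has one row per
index bin; joining on coordinates rather than exon ordinals tolerates
slightly different parental target sets. Duplicate keys within one parent
resolve to the first occurrence (warned). The de novo filter keeps bins
where the index call is non-normal and both parental calls are normal;
bins with incomplete parental data are excluded and counted separately
rather than reported as de novo.

## Plot series

Series are computed, not rendered; any plotting layer can consume the
dataclasses or their TSV/JSON serializations. Boxplot series: one entry per
reference exon with the reference box (q1/median/q3, mean, min/max
whiskers) for log2 and depth and the analyzed sample's point and call;
unknown genes raise an error carrying prefix matches for autocompletion.
Scatter series: every bin becomes a point; a point is flagged when its
midpoint lies in a segment whose own log2 classifies non-normal; genome
view concatenates chromosomes with cumulative offsets. BAF series:
alt/(ref+alt), undefined (skipped) at zero depth.

LOH is operationalized as a sliding window of 25 consecutive SNVs flagged
when at most 10% of its points fall strictly inside the heterozygous band
(0.3, 0.7); overlapping flagged windows merge into maximal per-chromosome
intervals, and chromosomes with fewer points than one window are evaluated
as a single window. The defaults trade sensitivity for robustness to
isolated miscalled genotypes; the interval boundary is only localized to
about one window of SNVs. No distinction between somatic LOH and
uniparental disomy is attempted.

## Synthetic data

The generator emulates the input formats, not sequencing physics: per bin
log2 ~ Normal(0, 0.15) plus an injected shift (het-del −1.0, hom-del −3.3,
dup +0.58 — chosen so the intended category is assigned with ≥ 99.9%
probability at the default SD), depth coupled multiplicatively
(200·2^log2) so depth- and log2-based views agree, weight ~ Uniform(0.5, 1).
cns tables are maximal runs of same-call adjacent bins. VCFs carry
biallelic SNVs with genotypes het / hom-ref / hom-alt at 0.5/0.25/0.25 and
allelic depths (15,15)/(30,0)/(0,30); inside an LOH interval heterozygous
genotypes are suppressed. All draws are consumed in a fixed order from a
single seeded generator, so identical seeds give byte-identical files. Not
modeled: GC/mappability bias, weight-depth correlation, segmentation noise,
read-level errors — so passing tests demonstrate the algorithms' contracts,
not performance on real capture data.

Exact-recovery tests (injected frequency recovery, trio de novo recovery)
use cohorts with baseline SD 0.02 so that every injected shift is at least
5σ from the nearest call boundary and category counts are identifiable;
behavior tests that only involve homozygous deletions use the default SD
0.15, where the −1.1 cutoff is more than 7σ from baseline. Statistical
suites use 10,000-bin null draws over 5 seeds (z-test calibration) and
1,000 random p-vectors (BH agreement at 1e−12); these sizes give binomial
standard errors small enough for 3·SE bounds while keeping the whole suite
in seconds.

## Numerical and degenerate-input choices

- Quartiles: linear interpolation (the common numeric-library default),
  stated so independent oracles match exactly.
- BH uses a stable mergesort, making it permutation-equivariant including
  ties.
- Single-sample references: SD 0, all quantiles equal the value; such exons
  are skipped by the z-test (σ = 0) with a logged count.
- Empty cohorts, empty panels and empty testable sets are content errors,
  not silent empties; unknown VCF regions yield empty collections.
- Thresholds validate hom_del < het_del < dup at construction.

## CLI

The CLI is a thin dispatch over the library: one subcommand per stage,
threshold defaults injected in one place, outputs written to a temp file
and atomically moved, inputs logged with md5 checksums and the tool
version. Exit codes: 0 success, 1 user/configuration error (including
usage errors), 2 internal error.
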