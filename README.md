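# exoncnv

Exon-resolution analysis of copy-number variants (CNVs) from CNVkit-style
coverage tables, as a headless library plus CLI.

Clinical CNV analysis increasingly replaces legacy single-exon assays
(MLPA) with read-depth calling from exome/genome sequencing. The raw
material is a per-bin table (the "cnr" file): for every targeted exon-sized
bin, a bias-corrected **log2 coverage ratio** against a pooled reference
(log2 ≈ 0 for two copies), a raw mean **depth**, and a reliability
**weight**. `exoncnv` turns cohorts of such tables into the artifacts a
diagnostic analyst needs:

- **Cohort exon reference** — for every (gene, exon ordinal) the in-house
  frequency of heterozygous deletion, homozygous deletion and duplication,
  plus the mean/median/SD/quartile/min/max of log2 and depth needed to draw
  MLPA-like per-exon boxplots.
- **Filterable call grids** — seven presets (total, bintest, homozygous
  deletion, panel-restricted variants, consecutive deletions/amplifications)
  combined with custom filters on region, gene, depth, copy number, |log2|
  and in-house frequency.
- **Bin-wise z-test** — per-bin z = (log2 − μ_ref)/σ_ref with a two-sided
  normal p-value, Benjamini–Hochberg corrected across bins, for single-exon
  CNV candidates.
- **Trio mode** — a left join of parental cnr tables onto the index sample
  and a de novo filter (aberrant child, both parents normal).
- **Plot series** — per-exon boxplot series, genome/chromosome log2 scatter
  with aberrant-segment overlay, B-allele-frequency (BAF) series from a VCF
  (balance = alt/(ref+alt): 0, ~0.5 or 1), and a windowed
  loss-of-heterozygosity (LOH) flag over the BAF series.
- **AnnotSV table reduction** — project an AnnotSV full-annotation TSV onto
  a configured column set and filter by SV type, gene panel and ACMG class.

Calling uses four log2 cutoffs (defaults): duplication > 0.3, heterozygous
deletion ≤ −0.4, homozygous deletion < −1.1, and a data-grid highlight below
−0.65. Copy number is round(2·2^log2). A deterministic, seeded synthetic-data
generator (`exoncnv.synth`) produces cnr cohorts with injected single- and
multi-exon events, matching cns segment tables, and VCFs with optional LOH
regions, and is the basis of the test suite.

## Worked example

```python
import exoncnv as x

spec = x.demo_spec(seed=3)              # 3 genes, 10 samples, 3 injected CNVs
cohort = x.synth_cohort(spec)

# leave-one-out reference, then annotate the held-out sample
reference = x.build_reference({k: v for k, v in cohort.items() if k != "sample_001"})
bins = x.annotate_frequencies(cohort["sample_001"], reference)

hom = x.apply_preset(bins, None, x.FilterConfig(preset="homozygous_deletion"))
for b in hom:
    print(f"{b.gene} exon {b.exon_index}  log2={b.log2:+.3f}  cn={b.cn}  "
          f"call={b.call}  inhouse hom-del freq={b.hom_del_freq:.2f}")

result = x.recompute_bintest(bins, reference, alpha=0.05)
print(f"bintest: {len(result.significant)} of {len(result.tested)} bins significant")

series = x.boxplot_series("GENA", reference, bins)
e = series.entries[6]
print(f"GENA exon {e.exon_index}: sample log2 {e.sample_log2:+.3f} vs reference "
      f"box [{e.log2_box.q1:+.3f}, {e.log2_box.q3:+.3f}] -> {e.sample_call}")
```

prints

```
GENB exon 3  log2=-3.327  cn=0  call=homozygous_deletion  inhouse hom-del freq=0.00
bintest: 5 of 24 bins significant
GENA exon 7: sample log2 +0.538 vs reference box [-0.057, +0.017] -> duplication
```

The injected single-exon homozygous deletion in GENB is the only bin passing
the homozygous-deletion preset (its in-house frequency is 0 because the
leave-one-out reference never saw the event); the BH-corrected bin z-test
flags it plus the injected three-exon duplication and one noise bin; and the
boxplot series shows the duplicated exon 7 sitting above the reference box.

The same pipeline from the shell:

```sh
exoncnv synth --out-dir demo --seed 3
exoncnv build-reference demo/sample_0*.cnr --out demo/ref.tsv
exoncnv filter --cnr demo/sample_001.cnr --reference demo/ref.tsv \
    --preset homozygous_deletion --out demo/hom.tsv
exoncnv loh --vcf demo/sample_001.vcf --out demo/loh.tsv
```

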