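"""Deterministic, seeded generation of synthetic fixtures.

Emulates the toolkit's inputs: cnr cohorts with injected single- and
multi-exon deletions/duplications, matching bintest and cns tables, trio
sets, and SNV VCFs with an optional loss-of-heterozygosity region. Bins in
a sample without an injected event draw log2 from Normal(0, baseline SD);
depth is coupled multiplicatively to log2 (depth = baseline mean * 2**log2)
so depth- and log2-based views agree. Identical seeds give byte-identical
output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .filters import AnnotatedBin, annotate_frequencies, recompute_bintest
from .io import CnrRecord, CnsSegment, write_cnr_like
from .reference import ExonReference, Thresholds, classify_log2, log2_to_cn

#: default log2 shifts per event kind; chosen so the intended call category
#: is assigned with overwhelming probability at the default baseline SD
#: (het del 2->1 copy = -1, hom del ~0 copies, dup 2->3 copies = +0.58).
EVENT_SHIFTS = {"het_del": -1.0, "hom_del": -3.3, "dup": 0.58}


@dataclass(frozen=True)
class GeneModel:
    """Layout of one synthetic gene: equally spaced exon-sized bins."""

    gene: str
    chromosome: str
    n_exons: int
    start: int
    exon_spacing: int
    exon_length: int = 150

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ConfigError(f"gene {self.gene}: n_exons must be >= 1")
        if self.exon_length >= self.exon_spacing:
            raise ConfigError(f"gene {self.gene}: exon_length must be < exon_spacing")

    def bin_bounds(self, exon_index: int) -> tuple[int, int]:
        s = self.start + (exon_index - 1) * self.exon_spacing
        return s, s + self.exon_length


@dataclass(frozen=True)
class InjectedEvent:
    """A CNV injected into one sample over a contiguous exon range."""

    sample: int  # 0-based sample index
    gene: str
    exon_from: int
    exon_to: int
    kind: str  # het_del | hom_del | dup
    log2_shift: float | None = None  # default per kind

    def shift(self) -> float:
        return self.log2_shift if self.log2_shift is not None else EVENT_SHIFTS[self.kind]


@dataclass
class SynthSpec:
    """Full description of a synthetic cohort."""

    seed: int
    genes: list[GeneModel]
    n_samples: int
    baseline_log2_sd: float = 0.15
    baseline_depth_mean: float = 200.0
    injected_events: list[InjectedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.baseline_log2_sd <= 0 or self.baseline_depth_mean <= 0:
            raise ConfigError("baseline parameters must be positive")
        by_gene = {g.gene: g for g in self.genes}
        for ev in self.injected_events:
            if ev.kind not in EVENT_SHIFTS:
                raise ConfigError(f"unknown event kind: {ev.kind!r}")
            if not 0 <= ev.sample < self.n_samples:
                raise ConfigError(f"event sample {ev.sample} outside cohort")
            gm = by_gene.get(ev.gene)
            if gm is None:
                raise ConfigError(f"event gene {ev.gene!r} not in spec")
            if not 1 <= ev.exon_from <= ev.exon_to <= gm.n_exons:
                raise ConfigError(
                    f"event exon range {ev.exon_from}-{ev.exon_to} outside {ev.gene}"
                )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SynthSpec":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            seed=data["seed"],
            genes=[GeneModel(**g) for g in data["genes"]],
            n_samples=data["n_samples"],
            baseline_log2_sd=data.get("baseline_log2_sd", 0.15),
            baseline_depth_mean=data.get("baseline_depth_mean", 200.0),
            injected_events=[InjectedEvent(**e) for e in data.get("injected_events", [])],
        )


def sample_id(index: int) -> str:
    return f"sample_{index + 1:03d}"


def synth_cohort(spec: SynthSpec) -> dict[str, list[CnrRecord]]:
    """Generate one cnr table per sample.

    Bin labels follow the CNVkit target-name convention ``GENE_exon``.
    Draws are consumed in a fixed sample/gene/exon order, so outputs are a
    pure function of the spec (including the seed).
    """
    rng = np.random.default_rng(spec.seed)
    shifts: dict[tuple[int, str, int], float] = {}
    for ev in spec.injected_events:
        for e in range(ev.exon_from, ev.exon_to + 1):
            shifts[(ev.sample, ev.gene, e)] = shifts.get((ev.sample, ev.gene, e), 0.0) + ev.shift()

    cohort: dict[str, list[CnrRecord]] = {}
    for s in range(spec.n_samples):
        records: list[CnrRecord] = []
        for gm in spec.genes:
            for e in range(1, gm.n_exons + 1):
                log2 = float(rng.normal(0.0, spec.baseline_log2_sd))
                log2 += shifts.get((s, gm.gene, e), 0.0)
                weight = float(np.round(rng.uniform(0.5, 1.0), 6))
                start, end = gm.bin_bounds(e)
                depth = float(np.round(spec.baseline_depth_mean * 2.0 ** log2, 6))
                records.append(
                    CnrRecord(
                        chromosome=gm.chromosome,
                        start=start,
                        end=end,
                        gene=f"{gm.gene}_{e}",
                        depth=depth,
                        log2=round(log2, 6),
                        weight=weight,
                    )
                )
        records.sort(key=lambda r: (r.chromosome, r.start))
        cohort[sample_id(s)] = records
    return cohort


def bins_to_segments(
    records: Sequence[CnrRecord], thresholds: Thresholds | None = None
) -> list[CnsSegment]:
    """Aggregate bins into cns-style segments: maximal runs of adjacent
    same-call bins per chromosome, with mean log2/depth and a copy-number
    call on the segment mean."""
    if thresholds is None:
        thresholds = Thresholds()
    out: list[CnsSegment] = []
    ordered = sorted(records, key=lambda r: (r.chromosome, r.start))

    def flush(chunk: list[CnrRecord]) -> None:
        if not chunk:
            return
        mean_log2 = float(np.mean([r.log2 for r in chunk]))
        genes: list[str] = []
        for r in chunk:
            if r.gene not in genes:
                genes.append(r.gene)
        out.append(
            CnsSegment(
                chromosome=chunk[0].chromosome,
                start=chunk[0].start,
                end=chunk[-1].end,
                genes=genes,
                log2=round(mean_log2, 6),
                depth=round(float(np.mean([r.depth for r in chunk])), 6),
                probes=len(chunk),
                weight=round(float(np.sum([r.weight for r in chunk])), 6),
                cn=log2_to_cn(mean_log2),
            )
        )

    chunk: list[CnrRecord] = []
    for r in ordered:
        if chunk and (
            r.chromosome != chunk[-1].chromosome
            or classify_log2(r.log2, thresholds) != classify_log2(chunk[-1].log2, thresholds)
        ):
            flush(chunk)
            chunk = []
        chunk.append(r)
    flush(chunk)
    return out


def synth_bintest(
    records: Sequence[CnrRecord],
    reference: ExonReference,
    thresholds: Thresholds | None = None,
    alpha: float = 0.05,
) -> list[CnrRecord]:
    """Derive a bintest-style table for one sample: the sample's bins with
    the BH-adjusted bin z-test p-value attached, restricted to significant
    bins (single-bin CNV candidates)."""
    annotated = annotate_frequencies(records, reference, thresholds)
    result = recompute_bintest(annotated, reference, alpha=alpha)
    out = []
    for b in result.significant:
        out.append(
            CnrRecord(
                chromosome=b.chromosome,
                start=b.start,
                end=b.end,
                gene=f"{b.gene}_{b.exon_index}",
                depth=b.depth,
                log2=b.log2,
                weight=b.weight,
                p_value=min(1.0, round(b.p_adjusted, 6)),
            )
        )
    return out


def write_cohort(cohort: Mapping[str, list[CnrRecord]], out_dir: str | os.PathLike) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in cohort:
        path = out_dir / f"{name}.cnr"
        write_cnr_like(cohort[name], path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# SNV VCF generation

_BASES = "ACGT"

#: genotype mixture outside an LOH region: het / hom-ref / hom-alt.
GENOTYPE_PROBS = (0.5, 0.25, 0.25)
#: per-allele read depth for heterozygous calls.
ALLELE_DEPTH = 15


def synth_snvs(
    path: str | os.PathLike,
    chromosome: str,
    n_snvs: int,
    loh_interval: tuple[int, int] | None = None,
    seed: int = 0,
    chrom_length: int = 2_000_000,
) -> Path:
    """Write a single-sample VCF of biallelic SNVs with AD and GT fields.

    Outside ``loh_interval`` genotypes are drawn het / hom-ref / hom-alt
    with probabilities 0.5 / 0.25 / 0.25 and allelic depths (d, d), (2d, 0),
    (0, 2d) with d = 15; inside the interval no heterozygous genotype is
    emitted (hom-ref / hom-alt at 0.5 / 0.5). Positions are distinct,
    sorted, 1-based; output is deterministic per seed.
    """
    if n_snvs < 1:
        raise ConfigError("n_snvs must be >= 1")
    if n_snvs > chrom_length:
        raise ConfigError("n_snvs exceeds the chromosome model length")
    if loh_interval is not None:
        lo, hi = loh_interval
        if not 1 <= lo <= hi <= chrom_length:
            raise ConfigError(f"loh_interval {loh_interval} outside chromosome model")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=n_snvs, replace=False))

    d = ALLELE_DEPTH
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chromosome},length={chrom_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for pos in positions.tolist():
        in_loh = loh_interval is not None and loh_interval[0] <= pos <= loh_interval[1]
        u = rng.random()
        if in_loh:
            gt, ad = ("0/0", (2 * d, 0)) if u < 0.5 else ("1/1", (0, 2 * d))
        else:
            if u < GENOTYPE_PROBS[0]:
                gt, ad = "0/1", (d, d)
            elif u < GENOTYPE_PROBS[0] + GENOTYPE_PROBS[1]:
                gt, ad = "0/0", (2 * d, 0)
            else:
                gt, ad = "1/1", (0, 2 * d)
        ref = _BASES[pos % 4]
        alt = _BASES[(pos + 1) % 4]
        lines.append(
            f"{chromosome}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t{gt}:{ad[0]},{ad[1]}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def demo_spec(seed: int = 0) -> SynthSpec:
    """A small default cohort: three genes, ten samples, three injected
    events (a three-exon duplication, a single-exon homozygous deletion and
    a two-exon heterozygous deletion)."""
    genes = [
        GeneModel("GENA", "chr1", 10, 100_000, 2_000),
        GeneModel("GENB", "chr1", 6, 500_000, 3_000),
        GeneModel("GENC", "chr2", 8, 200_000, 2_500),
    ]
    events = [
        InjectedEvent(sample=0, gene="GENA", exon_from=7, exon_to=9, kind="dup"),
        InjectedEvent(sample=0, gene="GENB", exon_from=3, exon_to=3, kind="hom_del"),
        InjectedEvent(sample=1, gene="GENC", exon_from=2, exon_to=3, kind="het_del"),
    ]
    return SynthSpec(seed=seed, genes=genes, n_samples=10, injected_events=events)
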