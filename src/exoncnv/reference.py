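"""Cohort exon-level reference: per-exon CNV frequencies and boxplot statistics.

The reference summarizes a cohort of cnr tables exon by exon. For every
(gene, chromosome, exon ordinal) it stores the fraction of cohort samples
whose log2 ratio classifies as heterozygous deletion, homozygous deletion
or duplication, plus the location/spread statistics needed to draw an
MLPA-like boxplot (mean, median, SD, quartiles, min, max of both the log2
ratio and the raw depth).
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ContentError, ParseError, SchemaError
from .io import CnrRecord, assign_exon_indices, chromosome_sort_key


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio cutoffs for calling and grid highlighting.

    Defaults: duplication above 0.3, heterozygous deletion below -0.4,
    homozygous deletion below -1.1; grids highlight bins below -0.65.
    """

    dup_log2: float = 0.3
    het_del_log2: float = -0.4
    hom_del_log2: float = -1.1
    grid_highlight_log2: float = -0.65

    def __post_init__(self) -> None:
        if not self.hom_del_log2 < self.het_del_log2 < self.dup_log2:
            raise ValueError(
                "thresholds must satisfy hom_del < het_del < dup "
                f"(got {self.hom_del_log2}, {self.het_del_log2}, {self.dup_log2})"
            )


class CallCategory(enum.IntEnum):
    """Copy-number call classes, ordered by dosage."""

    HOMOZYGOUS_DELETION = 0
    HETEROZYGOUS_DELETION = 1
    NORMAL = 2
    DUPLICATION = 3

    def __str__(self) -> str:  # TSV-friendly
        return self.name.lower()


def classify_log2(log2: float, thresholds: Thresholds | None = None) -> CallCategory:
    """Assign a log2 ratio to exactly one call category.

    The partition is exhaustive and exclusive: homozygous deletion strictly
    below ``hom_del_log2``; heterozygous deletion on [hom_del, het_del]
    (the deletion cutoff itself still calls a deletion); duplication
    strictly above ``dup_log2``; normal otherwise (so 0.3 → normal).
    """
    if thresholds is None:
        thresholds = Thresholds()
    if not math.isfinite(log2):
        raise ValueError(f"log2 must be finite (got {log2})")
    if log2 < thresholds.hom_del_log2:
        return CallCategory.HOMOZYGOUS_DELETION
    if log2 <= thresholds.het_del_log2:
        return CallCategory.HETEROZYGOUS_DELETION
    if log2 > thresholds.dup_log2:
        return CallCategory.DUPLICATION
    return CallCategory.NORMAL


def log2_to_cn(log2: float) -> int:
    """Translate a log2 ratio into an integer copy number.

    Uses round(2 * 2**log2) with half-up rounding, floored at zero, which
    anchors the diploid points: 0 → 2 copies, -1 → 1, +0.585 → 3.
    """
    if not math.isfinite(log2):
        raise ValueError(f"log2 must be finite (got {log2})")
    return max(0, math.floor(2.0 * 2.0 ** log2 + 0.5))


@dataclass
class ExonReferenceStats:
    """Cohort summary for one exon (one reference row)."""

    gene: str
    chromosome: str
    exon_index: int
    n_samples: int
    het_del_freq: float
    hom_del_freq: float
    dup_freq: float
    mean_log2: float
    median_log2: float
    sd_log2: float
    q1_log2: float
    q3_log2: float
    min_log2: float
    max_log2: float
    mean_depth: float
    median_depth: float
    sd_depth: float
    q1_depth: float
    q3_depth: float
    min_depth: float
    max_depth: float

    def __post_init__(self) -> None:
        for f in ("het_del_freq", "hom_del_freq", "dup_freq"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1] (got {v})")
        if self.het_del_freq + self.hom_del_freq + self.dup_freq > 1.0 + 1e-12:
            raise ValueError("category frequencies must sum to <= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.sd_log2 < 0 or self.sd_depth < 0:
            raise ValueError("standard deviations must be >= 0")


#: fixed column order of the reference TSV serialization.
REFERENCE_COLUMNS = tuple(f.name for f in fields(ExonReferenceStats))


class ExonReference:
    """Queryable container of :class:`ExonReferenceStats` rows."""

    def __init__(self, stats: Iterable[ExonReferenceStats]):
        self.stats = sorted(
            stats,
            key=lambda s: (chromosome_sort_key(s.chromosome), s.gene, s.exon_index),
        )
        self._by_key = {(s.gene, s.chromosome, s.exon_index): s for s in self.stats}

    def __len__(self) -> int:
        return len(self.stats)

    def __iter__(self):
        return iter(self.stats)

    def lookup(self, gene: str, chromosome: str, exon_index: int) -> ExonReferenceStats | None:
        return self._by_key.get((gene, chromosome, exon_index))

    def genes(self) -> list[str]:
        return sorted({s.gene for s in self.stats})

    def exons_for_gene(self, gene: str) -> list[ExonReferenceStats]:
        return [s for s in self.stats if s.gene == gene]

    def to_tsv(self, path: str | os.PathLike) -> None:
        # floats use repr so a round-trip reproduces them bit-for-bit
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(REFERENCE_COLUMNS) + "\n")
            for s in self.stats:
                cells = []
                for name in REFERENCE_COLUMNS:
                    v = getattr(s, name)
                    cells.append(repr(v) if isinstance(v, float) else str(v))
                fh.write("\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ExonReference":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines:
            raise SchemaError(f"{path.name}: empty reference file")
        header = lines[0].split("\t")
        if header != list(REFERENCE_COLUMNS):
            raise SchemaError(f"{path.name}: unexpected reference header")
        stats = []
        for i, line in enumerate(lines[1:], start=1):
            cells = line.split("\t")
            if len(cells) != len(REFERENCE_COLUMNS):
                raise ParseError(f"row {i}: expected {len(REFERENCE_COLUMNS)} cells")
            kwargs = {}
            for name, cell in zip(REFERENCE_COLUMNS, cells):
                if name in ("gene", "chromosome"):
                    kwargs[name] = cell
                elif name in ("exon_index", "n_samples"):
                    kwargs[name] = int(cell)
                else:
                    kwargs[name] = float(cell)
            stats.append(ExonReferenceStats(**kwargs))
        return cls(stats)


def build_reference(
    cohort: Mapping[str, list[CnrRecord]],
    thresholds: Thresholds | None = None,
) -> ExonReference:
    """Aggregate a cohort of cnr tables into an exon-level reference.

    One row is produced per (gene, chromosome, exon ordinal) observed in at
    least one sample; the denominator ``n_samples`` counts only the samples
    in which that exon exists. Frequencies count exclusive call categories,
    so heterozygous and homozygous deletions never double-count. Quartiles
    use linear interpolation between order statistics; the SD is the sample
    estimator (n-1 denominator, 0 when a single sample carries the exon).
    """
    if thresholds is None:
        thresholds = Thresholds()
    if not cohort:
        raise ContentError("cohort is empty")

    per_exon: dict[tuple[str, str, int], tuple[list[float], list[float]]] = {}
    for sample_id in cohort:
        groups = assign_exon_indices(cohort[sample_id])
        for (gene, chrom), recs in groups.items():
            for i, rec in enumerate(recs, start=1):
                log2s, depths = per_exon.setdefault((gene, chrom, i), ([], []))
                log2s.append(rec.log2)
                depths.append(rec.depth)
    if not per_exon:
        raise ContentError("cohort contains no indexable (on-target) bins")

    stats = []
    for (gene, chrom, idx), (log2s, depths) in per_exon.items():
        n = len(log2s)
        calls = [classify_log2(v, thresholds) for v in log2s]
        l = np.asarray(log2s, dtype=float)
        d = np.asarray(depths, dtype=float)
        q1_l, med_l, q3_l = np.percentile(l, [25, 50, 75], method="linear")
        q1_d, med_d, q3_d = np.percentile(d, [25, 50, 75], method="linear")
        stats.append(
            ExonReferenceStats(
                gene=gene,
                chromosome=chrom,
                exon_index=idx,
                n_samples=n,
                het_del_freq=calls.count(CallCategory.HETEROZYGOUS_DELETION) / n,
                hom_del_freq=calls.count(CallCategory.HOMOZYGOUS_DELETION) / n,
                dup_freq=calls.count(CallCategory.DUPLICATION) / n,
                mean_log2=float(l.mean()),
                median_log2=float(med_l),
                sd_log2=float(l.std(ddof=1)) if n > 1 else 0.0,
                q1_log2=float(q1_l),
                q3_log2=float(q3_l),
                min_log2=float(l.min()),
                max_log2=float(l.max()),
                mean_depth=float(d.mean()),
                median_depth=float(med_d),
                sd_depth=float(d.std(ddof=1)) if n > 1 else 0.0,
                q1_depth=float(q1_d),
                q3_depth=float(q3_d),
                min_depth=float(d.min()),
                max_depth=float(d.max()),
            )
        )
    return ExonReference(stats)


def lookup_exon(
    reference: ExonReference, gene: str, chromosome: str, exon_index: int
) -> ExonReferenceStats | None:
    """Exact-key lookup; absent keys return None, never raise."""
    return reference.lookup(gene, chromosome, exon_index)
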