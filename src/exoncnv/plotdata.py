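"""Plot-ready series: MLPA-like per-exon boxplots, genome/chromosome log2
scatter with segment overlay, B-allele-frequency series, a windowed LOH
flag and IGV locus links.

These functions compute series content only; rendering is left to whatever
plotting layer consumes them, so the tested contract is the numbers, not
pixels.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

from .errors import ChromosomeNotFoundError, ConfigError, GeneNotFoundError
from .filters import AnnotatedBin
from .io import (
    CnrRecord,
    CnsSegment,
    EnvConfig,
    IGV_LINK_KEY,
    Region,
    SnvObservation,
    chromosome_sort_key,
    normalize_chromosome,
    parse_region,
)
from .reference import CallCategory, ExonReference, Thresholds, classify_log2

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MLPA-like boxplots


@dataclass
class BoxStats:
    """One box: quartile box, mean/median lines and min/max whiskers."""

    q1: float
    median: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float


@dataclass
class ExonBoxEntry:
    """Reference box plus the single analyzed sample's point for one exon."""

    exon_index: int
    chromosome: str
    log2_box: BoxStats
    depth_box: BoxStats
    sample_log2: float | None = None
    sample_depth: float | None = None
    sample_call: CallCategory | None = None


@dataclass
class BoxplotSeries:
    gene: str
    entries: list[ExonBoxEntry]
    thresholds: Thresholds

    def to_dict(self) -> dict:
        d = {
            "gene": self.gene,
            "thresholds": asdict(self.thresholds),
            "exons": [],
        }
        for e in self.entries:
            entry = asdict(e)
            entry["sample_call"] = None if e.sample_call is None else str(e.sample_call)
            d["exons"].append(entry)
        return d


def boxplot_series(
    gene: str,
    reference: ExonReference,
    sample_bins: Sequence[AnnotatedBin],
    thresholds: Thresholds | None = None,
) -> BoxplotSeries:
    """Build the per-exon boxplot series for one gene.

    One entry per reference exon in exon order; the sample's log2/depth and
    call are attached where the sample covers the exon and left missing
    otherwise. An unknown gene raises :class:`GeneNotFoundError` carrying
    prefix matches to support autocompletion.
    """
    if thresholds is None:
        thresholds = Thresholds()
    exons = reference.exons_for_gene(gene)
    if not exons:
        suggestions = [g for g in reference.genes() if g.upper().startswith(gene.upper())][:10]
        raise GeneNotFoundError(gene, suggestions)
    sample = {
        (b.chromosome, b.exon_index): b
        for b in sample_bins
        if b.gene == gene and b.exon_index is not None
    }
    entries = []
    for s in exons:
        b = sample.get((s.chromosome, s.exon_index))
        entries.append(
            ExonBoxEntry(
                exon_index=s.exon_index,
                chromosome=s.chromosome,
                log2_box=BoxStats(s.q1_log2, s.median_log2, s.q3_log2,
                                  s.mean_log2, s.min_log2, s.max_log2),
                depth_box=BoxStats(s.q1_depth, s.median_depth, s.q3_depth,
                                   s.mean_depth, s.min_depth, s.max_depth),
                sample_log2=b.log2 if b else None,
                sample_depth=b.depth if b else None,
                sample_call=classify_log2(b.log2, thresholds) if b else None,
            )
        )
    return BoxplotSeries(gene=gene, entries=entries, thresholds=thresholds)


# ---------------------------------------------------------------------------
# genome / chromosome scatter


@dataclass
class ScatterPoint:
    """One cnr bin in the scatter view; ``x`` carries the cumulative genome
    offset in genome view (equals position_mid in single-chromosome view)."""

    chromosome: str
    position_mid: int
    log2: float
    in_called_segment: bool
    x: int = 0


@dataclass
class SegmentInterval:
    chromosome: str
    start: int
    end: int
    log2: float
    call: CallCategory
    aberrant: bool
    x_start: int = 0
    x_end: int = 0


@dataclass
class ScatterSeries:
    region: str
    points: list[ScatterPoint]
    segments: list[SegmentInterval]
    chromosome_offsets: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "points": [asdict(p) for p in self.points],
            "segments": [
                {**asdict(s), "call": str(s.call)} for s in self.segments
            ],
            "chromosome_offsets": dict(self.chromosome_offsets),
        }


def scatter_series(
    cnr_bins: Sequence[CnrRecord],
    cns_segments: Sequence[CnsSegment],
    region: str = "genome",
    thresholds: Thresholds | None = None,
) -> ScatterSeries:
    """Compute the log2 scatter with aberrant-segment highlighting.

    Every bin in the region becomes a point; a point is flagged when its
    midpoint falls inside a segment whose log2 classifies as non-normal.
    Genome view concatenates chromosomes in natural order with cumulative
    offsets so all points share one x axis.
    """
    if thresholds is None:
        thresholds = Thresholds()
    chroms_present = {b.chromosome for b in cnr_bins}
    if region != "genome":
        wanted = normalize_chromosome(region)
        if wanted not in {normalize_chromosome(c) for c in chroms_present}:
            raise ChromosomeNotFoundError(f"no bins on chromosome {region!r}")
        bins = [b for b in cnr_bins if normalize_chromosome(b.chromosome) == wanted]
        segs = [s for s in cns_segments if normalize_chromosome(s.chromosome) == wanted]
    else:
        bins = list(cnr_bins)
        segs = list(cns_segments)

    offsets: dict[str, int] = {}
    if region == "genome":
        extent: dict[str, int] = {}
        for b in bins:
            extent[b.chromosome] = max(extent.get(b.chromosome, 0), b.end)
        for s in segs:
            extent[s.chromosome] = max(extent.get(s.chromosome, 0), s.end)
        cumulative = 0
        for chrom in sorted(extent, key=chromosome_sort_key):
            offsets[chrom] = cumulative
            cumulative += extent[chrom]

    aberrant = [
        (s, classify_log2(s.log2, thresholds))
        for s in segs
    ]
    segments = [
        SegmentInterval(
            chromosome=s.chromosome,
            start=s.start,
            end=s.end,
            log2=s.log2,
            call=call,
            aberrant=call is not CallCategory.NORMAL,
            x_start=offsets.get(s.chromosome, 0) + s.start,
            x_end=offsets.get(s.chromosome, 0) + s.end,
        )
        for s, call in aberrant
    ]
    aberrant_by_chrom: dict[str, list[SegmentInterval]] = {}
    for seg in segments:
        if seg.aberrant:
            aberrant_by_chrom.setdefault(normalize_chromosome(seg.chromosome), []).append(seg)

    points = []
    for b in bins:
        mid = b.midpoint
        flagged = any(
            seg.start <= mid < seg.end
            for seg in aberrant_by_chrom.get(normalize_chromosome(b.chromosome), [])
        )
        points.append(
            ScatterPoint(
                chromosome=b.chromosome,
                position_mid=mid,
                log2=b.log2,
                in_called_segment=flagged,
                x=offsets.get(b.chromosome, 0) + mid,
            )
        )
    return ScatterSeries(region=region, points=points, segments=segments,
                         chromosome_offsets=offsets)


# ---------------------------------------------------------------------------
# B-allele frequency and LOH


@dataclass
class BafPoint:
    chromosome: str
    position: int
    frequency: float


def baf_series(
    snvs: Sequence[SnvObservation],
    region: str | Region | None = None,
) -> list[BafPoint]:
    """Allelic-balance series: frequency = alt / (ref + alt).

    Hom-ref sites sit at 0, heterozygous near 0.5, hom-alt at 1.
    Observations with zero total depth are skipped (count logged).
    """
    if isinstance(region, str):
        region = parse_region(region)
    points = []
    n_skipped = 0
    for s in snvs:
        if region is not None:
            if normalize_chromosome(s.chromosome) != normalize_chromosome(region.chromosome):
                continue
            if region.start is not None and not region.start <= s.position <= region.end:
                continue
        total = s.ref_depth + s.alt_depth
        if total == 0:
            n_skipped += 1
            continue
        points.append(BafPoint(s.chromosome, s.position, s.alt_depth / total))
    if n_skipped:
        logger.info("baf_series: skipped %d observation(s) with zero depth", n_skipped)
    return points


@dataclass
class LohInterval:
    """A merged stretch of windows depleted of heterozygous calls."""

    chromosome: str
    start: int
    end: int
    n_snvs: int


def detect_loh(
    points: Sequence[BafPoint],
    window_snvs: int = 25,
    het_band: tuple[float, float] = (0.3, 0.7),
    max_het_fraction: float = 0.1,
) -> list[LohInterval]:
    """Flag candidate loss-of-heterozygosity intervals.

    A sliding window of ``window_snvs`` consecutive SNVs is flagged when the
    fraction of points strictly inside ``het_band`` is at most
    ``max_het_fraction``; overlapping flagged windows merge into maximal
    intervals per chromosome. Chromosomes with fewer points than the window
    are evaluated as a single window.
    """
    if window_snvs < 2:
        raise ConfigError("window_snvs must be >= 2")
    lo, hi = het_band
    by_chrom: dict[str, list[BafPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chromosome, []).append(p)

    intervals: list[LohInterval] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        pts = sorted(by_chrom[chrom], key=lambda p: p.position)
        n = len(pts)
        if n < 2:
            continue
        w = min(window_snvs, n)
        het = [1 if lo < p.frequency < hi else 0 for p in pts]
        flagged_ranges: list[tuple[int, int]] = []  # [i, j) point index ranges
        running = sum(het[:w])
        for i in range(0, n - w + 1):
            if i > 0:
                running += het[i + w - 1] - het[i - 1]
            if running / w <= max_het_fraction:
                if flagged_ranges and i <= flagged_ranges[-1][1]:
                    flagged_ranges[-1] = (flagged_ranges[-1][0], max(flagged_ranges[-1][1], i + w))
                else:
                    flagged_ranges.append((i, i + w))
        for i, j in flagged_ranges:
            intervals.append(
                LohInterval(
                    chromosome=chrom,
                    start=pts[i].position,
                    end=pts[j - 1].position,
                    n_snvs=j - i,
                )
            )
    return intervals


# ---------------------------------------------------------------------------
# IGV outlinks


def igv_locus_link(env: EnvConfig, chromosome: str, start: int, end: int) -> str:
    """Fill the env-configured IGV link template with a display locus.

    Internal coordinates are 0-based half-open; the emitted locus is the
    1-based inclusive display form ``chrom:start+1-end``.
    """
    template = env.get(IGV_LINK_KEY)
    if template is None:
        raise ConfigError(f"env config lacks {IGV_LINK_KEY}")
    if "{locus}" not in template:
        raise ConfigError(f"{IGV_LINK_KEY} has no {{locus}} placeholder")
    return template.replace("{locus}", f"{chromosome}:{start + 1}-{end}")


# ---------------------------------------------------------------------------
# serialization helpers shared by the CLI


def write_series_json(obj, path: str | os.PathLike) -> None:
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(data, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_baf_tsv(points: Sequence[BafPoint], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chromosome\tposition\tfrequency\n")
        for p in points:
            fh.write(f"{p.chromosome}\t{p.position}\t{p.frequency:.6f}\n")


def write_loh_tsv(intervals: Sequence[LohInterval], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chromosome\tstart\tend\tn_snvs\n")
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.n_snvs}\n")


def write_scatter_tsv(series: ScatterSeries, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chromosome\tposition_mid\tx\tlog2\tin_called_segment\n")
        for p in series.points:
            fh.write(f"{p.chromosome}\t{p.position_mid}\t{p.x}\t{p.log2:.6f}\t{p.in_called_segment}\n")
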