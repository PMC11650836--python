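"""Preset and custom filtering of annotated coverage bins.

Implements the seven analysis presets (total, bintest, homozygous deletion,
candidate-panel variants of total/bintest, consecutive deletions and
amplifications), the custom filter panel (region, genes, depth, copy number,
absolute log2, in-house frequency), consecutive-exon run detection, and the
bin-wise z-test against the cohort reference with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import ConfigError, ContentError
from .io import (
    ANTITARGET_LABELS,
    CnrRecord,
    PanelGeneList,
    Region,
    assign_exon_indices,
    normalize_chromosome,
    parse_region,
    split_gene_label,
)
from .reference import CallCategory, ExonReference, Thresholds, classify_log2, log2_to_cn

logger = logging.getLogger(__name__)


class Preset(enum.Enum):
    TOTAL = "total"
    BINTEST = "bintest"
    HOMOZYGOUS_DELETION = "homozygous_deletion"
    TOTAL_CANDIDATE = "total_candidate"
    BINTEST_CANDIDATE = "bintest_candidate"
    CONSECUTIVE_DEL = "consecutive_del"
    CONSECUTIVE_AMP = "consecutive_amp"


class RunDirection(enum.Enum):
    DELETION = "deletion"
    AMPLIFICATION = "amplification"


@dataclass
class FilterConfig:
    """User filter state: one preset plus optional custom filters.

    Unset custom filters are no-ops; set filters are combined by conjunction.
    ``max_inhouse_freq`` thresholds the maximum of the three in-house
    frequencies (a conservative any-event notion of commonness).
    """

    preset: Preset = Preset.TOTAL
    region: str | None = None
    genes: set[str] | None = None
    min_depth: float | None = None
    copy_numbers: set[int] | None = None
    min_abs_log2: float | None = None
    max_inhouse_freq: float | None = None
    consecutive_cutoff: int = 2

    def __post_init__(self) -> None:
        if isinstance(self.preset, str):
            self.preset = Preset(self.preset)
        if self.consecutive_cutoff < 1:
            raise ConfigError("consecutive_cutoff must be >= 1")
        if self.max_inhouse_freq is not None and not 0.0 <= self.max_inhouse_freq <= 1.0:
            raise ConfigError("max_inhouse_freq must be in [0, 1]")


@dataclass
class AnnotatedBin:
    """A cnr/bintest bin enriched with call, copy number and cohort context.

    ``exon_index`` is None for antitarget/background bins; the three
    frequencies are None when the exon is absent from the reference.
    ``highlight`` mirrors the data-grid color rule: log2 below the grid
    highlight threshold (default -0.65).
    """

    chromosome: str
    start: int
    end: int
    gene: str
    depth: float
    log2: float
    weight: float
    p_value: float | None
    exon_index: int | None
    call: CallCategory
    cn: int
    het_del_freq: float | None
    hom_del_freq: float | None
    dup_freq: float | None
    highlight: bool
    p_adjusted: float | None = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Run:
    """A maximal run of consecutive qualifying exons of one gene."""

    gene: str
    chromosome: str
    direction: RunDirection
    bins: list[AnnotatedBin]

    @property
    def length(self) -> int:
        return len(self.bins)

    @property
    def exon_from(self) -> int:
        return self.bins[0].exon_index

    @property
    def exon_to(self) -> int:
        return self.bins[-1].exon_index


def annotate_frequencies(
    records: Sequence[CnrRecord],
    reference: ExonReference | None = None,
    thresholds: Thresholds | None = None,
) -> list[AnnotatedBin]:
    """Annotate parsed bins with exon index, call, copy number and cohort
    frequencies, preserving the input row order.

    Bins whose exon is absent from the reference (or when no reference is
    given) keep None frequencies but are retained.
    """
    if thresholds is None:
        thresholds = Thresholds()
    groups = assign_exon_indices(records)
    index_of: dict[int, tuple[str, int]] = {}
    for (gene, _chrom), recs in groups.items():
        for i, rec in enumerate(recs, start=1):
            index_of[id(rec)] = (gene, i)

    annotated = []
    for rec in records:
        gene, exon_index = index_of.get(id(rec), (split_gene_label(rec.gene), None))
        if rec.gene in ANTITARGET_LABELS:
            gene, exon_index = rec.gene, None
        stats = None
        if reference is not None and exon_index is not None:
            stats = reference.lookup(gene, rec.chromosome, exon_index)
        annotated.append(
            AnnotatedBin(
                chromosome=rec.chromosome,
                start=rec.start,
                end=rec.end,
                gene=gene,
                depth=rec.depth,
                log2=rec.log2,
                weight=rec.weight,
                p_value=rec.p_value,
                exon_index=exon_index,
                call=classify_log2(rec.log2, thresholds),
                cn=log2_to_cn(rec.log2),
                het_del_freq=stats.het_del_freq if stats else None,
                hom_del_freq=stats.hom_del_freq if stats else None,
                dup_freq=stats.dup_freq if stats else None,
                highlight=rec.log2 < thresholds.grid_highlight_log2,
            )
        )
    return annotated


def _bin_passes(b: AnnotatedBin, config: FilterConfig, region: Region | None) -> bool:
    if region is not None:
        if normalize_chromosome(b.chromosome) != normalize_chromosome(region.chromosome):
            return False
        if region.start is not None:
            # region is 1-based inclusive, bins 0-based half-open
            if not (b.start < region.end and b.end > region.start - 1):
                return False
    if config.genes is not None:
        wanted = {g.upper() for g in config.genes}
        if b.gene.upper() not in wanted:
            return False
    if config.min_depth is not None and b.depth < config.min_depth:
        return False
    if config.copy_numbers is not None and b.cn not in config.copy_numbers:
        return False
    if config.min_abs_log2 is not None and abs(b.log2) < config.min_abs_log2:
        return False
    if config.max_inhouse_freq is not None:
        freqs = [f for f in (b.het_del_freq, b.hom_del_freq, b.dup_freq) if f is not None]
        if freqs and max(freqs) > config.max_inhouse_freq:
            return False
    return True


def apply_custom_filters(bins: Sequence[AnnotatedBin], config: FilterConfig) -> list[AnnotatedBin]:
    """Apply the conjunction of all set custom filters, preserving order."""
    region = parse_region(config.region) if config.region else None
    return [b for b in bins if _bin_passes(b, config, region)]


def find_consecutive_runs(
    bins: Sequence[AnnotatedBin],
    direction: RunDirection | str,
    min_run: int = 2,
    thresholds: Thresholds | None = None,
) -> list[Run]:
    """Find maximal runs of consecutively aberrant exons.

    Within each (gene, chromosome) group, a run is a maximal stretch of bins
    with strictly consecutive exon indices that all satisfy the direction
    predicate (deletion: log2 below the heterozygous-deletion threshold;
    amplification: log2 above the duplication threshold). Runs shorter than
    ``min_run`` are discarded; runs never span genes or chromosomes.
    """
    if min_run < 1:
        raise ConfigError("min_run must be >= 1")
    if thresholds is None:
        thresholds = Thresholds()
    direction = RunDirection(direction)
    if direction is RunDirection.DELETION:
        pred = lambda b: b.log2 < thresholds.het_del_log2
    else:
        pred = lambda b: b.log2 > thresholds.dup_log2

    groups: dict[tuple[str, str], list[AnnotatedBin]] = {}
    for b in bins:
        if b.exon_index is None:
            continue
        groups.setdefault((b.gene, b.chromosome), []).append(b)

    runs: list[Run] = []
    for (gene, chrom), members in groups.items():
        members = sorted(members, key=lambda b: b.exon_index)
        current: list[AnnotatedBin] = []
        for b in members:
            if pred(b) and (not current or b.exon_index == current[-1].exon_index + 1):
                current.append(b)
            else:
                if len(current) >= min_run:
                    runs.append(Run(gene, chrom, direction, current))
                current = [b] if pred(b) else []
        if len(current) >= min_run:
            runs.append(Run(gene, chrom, direction, current))
    runs.sort(key=lambda r: (r.chromosome, r.gene, r.exon_from))
    return runs


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    q(i) = p(i) * m / rank(i) after ascending sort, made monotone by a
    running minimum from the largest rank downward and capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q
    return out.tolist()


@dataclass
class BintestResult:
    """Outcome of the re-derived bin-wise z-test."""

    tested: list[AnnotatedBin]
    significant: list[AnnotatedBin]
    alpha: float
    n_skipped: int = 0


def recompute_bintest(
    bins: Sequence[AnnotatedBin],
    reference: ExonReference,
    alpha: float = 0.05,
) -> BintestResult:
    """Re-derive per-bin significance against the cohort reference.

    Each resolvable bin (exon present in the reference with positive log2
    SD) gets z = (log2 - reference mean) / reference SD, a two-sided normal
    p-value, and a Benjamini-Hochberg adjusted p across all tested bins.
    A bin is significant when its adjusted p is at most ``alpha``.
    Unresolvable bins are skipped and counted.
    """
    testable: list[tuple[AnnotatedBin, float]] = []
    n_skipped = 0
    for b in bins:
        stats = None
        if b.exon_index is not None:
            stats = reference.lookup(b.gene, b.chromosome, b.exon_index)
        if stats is None or stats.sd_log2 <= 0.0:
            n_skipped += 1
            continue
        z = (b.log2 - stats.mean_log2) / stats.sd_log2
        testable.append((b, z))
    if not testable:
        raise ContentError("no bin is testable against this reference")
    if n_skipped:
        logger.info("bintest: skipped %d bin(s) unresolvable in the reference", n_skipped)

    p_raw = [2.0 * _scipy_stats.norm.sf(abs(z)) for _b, z in testable]
    p_adj = bh_adjust(p_raw)
    tested = []
    for (b, _z), p, q in zip(testable, p_raw, p_adj):
        tested.append(dataclasses.replace(b, p_value=p, p_adjusted=q))
    significant = [b for b in tested if b.p_adjusted <= alpha]
    return BintestResult(tested=tested, significant=significant, alpha=alpha, n_skipped=n_skipped)


def apply_preset(
    bins_cnr: Sequence[AnnotatedBin],
    bins_bintest: Sequence[AnnotatedBin] | None,
    config: FilterConfig,
    panel: PanelGeneList | None = None,
    thresholds: Thresholds | None = None,
) -> list[AnnotatedBin] | list[Run]:
    """Dispatch one of the seven presets, then apply the custom filters.

    total/bintest pass their input through unfiltered; candidate presets
    restrict to panel genes (symbol membership, case-insensitive);
    homozygous_deletion keeps homozygously deleted cnr bins; the
    consecutive presets return exon runs (a run survives the custom filters
    only if every one of its bins passes).
    """
    if thresholds is None:
        thresholds = Thresholds()
    preset = Preset(config.preset)

    if preset in (Preset.BINTEST, Preset.BINTEST_CANDIDATE) and bins_bintest is None:
        raise ConfigError(f"preset {preset.value!r} requires a bintest table")
    if preset in (Preset.TOTAL_CANDIDATE, Preset.BINTEST_CANDIDATE) and panel is None:
        raise ConfigError(f"preset {preset.value!r} requires a candidate gene panel")

    if preset is Preset.TOTAL:
        selected = list(bins_cnr)
    elif preset is Preset.BINTEST:
        selected = list(bins_bintest)
    elif preset is Preset.HOMOZYGOUS_DELETION:
        selected = [b for b in bins_cnr if b.call is CallCategory.HOMOZYGOUS_DELETION]
    elif preset is Preset.TOTAL_CANDIDATE:
        selected = [b for b in bins_cnr if b.gene in panel]
    elif preset is Preset.BINTEST_CANDIDATE:
        selected = [b for b in bins_bintest if b.gene in panel]
    else:
        direction = (
            RunDirection.DELETION if preset is Preset.CONSECUTIVE_DEL else RunDirection.AMPLIFICATION
        )
        runs = find_consecutive_runs(bins_cnr, direction, config.consecutive_cutoff, thresholds)
        region = parse_region(config.region) if config.region else None
        return [r for r in runs if all(_bin_passes(b, config, region) for b in r.bins)]

    return apply_custom_filters(selected, config)


# ---------------------------------------------------------------------------
# TSV emission of filtered grids

_BIN_TSV_COLUMNS = (
    "chromosome", "start", "end", "gene", "exon_index", "depth", "log2",
    "weight", "call", "cn", "het_del_freq", "hom_del_freq", "dup_freq",
    "highlight", "p_value", "p_adjusted",
)


def _bin_cells(b: AnnotatedBin) -> list[str]:
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, float):
            return f"{v:.6f}"
        if isinstance(v, bool):
            return str(v)
        return str(v)

    return [
        b.chromosome, str(b.start), str(b.end), b.gene, fmt(b.exon_index),
        fmt(b.depth), fmt(b.log2), fmt(b.weight), str(b.call), str(b.cn),
        fmt(b.het_del_freq), fmt(b.hom_del_freq), fmt(b.dup_freq),
        str(b.highlight), fmt(b.p_value), fmt(b.p_adjusted),
    ]


def write_bins_tsv(bins: Sequence[AnnotatedBin], path: str | os.PathLike) -> None:
    """Write an annotated data grid as TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_BIN_TSV_COLUMNS) + "\n")
        for b in bins:
            fh.write("\t".join(_bin_cells(b)) + "\n")


def write_runs_tsv(runs: Sequence[Run], path: str | os.PathLike) -> None:
    """Write consecutive-exon runs as a bin-level TSV with run ids."""
    columns = _BIN_TSV_COLUMNS + ("run_id", "run_length")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for run_id, run in enumerate(runs, start=1):
            for b in run.bins:
                fh.write("\t".join(_bin_cells(b) + [str(run_id), str(run.length)]) + "\n")
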