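"""Trio analysis: join an index sample's bins with parental cnr tables and
filter for candidate de novo CNVs.

The join is a left join on the exact bin key (chromosome, start, end, gene
label), so the output always has one row per index bin; parental fields are
missing where a parent lacks the bin.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

from .filters import AnnotatedBin, _bin_cells, _BIN_TSV_COLUMNS
from .io import CnrRecord, split_gene_label
from .reference import CallCategory, Thresholds, classify_log2

logger = logging.getLogger(__name__)


@dataclass
class TrioRecord:
    """One index bin with the matching parental log2/depth and calls."""

    bin: AnnotatedBin
    father_log2: float | None = None
    father_depth: float | None = None
    father_call: CallCategory | None = None
    mother_log2: float | None = None
    mother_depth: float | None = None
    mother_call: CallCategory | None = None

    @property
    def has_complete_parents(self) -> bool:
        return self.father_call is not None and self.mother_call is not None


def _parent_lookup(records: Sequence[CnrRecord], who: str) -> dict[tuple, CnrRecord]:
    table: dict[tuple, CnrRecord] = {}
    n_dup = 0
    for rec in records:
        # gene labels are reduced to symbols so "GENE_3"-style target names
        # join against annotated index bins
        key = (rec.chromosome, rec.start, rec.end, split_gene_label(rec.gene))
        if key in table:
            n_dup += 1  # first occurrence wins
            continue
        table[key] = rec
    if n_dup:
        logger.warning("%s cnr contains %d duplicate bin key(s); first occurrence used", who, n_dup)
    return table


def trio_join(
    index_bins: Sequence[AnnotatedBin],
    father_bins: Sequence[CnrRecord],
    mother_bins: Sequence[CnrRecord],
    thresholds: Thresholds | None = None,
) -> list[TrioRecord]:
    """Left-join parental bins onto the index sample.

    Exactly one output record per index bin; parental calls are derived by
    classifying the parental log2 with the same thresholds as the index.
    Duplicate keys within a parent resolve to the first occurrence (warned).
    """
    if thresholds is None:
        thresholds = Thresholds()
    father = _parent_lookup(father_bins, "father")
    mother = _parent_lookup(mother_bins, "mother")
    out = []
    for b in index_bins:
        key = (b.chromosome, b.start, b.end, b.gene)
        rec = TrioRecord(bin=b)
        f = father.get(key)
        m = mother.get(key)
        if f is not None:
            rec.father_log2 = f.log2
            rec.father_depth = f.depth
            rec.father_call = classify_log2(f.log2, thresholds)
        if m is not None:
            rec.mother_log2 = m.log2
            rec.mother_depth = m.depth
            rec.mother_call = classify_log2(m.log2, thresholds)
        out.append(rec)
    return out


@dataclass
class DenovoResult:
    """De novo candidates plus the count of bins with incomplete parents."""

    records: list[TrioRecord]
    n_missing_parent: int


def filter_denovo(records: Sequence[TrioRecord]) -> DenovoResult:
    """Keep candidate de novo bins: index aberrant, both parents normal.

    Records with missing parental data are excluded and counted separately
    rather than treated as de novo evidence.
    """
    kept = []
    n_missing = 0
    for r in records:
        if not r.has_complete_parents:
            n_missing += 1
            continue
        if (
            r.bin.call is not CallCategory.NORMAL
            and r.father_call is CallCategory.NORMAL
            and r.mother_call is CallCategory.NORMAL
        ):
            kept.append(r)
    return DenovoResult(records=kept, n_missing_parent=n_missing)


def write_trio_tsv(records: Sequence[TrioRecord], path: str | os.PathLike) -> None:
    """Write trio records: index columns plus father_/mother_ columns."""
    parental = (
        "father_log2", "father_depth", "father_call",
        "mother_log2", "mother_depth", "mother_call",
    )
    columns = _BIN_TSV_COLUMNS + parental

    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, float):
            return f"{v:.6f}"
        return str(v)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in records:
            cells = _bin_cells(r.bin) + [
                fmt(r.father_log2), fmt(r.father_depth), fmt(r.father_call),
                fmt(r.mother_log2), fmt(r.mother_depth), fmt(r.mother_call),
            ]
            fh.write("\t".join(cells) + "\n")
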