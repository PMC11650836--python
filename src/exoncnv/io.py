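"""Readers and writers for CNVkit-style tables, SNV VCFs, panels and configs.

All tab-separated tables are UTF-8 with LF line endings and a header row.
Coordinates follow the source conventions: cnr/bintest/cns intervals are
0-based half-open (BED-like), VCF positions are 1-based. Missing cells are
``.`` or the empty string on read and are written back as the empty string.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigError,
    ContentError,
    ParseError,
    SchemaError,
    VcfFormatError,
)

logger = logging.getLogger(__name__)

CNR_COLUMNS = ("chromosome", "start", "end", "gene", "depth", "log2", "weight")
CNS_COLUMNS = ("chromosome", "start", "end", "gene", "log2", "depth", "probes", "weight")
PVALUE_COLUMN = "p_bintest"

#: gene labels marking off-target/background bins; excluded from exon
#: indexing and reference building but retained for scatter plots.
ANTITARGET_LABELS = frozenset({"Antitarget", "-"})

_MISSING_CELLS = {"", "."}

# ---------------------------------------------------------------------------
# domain records


@dataclass
class CnrRecord:
    """One coverage bin of a cnr or bintest table.

    ``log2`` is the bias-corrected log2 coverage ratio of the bin against a
    pooled reference (0 ~ two copies); ``depth`` is the raw mean coverage.
    ``p_value`` is only populated for bintest rows (bin-wise z-test,
    multiple-testing corrected).
    """

    chromosome: str
    start: int
    end: int
    gene: str
    depth: float
    log2: float
    weight: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0 (got {self.depth})")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0 (got {self.weight})")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1] (got {self.p_value})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CnsSegment:
    """One post-segmentation region aggregating ``probes`` bins."""

    chromosome: str
    start: int
    end: int
    genes: list[str]
    log2: float
    depth: float
    probes: int
    weight: float
    cn: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.probes < 1:
            raise ValueError(f"probes must be >= 1 (got {self.probes})")
        if self.cn is not None and self.cn < 0:
            raise ValueError(f"cn must be >= 0 (got {self.cn})")


@dataclass
class SnvObservation:
    """A biallelic SNV with per-allele read support (1-based position)."""

    chromosome: str
    position: int
    ref_depth: int
    alt_depth: int
    genotype: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1 (got {self.position})")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allelic depths must be >= 0")


@dataclass
class AnnotsvRecord:
    """One AnnotSV full-annotation row reduced to the configured columns.

    ``values`` preserves the configured column order; missing cells are None.
    """

    values: dict[str, str | None]

    def get(self, column: str) -> str | None:
        return self.values.get(column)

    @property
    def columns(self) -> list[str]:
        return list(self.values)


@dataclass
class PanelGeneList:
    """A named candidate-gene panel (upper-cased, deduplicated symbols)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ContentError(f"panel {self.name!r} contains no genes")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes


#: env-file keys with package-defined meaning (other keys pass through).
IGV_LINK_KEY = "IGV_LINK_TEMPLATE"
REFERENCE_PATH_KEY = "REFERENCE_PATH"
PANEL_DIR_KEY = "PANEL_DIR"


@dataclass
class EnvConfig:
    """KEY=VALUE configuration (IGV link template, default paths)."""

    values: dict[str, str] = field(default_factory=dict)

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.values.get(key, default)


@dataclass(frozen=True)
class Region:
    """A query region; ``start``/``end`` are 1-based inclusive or None."""

    chromosome: str
    start: int | None = None
    end: int | None = None


# ---------------------------------------------------------------------------
# small shared helpers


def normalize_chromosome(chrom: str) -> str:
    """Lower-case and strip a leading 'chr' for order/equality comparisons."""
    c = chrom.lower()
    return c[3:] if c.startswith("chr") else c


_SPECIAL_CHROMS = {"x": 23, "y": 24, "m": 25, "mt": 25}


def chromosome_sort_key(chrom: str):
    """Natural chromosome order: 1..22, X, Y, MT, then lexicographic."""
    c = normalize_chromosome(chrom)
    if c.isdigit():
        return (0, int(c), "")
    if c in _SPECIAL_CHROMS:
        return (0, _SPECIAL_CHROMS[c], "")
    return (1, 0, c)


_REGION_RE = re.compile(r"^([^:]+)(?::([\d,]+)-([\d,]+))?$")


def parse_region(text: str) -> Region:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive display)."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ConfigError(f"malformed region string: {text!r}")
    chrom, s, e = m.groups()
    if s is None:
        return Region(chrom)
    start, end = int(s.replace(",", "")), int(e.replace(",", ""))
    if start < 1 or end < start:
        raise ConfigError(f"malformed region interval: {text!r}")
    return Region(chrom, start, end)


def split_gene_label(label: str) -> str:
    """Reduce a CNVkit target label to its gene symbol.

    Labels of the form ``GENE_3`` (final underscore followed by a purely
    numeric suffix) are read as gene ``GENE``; anything else is used verbatim.
    """
    head, sep, tail = label.rpartition("_")
    if sep and head and tail.isdigit():
        return head
    return label


def _parse_float(value: str, column: str, row: int) -> float:
    v = value.strip()
    if v in _MISSING_CELLS:
        raise ParseError(f"row {row}: column {column!r} has a missing value")
    try:
        return float(v)
    except ValueError:
        raise ParseError(f"row {row}: column {column!r} is not numeric: {value!r}") from None


def _parse_int(value: str, column: str, row: int) -> int:
    v = value.strip()
    if v in _MISSING_CELLS:
        raise ParseError(f"row {row}: column {column!r} has a missing value")
    try:
        return int(v)
    except ValueError:
        raise ParseError(f"row {row}: column {column!r} is not an integer: {value!r}") from None


def _read_table(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return df


def _fmt(value: float | int | str | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


# ---------------------------------------------------------------------------
# cnr / bintest / cns


def read_cnr_like(path: str | os.PathLike, expect_pvalue: bool = False) -> list[CnrRecord]:
    """Read a cnr (or, with ``expect_pvalue``, bintest) table.

    Row order is preserved. A p-value column is parsed whenever present;
    ``expect_pvalue`` only makes its absence a schema error.
    """
    required = list(CNR_COLUMNS) + ([PVALUE_COLUMN] if expect_pvalue else [])
    df = _read_table(path, required)
    has_p = PVALUE_COLUMN in df.columns
    records: list[CnrRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cells = dict(zip(df.columns, row))
        p_raw = cells.get(PVALUE_COLUMN, "") if has_p else ""
        p = None if str(p_raw).strip() in _MISSING_CELLS else _parse_float(str(p_raw), PVALUE_COLUMN, i)
        try:
            records.append(
                CnrRecord(
                    chromosome=str(cells["chromosome"]).strip(),
                    start=_parse_int(str(cells["start"]), "start", i),
                    end=_parse_int(str(cells["end"]), "end", i),
                    gene=str(cells["gene"]).strip(),
                    depth=_parse_float(str(cells["depth"]), "depth", i),
                    log2=_parse_float(str(cells["log2"]), "log2", i),
                    weight=_parse_float(str(cells["weight"]), "weight", i),
                    p_value=p,
                )
            )
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from None
    return records


def write_cnr_like(records: Iterable[CnrRecord], path: str | os.PathLike) -> None:
    """Write cnr/bintest records; the p-value column appears only when used.

    Floats are serialized at 6 decimal places, so write-then-read
    reproduces every field at that precision and re-writing is byte-stable.
    """
    records = list(records)
    with_p = any(r.p_value is not None for r in records)
    columns = list(CNR_COLUMNS) + ([PVALUE_COLUMN] if with_p else [])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in records:
            cells = [r.chromosome, str(r.start), str(r.end), r.gene,
                     _fmt(r.depth), _fmt(r.log2), _fmt(r.weight)]
            if with_p:
                cells.append(_fmt(r.p_value))
            fh.write("\t".join(cells) + "\n")


def read_cns(path: str | os.PathLike) -> list[CnsSegment]:
    """Read a cns segment table; comma-joined gene cells become lists."""
    df = _read_table(path, CNS_COLUMNS)
    has_cn = "cn" in df.columns
    segments: list[CnsSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cells = dict(zip(df.columns, row))
        gene_cell = str(cells["gene"]).strip()
        genes = [g.strip() for g in gene_cell.split(",") if g.strip()] if gene_cell not in _MISSING_CELLS else []
        cn = None
        if has_cn and str(cells["cn"]).strip() not in _MISSING_CELLS:
            cn = _parse_int(str(cells["cn"]), "cn", i)
        try:
            segments.append(
                CnsSegment(
                    chromosome=str(cells["chromosome"]).strip(),
                    start=_parse_int(str(cells["start"]), "start", i),
                    end=_parse_int(str(cells["end"]), "end", i),
                    genes=genes,
                    log2=_parse_float(str(cells["log2"]), "log2", i),
                    depth=_parse_float(str(cells["depth"]), "depth", i),
                    probes=_parse_int(str(cells["probes"]), "probes", i),
                    weight=_parse_float(str(cells["weight"]), "weight", i),
                    cn=cn,
                )
            )
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from None
    return segments


def write_cns(segments: Iterable[CnsSegment], path: str | os.PathLike) -> None:
    segments = list(segments)
    with_cn = any(s.cn is not None for s in segments)
    columns = list(CNS_COLUMNS) + (["cn"] if with_cn else [])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for s in segments:
            cells = [s.chromosome, str(s.start), str(s.end), ",".join(s.genes),
                     _fmt(s.log2), _fmt(s.depth), str(s.probes), _fmt(s.weight)]
            if with_cn:
                cells.append("" if s.cn is None else str(s.cn))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_snvs_from_vcf(path: str | os.PathLike, region: str | Region | None = None) -> list[SnvObservation]:
    """Extract biallelic SNV allele depths from a VCF (plain or bgzip).

    Allelic depths come from the per-sample AD field of the first sample;
    records lacking AD fall back to a genotype convention where het gives
    (1, 1) and homozygous genotypes give (1, 0)/(0, 1), so the downstream
    allelic balance is exactly 0, 0.5 or 1. Multiallelic records and records
    without usable genotype information are skipped (a count is logged).
    An unknown region yields an empty collection, not an error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if isinstance(region, str):
        region = parse_region(region)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc

    observations: list[SnvObservation] = []
    n_multiallelic = 0
    n_unusable = 0
    try:
        for v in vcf:
            if region is not None:
                if normalize_chromosome(v.CHROM) != normalize_chromosome(region.chromosome):
                    continue
                if region.start is not None and not region.start <= v.POS <= region.end:
                    continue
            if len(v.ALT) != 1:
                n_multiallelic += 1
                continue
            genotype = None
            if v.genotypes:
                a, b = v.genotypes[0][0], v.genotypes[0][1]
                sep = "|" if v.genotypes[0][-1] else "/"
                if a >= 0 and b >= 0:
                    genotype = f"{a}{sep}{b}"
            ref_d = alt_d = None
            try:
                ad = v.format("AD")
            except Exception:
                ad = None
            if ad is not None and ad.shape[-1] >= 2:
                r, a_ = int(ad[0][0]), int(ad[0][1])
                if r >= 0 and a_ >= 0:
                    ref_d, alt_d = r, a_
            if ref_d is None:
                if genotype is None:
                    n_unusable += 1
                    continue
                alleles = sorted(int(x) for x in genotype.replace("|", "/").split("/"))
                if alleles == [0, 1]:
                    ref_d, alt_d = 1, 1
                elif alleles == [0, 0]:
                    ref_d, alt_d = 1, 0
                else:
                    ref_d, alt_d = 0, 1
            observations.append(
                SnvObservation(chromosome=v.CHROM, position=v.POS,
                               ref_depth=ref_d, alt_depth=alt_d, genotype=genotype)
            )
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(f"error while reading VCF {path}: {exc}") from exc
    if n_multiallelic:
        logger.info("skipped %d multiallelic record(s) in %s", n_multiallelic, path.name)
    if n_unusable:
        logger.info("skipped %d record(s) without AD or genotype in %s", n_unusable, path.name)
    return observations


# ---------------------------------------------------------------------------
# AnnotSV tables


def read_column_config(path: str | os.PathLike) -> list[str]:
    """Read a column-selection config: one name per line, or one tab line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if len(lines) == 1 and "\t" in lines[0]:
        columns = [c.strip() for c in lines[0].split("\t") if c.strip()]
    else:
        columns = lines
    if not columns:
        raise ConfigError(f"column config {path.name} names no columns")
    return columns


def read_annotsv_table(path: str | os.PathLike, column_config: Sequence[str]) -> list[AnnotsvRecord]:
    """Reduce an AnnotSV full-annotation TSV to the configured columns.

    The output records expose exactly the configured columns in configured
    order, whatever the file's own column order. Configured columns absent
    from the file raise a SchemaError naming all of them.
    """
    if not column_config:
        raise ConfigError("column config must name at least one column")
    df = _read_table(path, [])
    missing = [c for c in column_config if c not in df.columns]
    if missing:
        raise SchemaError(f"AnnotSV table is missing configured column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        cells = dict(zip(df.columns, row))
        values = {
            c: (None if str(cells[c]).strip() in _MISSING_CELLS else str(cells[c]))
            for c in column_config
        }
        records.append(AnnotsvRecord(values=values))
    return records


#: canonical AnnotSV column names for the roles the filters need.
_ANNOTSV_ROLE_DEFAULTS = {
    "chromosome": "SV_chrom",
    "start": "SV_start",
    "end": "SV_end",
    "sv_type": "SV_type",
    "genes": "Gene_name",
    "acmg": "ACMG_class",
}


def resolve_annotsv_keys(columns: Sequence[str]) -> dict[str, str | None]:
    """Map filter roles to actual column names (case-insensitive match)."""
    lower = {c.lower(): c for c in columns}
    return {role: lower.get(name.lower()) for role, name in _ANNOTSV_ROLE_DEFAULTS.items()}


def filter_annotsv(
    records: Sequence[AnnotsvRecord],
    sv_type: str | None = None,
    panel: PanelGeneList | None = None,
    min_acmg_class: int | None = None,
) -> list[AnnotsvRecord]:
    """Conjunction filter over reduced AnnotSV records.

    Filtering on a role whose column is not configured raises a ConfigError.
    ACMG cells that do not parse as an integer fail the ACMG filter.
    """
    if not records:
        return []
    keys = resolve_annotsv_keys(records[0].columns)

    def _need(role: str) -> str:
        col = keys[role]
        if col is None:
            raise ConfigError(
                f"filter needs AnnotSV column {_ANNOTSV_ROLE_DEFAULTS[role]!r}, "
                "which is not in the column config"
            )
        return col

    out = []
    for rec in records:
        if sv_type is not None:
            cell = rec.get(_need("sv_type"))
            if cell is None or cell.upper() != sv_type.upper():
                continue
        if panel is not None:
            cell = rec.get(_need("genes")) or ""
            symbols = {s.strip().upper() for s in re.split(r"[;,/]", cell) if s.strip()}
            if not symbols & panel.genes:
                continue
        if min_acmg_class is not None:
            cell = rec.get(_need("acmg")) or ""
            m = re.search(r"\d+", cell)
            if not m or int(m.group()) < min_acmg_class:
                continue
        out.append(rec)
    return out


def write_annotsv_tsv(records: Sequence[AnnotsvRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if records:
            columns = records[0].columns
            fh.write("\t".join(columns) + "\n")
            for rec in records:
                fh.write("\t".join("" if rec.get(c) is None else str(rec.get(c)) for c in columns) + "\n")


# ---------------------------------------------------------------------------
# panels and env configs


def load_panel(
    path: str | os.PathLike,
    kind: str = "txt",
    confidence: str | None = None,
) -> PanelGeneList:
    """Load a candidate-gene panel.

    ``txt``: one symbol per line, ``#`` comments allowed. ``panelapp_tsv``:
    tab-separated with a header; the gene-symbol column is the first whose
    header contains "symbol" (case-insensitive). With ``confidence`` set,
    rows are restricted to an exact match in the first column whose header
    contains "confidence" or "status".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    name = path.stem
    if kind == "txt":
        symbols = set()
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line.upper())
    elif kind == "panelapp_tsv":
        df = _read_table(path, [])
        symbol_cols = [c for c in df.columns if "symbol" in c.lower()]
        if not symbol_cols:
            raise SchemaError(f"{path.name}: no column header containing 'symbol'")
        if confidence is not None:
            conf_cols = [c for c in df.columns if "confidence" in c.lower() or "status" in c.lower()]
            if not conf_cols:
                raise SchemaError(f"{path.name}: no confidence/status column to filter on")
            df = df[df[conf_cols[0]].str.strip() == confidence]
        symbols = {
            s.strip().upper()
            for s in df[symbol_cols[0]].tolist()
            if s.strip() not in _MISSING_CELLS
        }
    else:
        raise ConfigError(f"unknown panel kind: {kind!r}")
    if not symbols:
        raise ContentError(f"panel file {path.name} yielded no gene symbols")
    return PanelGeneList(name=name, genes=frozenset(symbols))


def write_panel(panel: PanelGeneList, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(panel.genes):
            fh.write(g + "\n")


def read_env(path: str | os.PathLike) -> EnvConfig:
    """Parse a KEY=VALUE env file; duplicate keys are a ConfigError."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    values: dict[str, str] = {}
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"env file line {i} is not KEY=VALUE: {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key in values:
            raise ConfigError(f"duplicate env key: {key}")
        values[key] = value.strip()
    return EnvConfig(values=values)


# ---------------------------------------------------------------------------
# exon indexing


def assign_exon_indices(records: Iterable[CnrRecord]) -> dict[tuple[str, str], list[CnrRecord]]:
    """Group bins by (gene, chromosome) and order them by genomic start.

    The exon index of a bin is its 1-based position in the returned list.
    Target labels with a numeric underscore suffix (``GENE_3``) collapse to
    their gene symbol; antitarget/background bins are excluded. The result
    is invariant under permutation of the input rows.
    """
    groups: dict[tuple[str, str], list[CnrRecord]] = {}
    for rec in records:
        if rec.gene in ANTITARGET_LABELS:
            continue
        gene = split_gene_label(rec.gene)
        groups.setdefault((gene, rec.chromosome), []).append(rec)
    for key in groups:
        groups[key].sort(key=lambda r: (r.start, r.end))
    return groups


def iter_indexed_bins(groups: Mapping[tuple[str, str], list[CnrRecord]]):
    """Yield (gene, chromosome, exon_index, record) over an index mapping."""
    for (gene, chrom), recs in groups.items():
        for i, rec in enumerate(recs, start=1):
            yield gene, chrom, i, rec
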