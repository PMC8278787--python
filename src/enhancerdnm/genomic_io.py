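"""Readers/writers for the interval and variant formats the pipeline touches.

Coordinate conventions
----------------------
Intervals are BED-style 0-based half-open internally.  Browser-style
coordinates (1-based inclusive, e.g. ``chr10:128,568,604-128,569,741``)
convert by subtracting 1 from the start.  De novo variant (DNV) positions are
1-based, so a DNV at position ``p`` falls inside a region iff
``start < p <= end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Region",
    "DNVRecord",
    "TssAnnotation",
    "read_bed",
    "write_bed",
    "read_dnv_table",
    "write_dnv_table",
    "assign_dnvs_to_regions",
    "promoters_from_tss",
    "read_tss_table",
    "parse_region_string",
    "normalize_chrom",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position falls in this region."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class DNVRecord:
    """A single-nucleotide de novo variant call in one proband."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    cohort_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"DNV position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return self.ref in _BASES and self.alt in _BASES


@dataclass(frozen=True)
class TssAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"TSS position must be >= 1, got {self.tss}")


def normalize_chrom(chrom: str, add_prefix: bool = True) -> str:
    """Normalize mixed hg38/GRCh38 chromosome dialects (``10`` vs ``chr10``)."""
    if add_prefix:
        return chrom if chrom.startswith("chr") else "chr" + chrom
    return chrom[3:] if chrom.startswith("chr") else chrom


def parse_region_string(text: str) -> Region:
    """Parse ``chrom:start-end`` (0-based half-open, commas allowed)."""
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
    if m is None:
        raise ValueError(f"cannot parse region string {text!r}")
    return Region(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


def read_bed(path, chrom_prefix: bool | None = None) -> list[Region]:
    """Read a BED3/BED4/BED6 file into validated Regions.

    Parameters
    ----------
    chrom_prefix : optional bool
        When not None, chromosome names are normalized to carry (True) or
        drop (False) the ``chr`` prefix.  Default leaves names untouched.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed coordinates") from exc
            if chrom_prefix is not None:
                chrom = normalize_chrom(chrom, add_prefix=chrom_prefix)
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                regions.append(Region(chrom, start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


_DNV_REQUIRED = ("chrom", "pos", "ref", "alt", "sample")


def read_dnv_table(path, cohort_id: str = "", chrom_prefix: bool | None = None):
    """Read a tab-delimited DNV table.

    Returns ``(records, excluded)`` where ``excluded`` collects rows whose
    ref/alt are not single A/C/G/T bases (indels, MNVs): the rate model is
    substitution-only, but the events are preserved for reporting.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.lower() for c in df.columns]
    for col in _DNV_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records: list[DNVRecord] = []
    excluded: list[DNVRecord] = []
    for row in df.itertuples(index=False):
        chrom = row.chrom
        if chrom_prefix is not None:
            chrom = normalize_chrom(chrom, add_prefix=chrom_prefix)
        cohort = getattr(row, "cohort", None) or cohort_id
        rec = DNVRecord(chrom, int(row.pos), row.ref.upper(), row.alt.upper(),
                        row.sample, cohort)
        (records if rec.is_snv else excluded).append(rec)
    return records, excluded


def write_dnv_table(records: Iterable[DNVRecord], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("chrom\tpos\tref\talt\tsample\tcohort\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.sample_id}\t{r.cohort_id}\n")


def assign_dnvs_to_regions(
    dnvs: Iterable[DNVRecord], regions: Iterable[Region]
) -> dict[Region, list[DNVRecord]]:
    """Map each region to the DNVs it contains (bedtools-intersect semantics).

    A DNV may land in multiple overlapping regions; DNVs outside every region
    are simply unassigned.
    """
    regions = list(regions)
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: dict[Region, list[DNVRecord]] = {r: [] for r in regions}
    for d in dnvs:
        for r in by_chrom.get(d.chrom, ()):
            if r.start < d.pos <= r.end:
                out[r].append(d)
    return out


def read_tss_table(path) -> list[TssAnnotation]:
    """Read a TSV with columns gene_id, chrom, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.lower() for c in df.columns]
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        TssAnnotation(row.gene_id, row.chrom, int(row.tss), row.strand)
        for row in df.itertuples(index=False)
    ]


def promoters_from_tss(
    tss_list: Iterable[TssAnnotation],
    chrom_sizes: Mapping[str, int],
    flank: int = 5000,
) -> list[Region]:
    """Strand-aware promoter intervals: the ``flank`` bp upstream of each TSS.

    For a + strand gene with 1-based TSS t this is [t-1-flank, t-1) in 0-based
    coordinates, clamped at the chromosome start; for a - strand gene it is
    [t, t+flank) clamped at the chromosome end.  Each promoter carries its
    gene_id as the region name.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    promoters = []
    for t in tss_list:
        if t.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {t.chrom!r} for gene {t.gene_id}")
        size = chrom_sizes[t.chrom]
        if t.strand == "+":
            start, end = max(0, t.tss - 1 - flank), t.tss - 1
        else:
            start, end = t.tss, min(size, t.tss + flank)
        if end <= start:  # TSS at the very contig edge: no upstream sequence
            continue
        promoters.append(Region(t.chrom, start, end, name=t.gene_id, strand=t.strand))
    return promoters
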