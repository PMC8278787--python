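"""Copy-number classification of a region from windowed CN estimates.

Consumes per-sample tables of 1-kbp window copy-number estimates (the output
format of k-mer depth genotypers), averages the windows overlapping a region
(bedtools-map ``mean`` semantics: any overlap counts, no length weighting)
and calls deletion below 1.3 copies and duplication above 2.7, boundary
values being normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genomic_io import Region

__all__ = [
    "CNWindow",
    "DELETION_THRESHOLD",
    "DUPLICATION_THRESHOLD",
    "read_cn_windows",
    "mean_cn_over_region",
    "classify_cn",
    "screen_cohort_cn",
]

DELETION_THRESHOLD = 1.3
DUPLICATION_THRESHOLD = 2.7


@dataclass(frozen=True)
class CNWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    cn: float
    sample_id: str = ""

    def __post_init__(self):
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")
        if self.end <= self.start:
            raise ValueError(f"degenerate window {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, region: Region) -> bool:
        return self.chrom == region.chrom and self.start < region.end and self.end > region.start


def read_cn_windows(path, sample_id: str = "") -> list[CNWindow]:
    """Read a BED4-like TSV ``chrom start end cn``."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "cn"])
    return [
        CNWindow(str(r.chrom), int(r.start), int(r.end), float(r.cn), sample_id)
        for r in df.itertuples(index=False)
    ]


def mean_cn_over_region(windows: Iterable[CNWindow], region: Region) -> float:
    """Unweighted mean copy number over all windows overlapping the region."""
    cns = [w.cn for w in windows if w.overlaps(region)]
    if not cns:
        raise ValueError(
            f"no copy-number windows overlap {region.chrom}:{region.start}-{region.end}"
        )
    return sum(cns) / len(cns)


def classify_cn(mean_cn: float) -> str:
    """'deletion' below 1.3 copies, 'duplication' above 2.7, else 'normal'."""
    if mean_cn < 0:
        raise ValueError(f"mean copy number must be >= 0, got {mean_cn}")
    if mean_cn < DELETION_THRESHOLD:
        return "deletion"
    if mean_cn > DUPLICATION_THRESHOLD:
        return "duplication"
    return "normal"


def screen_cohort_cn(
    windows_by_sample: Mapping[str, Iterable[CNWindow]],
    region: Region,
    min_windows: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-sample CN calls over a region plus cohort summary counts.

    Samples with fewer than ``min_windows`` overlapping windows raise, since
    a call from too few windows is unreliable.
    Returns ``(calls, summary)`` where ``calls`` has columns sample, mean_cn,
    call and ``summary`` counts n_del / n_dup / n_normal.
    """
    if not windows_by_sample:
        raise ValueError("at least one sample is required")
    rows = []
    for sample, windows in windows_by_sample.items():
        overlapping = [w for w in windows if w.overlaps(region)]
        if len(overlapping) < min_windows:
            raise ValueError(
                f"sample {sample}: {len(overlapping)} windows overlap "
                f"{region.chrom}:{region.start}-{region.end}, need >= {min_windows}"
            )
        mean = sum(w.cn for w in overlapping) / len(overlapping)
        rows.append({"sample": sample, "mean_cn": mean, "call": classify_cn(mean)})
    calls = pd.DataFrame(rows)
    summary = {
        "n_del": int((calls["call"] == "deletion").sum()),
        "n_dup": int((calls["call"] == "duplication").sum()),
        "n_normal": int((calls["call"] == "normal").sum()),
    }
    return calls, summary
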