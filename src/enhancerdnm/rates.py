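"""Trinucleotide-context germline mutation-rate model.

The null model for de novo substitution counts is Poisson per site and
alternate allele: across ``N`` sequenced trios the expected number of DNVs at
a site with trinucleotide context ``c`` mutating to base ``a`` is

    lambda = 2 * N * mu(c, a)

where ``mu`` is the per-site, per-generation, per-haploid-genome substitution
probability and the factor 2 counts the two transmitted haplotypes per trio.
A region is annotated into a :class:`SiteAlleleGrid` holding every
(position, alt) intensity together with a functional weight in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic_io import Region

__all__ = [
    "RateTable",
    "SiteAlleleGrid",
    "GridEntry",
    "load_rate_table",
    "demo_rate_table",
    "demo_rate_table_path",
    "annotate_region",
    "revcomp",
    "load_weight_table",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
N_CONTEXTS = 64
N_ENTRIES = 192  # 64 contexts x 3 alternate alleles
MU_MAX = 1e-4


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RateTable:
    """Map (trinucleotide context, alt base) -> substitution probability mu."""

    entries: Mapping[tuple[str, str], float]
    strand_closed: bool = False

    def mu(self, context: str, alt: str) -> float:
        return self.entries[(context, alt)]

    def __len__(self) -> int:
        return len(self.entries)

    def mean_mu(self) -> float:
        return float(np.mean(list(self.entries.values())))

    def check_strand_closure(self, tol: float = 1e-12) -> bool:
        """Whether mu(c, a) == mu(revcomp(c), complement(a)) throughout."""
        for (ctx, alt), mu in self.entries.items():
            mate = (revcomp(ctx), alt.translate(_COMPLEMENT))
            if mate not in self.entries or abs(self.entries[mate] - mu) > tol:
                return False
        return True


def _validate_entry(context: str, alt: str, mu: float) -> None:
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValueError(f"invalid context {context!r}")
    if alt not in _BASES:
        raise ValueError(f"invalid alt base {alt!r}")
    if alt == context[1]:
        raise ValueError(f"alt {alt} equals the context center base in {context}")
    if not 0 < mu < MU_MAX:
        raise ValueError(f"mu for ({context}, {alt}) must lie in (0, {MU_MAX}), got {mu}")


def load_rate_table(path, strand_closure: bool = False) -> RateTable:
    """Load a rate TSV with columns ``context``, ``alt``, ``mu``.

    With ``strand_closure`` set, entries missing their reverse-complement mate
    are filled by symmetry; a mate present with a conflicting value is an
    error.  The completed table must have all 192 entries.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"context": str, "alt": str})
    for col in ("context", "alt", "mu"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    entries: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        ctx, alt, mu = row.context.upper(), row.alt.upper(), float(row.mu)
        _validate_entry(ctx, alt, mu)
        if (ctx, alt) in entries:
            raise ValueError(f"duplicate rate entry ({ctx}, {alt})")
        entries[(ctx, alt)] = mu
    if strand_closure:
        for (ctx, alt), mu in list(entries.items()):
            mate = (revcomp(ctx), alt.translate(_COMPLEMENT))
            if mate in entries:
                if abs(entries[mate] - mu) > 1e-12:
                    raise ValueError(
                        f"strand-closure conflict: {mate} = {entries[mate]} vs "
                        f"revcomp of ({ctx}, {alt}) = {mu}"
                    )
            else:
                entries[mate] = mu
    if len(entries) != N_ENTRIES:
        raise ValueError(f"rate table has {len(entries)} entries, expected {N_ENTRIES}")
    return RateTable(entries, strand_closed=strand_closure)


def demo_rate_table(mu_transition: float = 1.5e-8, mu_transversion: float = 5e-9) -> RateTable:
    """A synthetic demonstration table: context-independent transition/
    transversion rates of order 1e-8 with the canonical ~3:1 ratio.

    This is illustrative package data for no-download runs, not an empirical
    germline rate estimate.
    """
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    entries = {}
    for x in _BASES:
        for ref in _BASES:
            for y in _BASES:
                ctx = x + ref + y
                for alt in _BASES:
                    if alt == ref:
                        continue
                    mu = mu_transition if transitions[ref] == alt else mu_transversion
                    entries[(ctx, alt)] = mu
    return RateTable(entries, strand_closed=True)


def write_rate_table(table: RateTable, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("context\talt\tmu\n")
        for (ctx, alt), mu in sorted(table.entries.items()):
            fh.write(f"{ctx}\t{alt}\t{mu:.6e}\n")


def demo_rate_table_path():
    """Path to the bundled synthetic demonstration rate table."""
    return resources.files("enhancerdnm").joinpath("data/demo_rate_table.tsv")


@dataclass(frozen=True)
class GridEntry:
    pos: int  # 1-based
    ref: str
    alt: str
    lam: float
    w: float


@dataclass
class SiteAlleleGrid:
    """Per-region lattice of null DNV intensities and functional weights."""

    region: Region
    entries: list[GridEntry]
    n_trios: int
    skipped_sites: int = 0

    @property
    def total_lam(self) -> float:
        return float(sum(e.lam for e in self.entries))

    @property
    def lams(self) -> np.ndarray:
        return np.array([e.lam for e in self.entries])

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.w for e in self.entries])

    def lookup(self) -> dict[tuple[int, str], GridEntry]:
        cached = getattr(self, "_lookup", None)
        if cached is None or len(cached) != len(self.entries):
            cached = {(e.pos, e.alt): e for e in self.entries}
            object.__setattr__(self, "_lookup", cached)
        return cached


def annotate_region(
    sequence: str,
    region: Region,
    table: RateTable,
    n_trios: int,
    weights: Mapping[tuple[int, str], float] | None = None,
    sequence_start: int | None = None,
) -> SiteAlleleGrid:
    """Build the site-by-allele intensity grid for one region.

    Parameters
    ----------
    sequence : str
        Reference bases covering at least [region.start - 1, region.end + 1)
        so every internal site has a full trinucleotide context.  Sites whose
        context is unavailable (contig edge) or contains a non-ACGT base are
        skipped and counted.
    weights : optional map (1-based pos, alt) -> score
        Functional weights, clipped into [0, 1].  Default is uniform w = 1,
        which reduces the load statistic to a rate-weighted burden.
    sequence_start : optional int
        0-based genomic position of ``sequence[0]``; defaults to
        ``region.start - 1`` (the minimal padded slice).
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    seq = sequence.upper()
    offset = region.start - 1 if sequence_start is None else sequence_start
    if offset > region.start - 1 and region.start > 0:
        raise ValueError("sequence does not cover the left flank of the region")
    entries: list[GridEntry] = []
    skipped = 0
    for pos0 in range(region.start, region.end):  # 0-based site
        i = pos0 - offset
        if i - 1 < 0 or i + 1 >= len(seq):
            skipped += 1  # terminal site at a contig edge
            continue
        ctx = seq[i - 1 : i + 2]
        if any(b not in "ACGT" for b in ctx):
            skipped += 1
            continue
        ref = ctx[1]
        for alt in _BASES:
            if alt == ref:
                continue
            lam = 2.0 * n_trios * table.mu(ctx, alt)
            w = 1.0
            if weights is not None:
                w = float(np.clip(weights.get((pos0 + 1, alt), 0.0), 0.0, 1.0))
            entries.append(GridEntry(pos0 + 1, ref, alt, lam, w))
    return SiteAlleleGrid(region=region, entries=entries, n_trios=n_trios, skipped_sites=skipped)


def load_weight_table(path) -> dict[tuple[int, str], float]:
    """Read a per-allele score TSV (chrom pos alt score) and min-max scale
    scores to [0, 1].  Returns a (pos, alt) -> weight map (single-chromosome
    use; the chrom column is carried through for provenance only)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("pos", "alt", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    scores = df["score"].astype(float)
    lo, hi = scores.min(), scores.max()
    scaled = np.zeros(len(scores)) if hi == lo else (scores - lo) / (hi - lo)
    return {
        (int(p), str(a).upper()): float(s)
        for p, a, s in zip(df["pos"], df["alt"], scaled)
    }
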