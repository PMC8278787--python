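"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic given its seed and emulates one input class:

* a random reference contig with i.i.d. bases at a set GC fraction, with the
  tested regions (enhancer-sized intervals) placed along it;
* trio-cohort DNV tables drawn from the context-dependent Poisson null
  lambda = 2 N mu(context, alt), with an optional per-region enrichment
  multiplier gamma on lambda (gamma = 1 is the exact null of the load test;
  enrichment is the simplest alternative consistent with a Poisson null);
* per-sample windowed copy-number tables with planted deletion/duplication
  events on a diploid baseline;
* expression matrices with linear age/brain-region effects and a planted
  co-expression module at a chosen rank correlation (Gaussian copula);
* phenotype tables with per-group Bernoulli prevalences and NA masking.

Cohort sizes default to the study conditions: a 516-trio discovery cohort
and a 2155-trio replication cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import CNWindow
from .exprcorr import ExpressionMatrix
from .burden import PhenotypeTable, PRESENT, ABSENT, MISSING
from .genomic_io import DNVRecord, Region
from .rates import RateTable, annotate_region

__all__ = [
    "SimulationConfig",
    "generate_genome",
    "place_regions",
    "simulate_trio_dnvs",
    "simulate_weights",
    "simulate_cn_windows",
    "simulate_expression",
    "simulate_phenotypes",
    "synthetic_phenotype_reconstruction",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs for every generator; defaults are the study conditions."""

    seed: int = 0
    # genome
    contig_name: str = "chrS"
    gc: float = 0.41
    # regions (VISTA-enhancer-sized intervals)
    n_regions: int = 20
    region_length: tuple[int, int] = (2000, 3000)
    region_gap: int = 500
    # trio cohorts: (label, n_trios)
    cohorts: tuple[tuple[str, int], ...] = (("discovery", 516), ("replication", 2155))
    # per-region enrichment multiplier gamma on lambda (missing -> 1.0)
    enrichment: dict[str, float] = field(default_factory=dict)
    # copy-number screen
    cn_n_samples: int = 10
    cn_noise_sd: float = 0.05
    cn_window_size: int = 1000
    # expression screen
    expr_n_background: int = 500
    expr_module_size: int = 40
    expr_n_samples: int = 200
    expr_rho: float = 0.8
    expr_age_range: tuple[float, float] = (8.0, 40.0)
    expr_regions: tuple[str, ...] = ("cortex", "cerebellum", "thalamus")
    # phenotypes
    pheno_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"coding": 20, "noncoding": 3}
    )
    pheno_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "id_gdd": {"coding": 0.95, "noncoding": 0.02},
            "autism": {"coding": 0.15, "noncoding": 0.98},
            "hypotonia": {"coding": 0.8, "noncoding": 0.9},
        }
    )
    pheno_missingness: float = 0.1


def generate_genome(config: SimulationConfig, length: int | None = None) -> dict[str, str]:
    """Seeded i.i.d. reference contig at the configured GC fraction."""
    if length is None:
        length = config.n_regions * (config.region_length[1] + config.region_gap) + 2 * config.region_gap
    if length < 1000:
        raise ValueError("contig length must be >= 1000")
    rng = np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return {config.contig_name: seq}


def place_regions(config: SimulationConfig, genome: Mapping[str, str]) -> list[Region]:
    """Non-overlapping enhancer-sized regions tiled along the contig."""
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.contig_name
    size = len(genome[chrom])
    regions = []
    cursor = config.region_gap
    for i in range(config.n_regions):
        length = int(rng.integers(config.region_length[0], config.region_length[1] + 1))
        if cursor + length > size - 1:
            raise ValueError("contig too short for the requested regions")
        regions.append(Region(chrom, cursor, cursor + length, name=f"region_{i:03d}"))
        cursor += length + config.region_gap
    return regions


def _region_grid(genome, region, table, n_trios, weights=None):
    seq = genome[region.chrom]
    lo = max(0, region.start - 1)
    return annotate_region(seq[lo : region.end + 1], region, table, n_trios,
                           weights=weights, sequence_start=lo)


def simulate_weights(
    genome: Mapping[str, str],
    regions: Sequence[Region],
    seed: int,
    lattice: float = 0.01,
    lo: float = 0.05,
    hi: float = 1.0,
) -> dict[tuple[int, str], float]:
    """Per-(pos, alt) functional scores, uniform on a fixed-precision lattice.

    Continuous-valued scores make the null distribution of the weighted load
    effectively continuous, which is what real deleteriousness scores look
    like after min-max scaling; the lattice keeps exact tail computation
    available.
    """
    rng = np.random.default_rng(seed)
    levels = np.arange(round(lo / lattice), round(hi / lattice) + 1)
    out: dict[tuple[int, str], float] = {}
    for region in regions:
        for pos0 in range(region.start, region.end):
            for alt in "ACGT":
                out[(pos0 + 1, alt)] = float(rng.choice(levels) * lattice)
    return out


def simulate_trio_dnvs(
    genome: Mapping[str, str],
    regions: Sequence[Region],
    table: RateTable,
    cohorts: Sequence[tuple[str, int]],
    enrichment: Mapping[str, float] | None = None,
    seed: int = 0,
    weights: Mapping[tuple[int, str], float] | None = None,
    grid_cache: dict | None = None,
) -> dict[str, tuple[list[DNVRecord], int]]:
    """Draw DNVs per cohort: count ~ Poisson(gamma_region * 2 N mu) per entry.

    Events are assigned to uniformly drawn proband identifiers within the
    cohort.  gamma = 0 silences a region entirely.
    """
    enrichment = dict(enrichment or {})
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[list[DNVRecord], int]] = {}
    for label, n_trios in cohorts:
        records: list[DNVRecord] = []
        for region in regions:
            if region.end > len(genome[region.chrom]):
                raise ValueError(f"region {region.name} lies outside the genome")
            gamma = float(enrichment.get(region.name, 1.0))
            if gamma < 0:
                raise ValueError("enrichment gamma must be >= 0")
            if gamma == 0:
                continue
            key = (region.name, n_trios)
            grid = grid_cache.get(key) if grid_cache is not None else None
            if grid is None:
                grid = _region_grid(genome, region, table, n_trios, weights)
                if grid_cache is not None:
                    grid_cache[key] = grid
            lams = gamma * grid.lams
            counts = rng.poisson(lams)
            for entry, k in zip(grid.entries, counts):
                for _ in range(int(k)):
                    proband = f"{label}.p{int(rng.integers(1, n_trios + 1))}"
                    records.append(
                        DNVRecord(region.chrom, entry.pos, entry.ref, entry.alt,
                                  proband, label)
                    )
        out[label] = (records, n_trios)
    return out


def simulate_cn_windows(
    genome: Mapping[str, str],
    config: SimulationConfig,
    planted: Sequence[tuple[str, Region, float]] = (),
) -> dict[str, list[CNWindow]]:
    """Per-sample 1-kbp CN window tables: diploid baseline plus planted events.

    ``planted`` holds (sample_id, region, cn_level) triples; windows
    overlapping a planted region are re-drawn at cn_level + noise.
    """
    rng = np.random.default_rng(config.seed + 2)
    chrom = config.contig_name
    size = len(genome[chrom])
    for _, region, _ in planted:
        if region.end > size:
            raise ValueError(f"planted event on {region.name} lies outside the genome")
    starts = np.arange(0, size - config.cn_window_size + 1, config.cn_window_size)
    samples = [f"cn_sample_{i:03d}" for i in range(config.cn_n_samples)]
    events = {(s, int(st)): lvl
              for s, region, lvl in planted
              for st in starts
              if st < region.end and st + config.cn_window_size > region.start}
    out: dict[str, list[CNWindow]] = {}
    for sample in samples:
        cns = 2.0 + rng.normal(0.0, config.cn_noise_sd, size=len(starts))
        windows = []
        for st, cn in zip(starts, cns):
            level = events.get((sample, int(st)))
            if level is not None:
                cn = level + rng.normal(0.0, config.cn_noise_sd)
            windows.append(CNWindow(chrom, int(st), int(st) + config.cn_window_size,
                                    max(0.0, float(cn)), sample))
        out[sample] = windows
    return out


def simulate_expression(
    config: SimulationConfig, target_gene: str = "TARGET"
) -> tuple[ExpressionMatrix, set[str]]:
    """Expression matrix with covariate effects and a planted module.

    The target gene plus ``expr_module_size`` module genes share a latent
    factor through a Gaussian copula tuned so each module gene's rank
    correlation with the target is ``expr_rho`` (Pearson r = 2 sin(pi rho/6)
    on the latent scale); background genes are independent.  Age enters every
    gene linearly and brain region as additive shifts, so the module is only
    recoverable after residualization.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.expr_n_samples
    samples = [f"s{i:03d}" for i in range(n)]
    age = rng.uniform(*config.expr_age_range, size=n)
    region = rng.choice(config.expr_regions, size=n)
    region_shift = {r: rng.normal(0, 1.5) for r in config.expr_regions}
    shift = np.array([region_shift[r] for r in region])

    r_latent = 2.0 * np.sin(np.pi * config.expr_rho / 6.0)
    z = rng.normal(size=n)  # shared latent factor (target residual scale)
    rows = {target_gene: z}
    module = set()
    for i in range(config.expr_module_size):
        g = f"MOD{i:03d}"
        module.add(g)
        rows[g] = r_latent * z + np.sqrt(1 - r_latent**2) * rng.normal(size=n)
    for i in range(config.expr_n_background):
        rows[f"BG{i:04d}"] = rng.normal(size=n)

    age_slopes = {g: rng.normal(0, 0.05) for g in rows}
    values = pd.DataFrame(
        {s: np.nan for s in samples}, index=list(rows), dtype=float
    )
    mat = np.vstack([rows[g] + age_slopes[g] * age + shift for g in rows])
    values.iloc[:, :] = mat
    covars = pd.DataFrame({"age": age, "region": region}, index=samples)
    return ExpressionMatrix(values, covars, scale="log2"), module


def simulate_phenotypes(config: SimulationConfig) -> PhenotypeTable:
    """Bernoulli phenotype statuses per group with NA masking."""
    rng = np.random.default_rng(config.seed + 4)
    rows = []
    index = []
    for group, size in config.pheno_group_sizes.items():
        for i in range(size):
            index.append(f"{group}.p{i + 1}")
            row = {"group": group}
            for pheno, prev in config.pheno_prevalence.items():
                if rng.uniform() < config.pheno_missingness:
                    row[pheno] = MISSING
                else:
                    row[pheno] = PRESENT if rng.uniform() < prev[group] else ABSENT
            rows.append(row)
    return PhenotypeTable(pd.DataFrame(rows, index=index))


def synthetic_phenotype_reconstruction() -> PhenotypeTable:
    """Synthetic stand-in for the published coding-vs-noncoding phenotype table.

    Deterministically reconstructs the assessed/present margins the study
    reports: 20 probands with coding DNVs in the target gene vs 3 with
    enhancer DNVs; intellectual disability / global developmental delay
    present in all 17 assessed coding probands and absent in all 3 noncoding
    probands; autism in 3/3 noncoding vs 2/17 assessed coding; two coding
    probands missing the ataxia assessment.  Individual-level assignments
    beyond these margins are arbitrary.
    """
    rows = []
    index = []
    for i in range(20):
        pid = f"coding.p{i + 1}"
        index.append(pid)
        rows.append({
            "group": "coding",
            "id_gdd": MISSING if i >= 17 else PRESENT,
            "autism": MISSING if i >= 17 else (PRESENT if i < 2 else ABSENT),
            "ataxia": MISSING if i >= 18 else (PRESENT if i < 12 else ABSENT),
        })
    for i in range(3):
        pid = f"noncoding.p{i + 1}"
        index.append(pid)
        rows.append({"group": "noncoding", "id_gdd": ABSENT, "autism": PRESENT,
                     "ataxia": ABSENT})
    return PhenotypeTable(pd.DataFrame(rows, index=index))


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
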