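"""Reproducible validation studies over the package's own machinery.

Each function runs one self-contained study — a published-count exact test,
an approximation-accuracy sweep, a type-I calibration run, a power/ranking
simulation, or a planted-signal recovery — and returns a small dict of the
quantities it measured.  The numbered drivers under ``analysis/`` and the
acceptance script are thin wrappers over these functions, so every reported
number is recomputed from scratch at run time.

Study conditions follow the trio-cohort design the pipeline targets: a
516-trio discovery cohort plus a 2155-trio replication cohort (2671 trios
combined), enhancer-scale regions of 2-3 kbp, and order-1e-8 context
substitution rates.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats

from .burden import ContingencyTable, fisher_exact, phenotype_compare
from .cnv import screen_cohort_cn
from .exprcorr import correlate_with_target, residualize, select_correlated
from .fitdnm import (
    exact_pvalue_oracle,
    saddlepoint_pvalue,
    test_regions,
)
from .rates import demo_rate_table
from .synthetic_data import (
    SimulationConfig,
    generate_genome,
    place_regions,
    simulate_cn_windows,
    simulate_expression,
    simulate_trio_dnvs,
    simulate_weights,
    synthetic_phenotype_reconstruction,
)

# Published morbidity-map window counts over the enhancer: deletion and
# duplication carriers among 29,085 NDD cases vs 19,584 controls.  These
# counts are inputs (a printed table), the p-values are recomputed.
MORBIDITY_CASES = 29_085
MORBIDITY_CONTROLS = 19_584
MORBIDITY_DEL_CASE_COUNT = 27
MORBIDITY_DUP_CASE_COUNT = 6

DISCOVERY_TRIOS = 516
REPLICATION_TRIOS = 2155


def morbidity_map_burden() -> dict:
    """One-sided Fisher deletion/duplication burden on the published counts."""
    out = {}
    for kind, k in (("deletion", MORBIDITY_DEL_CASE_COUNT),
                    ("duplication", MORBIDITY_DUP_CASE_COUNT)):
        table = ContingencyTable(k, MORBIDITY_CASES - k, 0, MORBIDITY_CONTROLS)
        res = fisher_exact(table, alternative="greater")
        out[kind] = {"p": res.p, "case_count": k, "control_count": 0,
                     "odds_ratio": res.odds_ratio}
    return out


def phenotype_severity() -> dict:
    """Coding-vs-noncoding phenotype comparisons on the reconstruction table.

    Intellectual disability / global developmental delay is tested for a
    higher rate in the coding group; autism for a higher rate in the
    noncoding (enhancer) group.  Both one-sided Fisher.
    """
    table = synthetic_phenotype_reconstruction()
    ct_id, p_id, _ = phenotype_compare(table, "id_gdd", "coding", "noncoding")
    ct_au, p_au, _ = phenotype_compare(table, "autism", "noncoding", "coding")
    return {
        "id_gdd": {"p": p_id, "counts": (ct_id.a, ct_id.b, ct_id.c, ct_id.d)},
        "autism": {"p": p_au, "counts": (ct_au.a, ct_au.b, ct_au.c, ct_au.d)},
    }


def saddlepoint_accuracy_study(n_grids: int = 250, seed: int = 0) -> dict:
    """Saddlepoint vs exact-convolution agreement on randomized small grids.

    Grids of 2-12 entries with fixed-precision weights (0.30-1.00 on a 0.05
    lattice) and intensities lambda ~ U(0.05, 1); observations are taken at
    several multiples of the null mean and compared wherever the exact tail
    lies in [1e-8, 0.5].  Returns the largest |log10 p_sp - log10 p_exact|.
    """
    from .genomic_io import Region
    from .rates import GridEntry, SiteAlleleGrid

    rng = np.random.default_rng(seed)
    region = Region("chrS", 0, 10_000_000)
    worst = 0.0
    n_points = 0
    for _ in range(n_grids):
        n = int(rng.integers(2, 13))
        ws = np.round(rng.integers(6, 21, n) * 0.05, 2)
        lams = rng.uniform(0.05, 1.0, n)
        entries = [GridEntry(i + 1, "A", "C", float(l), float(w))
                   for i, (l, w) in enumerate(zip(lams, ws))]
        grid = SiteAlleleGrid(region=region, entries=entries, n_trios=1)
        mean = float(np.sum(lams * ws))
        for mult in (1.5, 2.5, 4.0, 6.0, 9.0):
            t = mean * mult + float(rng.uniform(0, 0.2))
            p_exact = exact_pvalue_oracle(grid, t, tol=1e-12)
            if not 1e-8 < p_exact < 0.5:
                continue
            p_sp = saddlepoint_pvalue(grid, t)
            worst = max(worst, abs(math.log10(p_sp) - math.log10(p_exact)))
            n_points += 1
    return {"max_abs_log10_error": worst, "n_comparisons": n_points,
            "n_grids": n_grids}


def uniform_weight_equivalence_study(n_grids: int = 100, seed: int = 0) -> dict:
    """With w = 1 everywhere the weighted-load p must equal the Poisson tail."""
    from .genomic_io import Region
    from .rates import GridEntry, SiteAlleleGrid

    rng = np.random.default_rng(seed)
    region = Region("chrS", 0, 10_000_000)
    worst = 0.0
    for _ in range(n_grids):
        n = int(rng.integers(1, 40))
        lams = rng.uniform(1e-5, 0.2, n)
        entries = [GridEntry(i + 1, "A", "C", float(l), 1.0)
                   for i, l in enumerate(lams)]
        grid = SiteAlleleGrid(region=region, entries=entries, n_trios=1)
        lam_total = float(lams.sum())
        t = int(rng.integers(1, 6))
        p_fit = saddlepoint_pvalue(grid, float(t))
        p_pois = float(stats.poisson.sf(t - 1, lam_total))
        worst = max(worst, abs(p_fit - p_pois))
    return {"max_abs_difference": worst, "n_grids": n_grids}


def calibration_study(
    seed: int = 0,
    n_regions: int = 40,
    n_replicates: int = 50,
    n_trios: int = DISCOVERY_TRIOS + REPLICATION_TRIOS,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the load test under the generator's exact null.

    ``n_regions * n_replicates`` independent region-tests are simulated at
    enrichment gamma = 1 with a continuous per-allele functional-score map
    (scores on a 0.01 lattice), and the fraction of tests rejecting at
    ``alpha`` is compared with the exact binomial band around ``alpha``.
    """
    cfg = SimulationConfig(seed=seed, n_regions=n_regions)
    genome = generate_genome(cfg)
    regions = place_regions(cfg, genome)
    table = demo_rate_table()
    weights = simulate_weights(genome, regions, seed=seed + 1000)
    cache: dict = {}
    pvals = []
    for rep in range(n_replicates):
        dnvs = simulate_trio_dnvs(
            genome, regions, table, [("all", n_trios)], seed=seed + 2000 + rep,
            weights=weights, grid_cache=cache,
        )
        results = test_regions(regions, dnvs, table, genome, weights=weights,
                               grid_cache=cache)
        pvals.extend(r.p_fitdnm for r in results)
    pvals = np.asarray(pvals)
    n = pvals.size
    rate = float(np.mean(pvals < alpha))
    lo, hi = stats.binom.interval(0.95, n, alpha)
    return {
        "rejection_rate": rate,
        "n_tests": int(n),
        "alpha": alpha,
        "binomial_band": (lo / n, hi / n),
        "within_band": bool(lo / n <= rate <= hi / n),
    }


def power_ranking_study(
    seed: int = 0,
    n_replicates: int = 100,
    gamma: float = 20.0,
    enriched_region: str = "region_007",
) -> dict:
    """Ranking power: does the gamma-enriched region top the combined screen?

    Twenty enhancer-scale regions, discovery + replication cohorts, one
    region enriched gamma-fold.  A replicate succeeds when that region is
    the unique smallest combined p.
    """
    cfg = SimulationConfig(seed=seed, enrichment={enriched_region: gamma})
    genome = generate_genome(cfg)
    regions = place_regions(cfg, genome)
    table = demo_rate_table()
    cache: dict = {}
    wins = 0
    for rep in range(n_replicates):
        dnvs = simulate_trio_dnvs(
            genome, regions, table, cfg.cohorts, enrichment=cfg.enrichment,
            seed=seed + 5000 + rep, grid_cache=cache,
        )
        results = test_regions(regions, dnvs, table, genome, grid_cache=cache)
        combined = [r for r in results if r.cohort == "combined"]
        best = min(combined, key=lambda r: r.p_fitdnm)
        unique = sum(1 for r in combined if r.p_fitdnm == best.p_fitdnm) == 1
        if best.region == enriched_region and unique:
            wins += 1
    return {
        "top_rank_fraction": wins / n_replicates,
        "n_replicates": n_replicates,
        "gamma": gamma,
    }


def cn_recovery_study(seed: int = 0, n_samples: int = 30) -> dict:
    """Planted CNV recovery at the generator's default noise (sd 0.05).

    Plants deletions (cn 1.0) and duplications (cn 3.0) in known samples,
    screens every region, and scores sensitivity and the false-call rate
    over all sample-region pairs.
    """
    cfg = SimulationConfig(seed=seed, n_regions=5, cn_n_samples=n_samples)
    genome = generate_genome(cfg)
    regions = place_regions(cfg, genome)
    planted = [
        ("cn_sample_001", regions[0], 1.0),
        ("cn_sample_004", regions[2], 0.9),
        ("cn_sample_010", regions[3], 3.0),
        ("cn_sample_017", regions[0], 3.1),
    ]
    truth = {(s, r.name): ("deletion" if lvl < 2 else "duplication")
             for s, r, lvl in planted}
    by_sample = simulate_cn_windows(genome, cfg, planted=planted)
    tp = fp = fn = 0
    n_pairs = 0
    for region in regions:
        calls, _ = screen_cohort_cn(by_sample, region)
        for row in calls.itertuples(index=False):
            n_pairs += 1
            expected = truth.get((row.sample, region.name), "normal")
            if expected != "normal":
                tp += int(row.call == expected)
                fn += int(row.call != expected)
            else:
                fp += int(row.call != "normal")
    return {
        "sensitivity": tp / (tp + fn),
        "false_call_rate": fp / (n_pairs - (tp + fn)),
        "n_planted": len(planted),
        "n_sample_region_pairs": n_pairs,
    }


def module_recovery_study(seed: int = 0, threshold: float = 0.6) -> dict:
    """Planted co-expression module recovery through the full screen.

    Generator defaults: rank correlation 0.8 with the target, 200 samples,
    500 background genes, linear age and brain-region effects that must be
    regressed away before the module is visible.
    """
    cfg = SimulationConfig(seed=seed)
    matrix, module = simulate_expression(cfg)
    resid = residualize(matrix)
    rho, _ = correlate_with_target(resid, "TARGET")
    selected = select_correlated(rho.drop("TARGET"), threshold)
    tp = len(selected & module)
    return {
        "precision": tp / max(1, len(selected)),
        "recall": tp / len(module),
        "n_selected": len(selected),
        "module_size": len(module),
        "n_background": cfg.expr_n_background,
    }


def rational_hypergeom_pvalue(a: int, b: int, c: int, d: int,
                              alternative: str = "greater") -> float:
    """Independent Fisher oracle: exact-rational hypergeometric summation."""
    row1, row2 = a + b, c + d
    n1 = a + c
    denom = math.comb(row1 + row2, n1)

    def mass(k):
        if k < 0 or k > row1 or n1 - k > row2 or n1 - k < 0:
            return Fraction(0)
        return Fraction(math.comb(row1, k) * math.comb(row2, n1 - k), denom)

    kmin, kmax = max(0, n1 - row2), min(row1, n1)
    if alternative == "greater":
        return float(sum(mass(k) for k in range(a, kmax + 1)))
    if alternative == "less":
        return float(sum(mass(k) for k in range(kmin, a + 1)))
    obs = mass(a)
    return float(sum(m for k in range(kmin, kmax + 1) if (m := mass(k)) <= obs))


def fisher_oracle_study(n_tables: int = 1000, seed: int = 0) -> dict:
    """fisher_exact vs the rational hypergeometric oracle on random tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_tables:
        a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        alt = ("greater", "less", "two_sided")[done % 3]
        p = fisher_exact(ContingencyTable(a, b, c, d), alt).p
        worst = max(worst, abs(p - rational_hypergeom_pvalue(a, b, c, d, alt)))
        done += 1
    return {"max_abs_difference": worst, "n_tables": n_tables}
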