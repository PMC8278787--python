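"""The weighted de novo load test: statistic, tail probabilities, oracles,
cohort pooling, and multiplicity adjustment."""

import math

import numpy as np
import pytest

from conftest import make_grid
from enhancerdnm.genomic_io import DNVRecord, Region
from enhancerdnm.fitdnm import (
    adjust_pvalues,
    conditional_pvalue,
    exact_pvalue_oracle,
    montecarlo_pvalue,
    region_pvalue,
    saddlepoint_pvalue,
    score_statistic,
)
from enhancerdnm.fitdnm import test_regions as run_region_tests
from enhancerdnm.rates import demo_rate_table
from enhancerdnm.synthetic_data import (
    SimulationConfig,
    generate_genome,
    place_regions,
    simulate_trio_dnvs,
)


def dnv_at(grid, idx, region=None):
    region = region or grid.region
    e = grid.entries[idx]
    return DNVRecord(region.chrom, e.pos, e.ref, e.alt, f"p{idx}")


class TestScoreStatistic:
    def test_weighted_sum_with_multiplicity(self):
        grid = make_grid([0.1, 0.1, 0.1], [0.7, 0.25, 1.0])
        assert score_statistic(grid, []) == 0.0
        dnvs = [dnv_at(grid, 0), dnv_at(grid, 1)]
        assert score_statistic(grid, dnvs) == pytest.approx(0.95)
        # a recurrent identical event counts twice
        assert score_statistic(grid, dnvs + [dnv_at(grid, 0)]) == pytest.approx(1.65)

    def test_uniform_weights_count_events(self):
        grid = make_grid([0.1] * 5, [1.0] * 5)
        assert score_statistic(grid, [dnv_at(grid, i) for i in (0, 2, 4)]) == 3.0

    def test_reference_mismatch_is_error(self):
        grid = make_grid([0.1], [1.0])
        bad = DNVRecord(grid.region.chrom, grid.entries[0].pos, "G", "C", "p0")
        with pytest.raises(ValueError, match="reference mismatch"):
            score_statistic(grid, [bad])

    def test_dnv_outside_region_is_error(self):
        grid = make_grid([0.1], [1.0], region=Region("chr1", 0, 100))
        with pytest.raises(ValueError, match="outside region"):
            score_statistic(grid, [DNVRecord("chr1", 101, "A", "C", "p0")])


class TestSaddlepointPvalue:
    def test_zero_statistic_gives_one(self):
        assert saddlepoint_pvalue(make_grid([0.5], [1.0]), 0.0) == 1.0

    def test_uniform_weight_poisson_closed_form(self):
        # Lambda = 0.01, t = 2: P(Poisson(0.01) >= 2) = 1 - e^-0.01 (1 + 0.01)
        grid = make_grid([0.002] * 5, [1.0] * 5)
        expected = 1 - math.exp(-0.01) * 1.01
        assert saddlepoint_pvalue(grid, 2.0) == pytest.approx(expected, rel=1e-10)

    def test_two_entry_grid_matches_exact_convolution(self):
        grid = make_grid([0.1, 0.1], [1.0, 0.5])
        p_sp = saddlepoint_pvalue(grid, 1.5)
        p_ex = exact_pvalue_oracle(grid, 1.5, tol=1e-12)
        assert p_sp == pytest.approx(p_ex, rel=1e-9)

    def test_degenerate_null_warns_and_returns_zero(self):
        grid = make_grid([], [])
        with pytest.warns(UserWarning, match="degenerate"):
            assert saddlepoint_pvalue(grid, 1.0) == 0.0

    def test_monotone_nonincreasing_in_t(self):
        rng = np.random.default_rng(3)
        grid = make_grid(rng.uniform(0.05, 0.8, 12), np.round(rng.integers(6, 21, 12) * 0.05, 2))
        ts = np.linspace(0.5, 8.0, 40)
        ps = [saddlepoint_pvalue(grid, t) for t in ts]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_invariant_to_trio_mu_rescaling_at_fixed_lambda(self, random_sequence):
        # 10x the trios at a tenth of the rates: identical lambdas, identical p
        from enhancerdnm.rates import RateTable, annotate_region, demo_rate_table

        base = demo_rate_table()
        tenth = RateTable({k: v / 10 for k, v in base.entries.items()})
        region = Region("chr1", 100, 400, "r")
        g1 = annotate_region(random_sequence, region, base, 500, sequence_start=0)
        g2 = annotate_region(random_sequence, region, tenth, 5000, sequence_start=0)
        assert np.allclose(g1.lams, g2.lams)
        assert saddlepoint_pvalue(g1, 2.0) == saddlepoint_pvalue(g2, 2.0)

    def test_saddlepoint_path_tracks_exact_on_larger_grids(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(9, 13))
            ws = np.round(rng.integers(6, 21, n) * 0.05, 2)
            lams = rng.uniform(0.05, 1.0, n)
            grid = make_grid(lams, ws)
            mean = float(np.sum(lams * ws))
            for mult in (2.5, 5.0):
                t = mean * mult
                p_ex = exact_pvalue_oracle(grid, t)
                if not 1e-8 < p_ex < 0.5:
                    continue
                p_sp = saddlepoint_pvalue(grid, t)
                assert abs(math.log10(p_sp) - math.log10(p_ex)) <= 0.05


class TestExactOracle:
    def test_single_entry_closed_forms(self):
        grid = make_grid([0.2], [1.0])
        assert exact_pvalue_oracle(grid, 1.0) == pytest.approx(1 - math.exp(-0.2), abs=1e-12)
        assert exact_pvalue_oracle(grid, 0.0) == 1.0

    def test_unattainable_t_has_negligible_mass(self):
        grid = make_grid([0.01], [1.0])
        assert exact_pvalue_oracle(grid, 60.0, tol=1e-12) < 1e-12

    def test_agrees_with_arbitrary_precision_poisson_sum(self):
        # independent high-precision check via fractions of the Poisson series
        from fractions import Fraction

        lam = 0.3
        grid = make_grid([0.1] * 3, [1.0] * 3)
        # P(X >= 4) = 1 - sum_{k<4} e^-lam lam^k / k!
        partial = sum(lam**k / math.factorial(k) for k in range(4))
        expected = 1 - math.exp(-lam) * partial
        assert exact_pvalue_oracle(grid, 4.0) == pytest.approx(expected, rel=1e-10)


class TestMonteCarlo:
    def test_deterministic_and_covers_closed_form(self):
        grid = make_grid([0.002] * 5, [1.0] * 5)
        p1, ci = montecarlo_pvalue(grid, 1.0, n_sims=200_000, seed=11)
        p2, _ = montecarlo_pvalue(grid, 1.0, n_sims=200_000, seed=11)
        assert p1 == p2
        closed = 1 - math.exp(-0.01)
        assert ci[0] <= closed <= ci[1]

    def test_zero_t_gives_one(self):
        grid = make_grid([0.1], [1.0])
        assert montecarlo_pvalue(grid, 0.0, n_sims=1000, seed=0)[0] == 1.0

    def test_minimum_sims_enforced(self):
        with pytest.raises(ValueError, match="n_sims"):
            montecarlo_pvalue(make_grid([0.1], [1.0]), 1.0, n_sims=10, seed=0)


class TestConditional:
    def test_two_event_enumeration(self):
        # weights 1.0 / 0.5 with equal intensity: given 2 events the sums are
        # 2.0, 1.5, 1.0 with probabilities 1/4, 1/2, 1/4
        grid = make_grid([0.1, 0.1], [1.0, 0.5])
        assert conditional_pvalue(grid, 1.5, 2) == pytest.approx(0.75)
        assert conditional_pvalue(grid, 2.0, 2) == pytest.approx(0.25)
        assert conditional_pvalue(grid, 0.0, 2) == 1.0
        assert conditional_pvalue(grid, 0.5, 0) == 0.0

    def test_uniform_weights_condition_to_certainty(self):
        # with w = 1 everywhere, T | N = n is degenerate at n
        grid = make_grid([0.2, 0.3, 0.1], [1.0, 1.0, 1.0])
        assert conditional_pvalue(grid, 3.0, 3) == pytest.approx(1.0)
        assert conditional_pvalue(grid, 3.5, 3) == pytest.approx(0.0)


class TestAdjustPvalues:
    def test_identity_for_single_test(self):
        assert adjust_pvalues([0.01], "bonferroni")[0] == pytest.approx(0.01)

    def test_bonferroni_hand_value(self):
        # 544 tested regions at p = 1.1e-4 -> 544 * 1.1e-4
        p = [1.1e-4] + [1.0] * 543
        assert adjust_pvalues(p, "bonferroni")[0] == pytest.approx(0.05984)

    def test_bh_step_up_recursion(self):
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "BH")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm")


@pytest.fixture(scope="module")
def small_world():
    cfg = SimulationConfig(seed=123, n_regions=4, region_length=(400, 600),
                           cohorts=(("disc", 400), ("repl", 400)))
    genome = generate_genome(cfg)
    regions = place_regions(cfg, genome)
    return cfg, genome, regions, demo_rate_table()


class TestTestRegions:

    def test_no_dnvs_gives_p_one(self, small_world):
        _, genome, regions, table = small_world
        results = run_region_tests(regions, {"disc": ([], 400)}, table, genome)
        assert all(r.p_fitdnm == 1.0 and r.n_dnvs == 0 for r in results)

    def test_pooling_doubles_lambda_and_t(self, small_world):
        _, genome, regions, table = small_world
        grid_region = regions[0]
        e_pos = grid_region.start + 10
        ref = genome[grid_region.chrom][e_pos]
        alt = "A" if ref != "A" else "C"
        dnv = DNVRecord(grid_region.chrom, e_pos + 1, ref, alt, "p1", "disc")
        results = run_region_tests(
            regions[:1],
            {"disc": ([dnv], 400), "repl": ([dnv], 400)},
            table,
            genome,
        )
        by_cohort = {r.cohort: r for r in results}
        assert by_cohort["combined"].lam_total == pytest.approx(
            2 * by_cohort["disc"].lam_total
        )
        assert by_cohort["combined"].t_obs == pytest.approx(2 * by_cohort["disc"].t_obs)
        assert by_cohort["combined"].n_dnvs == 2

    def test_uniform_weight_fitdnm_equals_poisson(self, small_world):
        cfg, genome, regions, table = small_world
        dnvs = simulate_trio_dnvs(genome, regions, table,
                                  [("disc", 50000)], seed=9)
        results = run_region_tests(regions, dnvs, table, genome)
        for r in results:
            assert r.p_fitdnm == pytest.approx(r.p_poisson, abs=1e-10)

    def test_results_sorted_by_p(self, small_world):
        cfg, genome, regions, table = small_world
        dnvs = simulate_trio_dnvs(genome, regions, table, cfg.cohorts,
                                  enrichment={"region_001": 50.0}, seed=5)
        results = run_region_tests(regions, dnvs, table, genome)
        ps = [r.p_fitdnm for r in results]
        assert ps == sorted(ps)
        assert results[0].region == "region_001"

    def test_enriched_region_ranks_first(self, small_world):
        # gamma = 20 on one region should dominate the combined ranking
        cfg, genome, regions, table = small_world
        wins = 0
        for seed in range(10):
            dnvs = simulate_trio_dnvs(genome, regions, table,
                                      [("disc", 10000), ("repl", 10000)],
                                      enrichment={"region_002": 20.0}, seed=seed)
            results = run_region_tests(regions, dnvs, table, genome)
            combined = [r for r in results if r.cohort == "combined"]
            if min(combined, key=lambda r: r.p_fitdnm).region == "region_002":
                wins += 1
        assert wins >= 9
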