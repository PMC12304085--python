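"""Burrows composite LD, the drift-plus-sampling inversion, jackknife CIs
and the physical-linkage correction."""

import itertools
import math

import numpy as np
import pytest

from nebench import genome_sim as gs
from nebench.bench_io import make_fixtures
from nebench.errors import ConfigError, NebenchError
from nebench.genome_sim import GenotypeMatrix
from nebench.ld_ne import (
    LDSummary,
    burrows_r2,
    estimate_ld_ne,
    jackknife_ci,
    ld_ne_estimate,
    ld_summary,
    linkage_correction,
)


def brute_force_pair(x, y):
    """Direct evaluation of the composite covariance formula (oracle)."""
    n = len(x)
    pa = sum(x) / (2 * n)
    pb = sum(y) / (2 * n)
    paa = sum(1 for v in x if v == 2) / n
    pbb = sum(1 for v in y if v == 2) / n
    delta = sum(xi * yi for xi, yi in zip(x, y)) / (2 * n) - 2 * pa * pb
    va = pa * (1 - pa) + paa - pa**2
    vb = pb * (1 - pb) + pbb - pb**2
    return delta, delta**2 / (va * vb)


class TestBurrowsR2:
    def test_identical_columns_give_unity(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]])
        stat = burrows_r2(g, 0, 1)
        assert stat.r2 == pytest.approx(1.0)
        assert stat.delta > 0

    def test_complement_coding_gives_unity_negative_delta(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        g = np.column_stack([x, 2 - x])
        stat = burrows_r2(g, 0, 1)
        assert stat.r2 == pytest.approx(1.0)
        assert stat.delta < 0

    def test_printed_toy_matches_brute_force(self):
        x = [0, 1, 2, 1, 0, 1]
        y = [1, 1, 2, 0, 0, 2]
        g = np.column_stack([x, y])
        stat = burrows_r2(g, 0, 1)
        d, r2 = brute_force_pair(x, y)
        assert stat.delta == pytest.approx(d)
        assert stat.r2 == pytest.approx(r2)
        assert stat.s_pair == 6

    def test_monomorphic_locus_excluded_not_raised(self):
        g = np.column_stack([[1, 1, 1, 1], [0, 1, 2, 1]])
        assert burrows_r2(g, 0, 1).excluded  # zero-variance column

    def test_missing_data_reduce_pair_sample(self):
        g = np.column_stack([[0, 1, 2, 1, -1, 2], [1, 1, 2, 0, 0, -1]])
        stat = burrows_r2(g, 0, 1)
        assert stat.s_pair == 4

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(40, 2))
        a = burrows_r2(g, 0, 1)
        g2 = g.copy()
        g2[:, 0] = 2 - g2[:, 0]
        b = burrows_r2(g2, 0, 1)
        assert a.r2 == pytest.approx(b.r2)

    def test_individual_order_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(40, 2))
        a = burrows_r2(g, 0, 1)
        b = burrows_r2(g[rng.permutation(40)], 0, 1)
        assert a.r2 == pytest.approx(b.r2)


class TestLdSummary:
    def test_all_pairs_count(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(50, 3))
        s = ld_summary(g, maf_min=0.0)
        assert s.n_pairs == 3

    def test_between_chromosome_policy(self):
        rng = np.random.default_rng(3)
        gm = GenotypeMatrix(
            genotypes=rng.integers(0, 3, size=(50, 4)).astype(np.int8),
            chrom=np.array([0, 0, 1, 1]),
            pos=np.arange(4, dtype=float),
            individuals=np.arange(50),
        )
        s = ld_summary(gm, maf_min=0.0, policy="between-chrom")
        assert s.n_pairs == 4

    def test_aggregate_matches_pairwise_mean(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(30, 8))
        s = ld_summary(g, maf_min=0.0)
        stats = [burrows_r2(g, a, b) for a, b in itertools.combinations(range(8), 2)]
        stats = [st for st in stats if not st.excluded]
        weights = np.array([st.s_pair for st in stats], dtype=float)
        expected = (weights * [st.r2 for st in stats]).sum() / weights.sum()
        assert s.mean_r2 == pytest.approx(expected)
        assert s.harmonic_s == pytest.approx(
            len(stats) / sum(1 / st.s_pair for st in stats)
        )

    def test_too_few_loci_raises(self):
        g = np.ones((20, 3), dtype=np.int8)
        with pytest.raises(NebenchError):
            ld_summary(g, maf_min=0.05)

    def test_null_sampling_expectation(self):
        # independent loci, individuals drawn from infinite pool: the drift
        # term vanishes and mean r2 - 1/S is centred on zero
        rng = np.random.default_rng(5)
        s, loci, reps = 40, 30, 300
        devs = []
        for _ in range(reps):
            f = rng.uniform(0.2, 0.8, loci)
            g = rng.binomial(2, f, size=(s, loci))
            summ = ld_summary(g, maf_min=0.05)
            devs.append(summ.mean_r2 - 1.0 / summ.harmonic_s)
        mean_dev = np.mean(devs)
        se = np.std(devs) / math.sqrt(reps)
        # 1/S is the first-order expectation; the literature's refinement
        # carries a +3.19/S^2 term, which bounds the allowed residual bias
        assert abs(mean_dev) < max(4 * se, 3.2 / s**2)


class TestInversion:
    def test_known_r2_recovers_ne(self):
        s = LDSummary(n_loci=100, n_pairs=4950,
                      mean_r2=1.0 / (3 * 500) + 1.0 / 80, harmonic_s=80,
                      policy="all", maf_min=0.05)
        est = ld_ne_estimate(s)
        assert est.point == pytest.approx(500.0)

    def test_zero_drift_signal_flags_infinite(self):
        s = LDSummary(n_loci=100, n_pairs=4950, mean_r2=1.0 / 80,
                      harmonic_s=80, policy="all", maf_min=0.05)
        est = ld_ne_estimate(s)
        assert math.isinf(est.point)
        assert est.aux["r2_drift"] <= 0
        assert not est.is_finite

    def test_monotone_in_r2(self):
        nes = []
        for r2 in (0.013, 0.016, 0.02):
            s = LDSummary(n_loci=10, n_pairs=45, mean_r2=r2, harmonic_s=100,
                          policy="all", maf_min=0.05)
            nes.append(ld_ne_estimate(s).point)
        assert nes[0] > nes[1] > nes[2]

    def test_refined_formula_differs_from_baseline(self):
        s = LDSummary(n_loci=10, n_pairs=45, mean_r2=0.014, harmonic_s=100,
                      policy="all", maf_min=0.05)
        a = ld_ne_estimate(s, formula="baseline").point
        b = ld_ne_estimate(s, formula="refined").point
        assert a != b
        assert b > 0


class TestEstimatorRecovery:
    def test_wf_fixture_recovery_moderate_scale(self):
        # 40 replicates at a reduced scale of the ideal-population fixture
        ests = []
        for rep in range(40):
            gm = make_fixtures(
                "wf-ideal", {"n": 120, "loci": 400, "sample_size": 60}, seed=rep
            )
            ests.append(estimate_ld_ne(gm, maf_min=0.05).point)
        finite = [e for e in ests if math.isfinite(e)]
        assert len(finite) >= 35
        assert np.median(finite) == pytest.approx(120, rel=0.25)


class TestJackknife:
    def test_identical_copies_degenerate(self):
        g = np.tile(np.array([1, 1, 1, 1], dtype=np.int8), (20, 1))
        lo, hi = jackknife_ci(g, maf_min=0.0)
        assert math.isnan(lo) and math.isnan(hi)

    def test_too_few_individuals(self):
        g = np.random.default_rng(0).integers(0, 3, size=(5, 10))
        with pytest.raises(NebenchError):
            jackknife_ci(g)

    def test_interval_brackets_point(self):
        gm = make_fixtures("wf-ideal", {"n": 100, "loci": 200, "sample_size": 50},
                           seed=1)
        est = estimate_ld_ne(gm)
        lo, hi = jackknife_ci(gm)
        assert lo <= est.point <= hi

    def test_locus_jackknife_available(self):
        gm = make_fixtures("wf-ideal", {"n": 100, "loci": 150, "sample_size": 50},
                           seed=2)
        lo, hi = jackknife_ci(gm, unit="locus")
        assert lo > 0 and hi > lo

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n_samp in (30, 60, 120):
            gm = make_fixtures(
                "wf-ideal", {"n": 150, "loci": 150, "sample_size": n_samp}, seed=7
            )
            lo, hi = jackknife_ci(gm)
            # width on the inverse scale stays finite even when hi is inf
            widths.append(1.0 / lo - (0.0 if math.isinf(hi) else 1.0 / hi))
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_near_nominal(self):
        covered, reps = 0, 40
        truth = 150
        for rep in range(reps):
            gm = make_fixtures(
                "wf-ideal", {"n": truth, "loci": 250, "sample_size": 75},
                seed=100 + rep,
            )
            lo, hi = jackknife_ci(gm)
            if lo <= truth <= hi:
                covered += 1
        # nominal 95%; the method is known to under-cover
        assert covered / reps >= 0.7


class TestLinkageCorrection:
    def test_many_chromosomes_no_correction(self):
        assert linkage_correction(1000.0, n_chromosomes=500) == pytest.approx(1000.0)

    def test_few_chromosomes_adjust_upward(self):
        corrected = linkage_correction(1000.0, n_chromosomes=4)
        assert corrected > 1000.0

    def test_genome_size_variant(self):
        by_chr = linkage_correction(800.0, n_chromosomes=10)
        by_cm = linkage_correction(800.0, genome_cm=1000.0)
        assert by_chr == pytest.approx(by_cm)

    def test_missing_information_raises(self):
        with pytest.raises(ConfigError):
            linkage_correction(1000.0)

    def test_infinite_estimate_rejected(self):
        with pytest.raises(NebenchError):
            linkage_correction(math.inf, n_chromosomes=10)

    def test_linked_all_pairs_biased_low_vs_between_chrom(self, founder_pop):
        # physically linked loci inflate mean r2 when all pairs are used;
        # restricting to between-chromosome pairs removes that signal, and
        # the correction moves the all-pairs estimate toward it
        ped = founder_pop.pedigree
        ids = np.flatnonzero(ped.birth_step == 0)[:40]
        spec = gs.GenomeSpec(chromosomes=(6e6,) * 4, recombination_rate=1e-8,
                             mutation_rate=2e-8, generation_years=1.0)
        rng = np.random.default_rng(3)
        gm = gs.simulate_genomes(ped, ids, spec, 300.0, rng)
        all_pairs = ld_summary(gm, maf_min=0.05, policy="all")
        between = ld_summary(gm, maf_min=0.05, policy="between-chrom")
        assert all_pairs.mean_r2 > between.mean_r2
        ne_all = ld_ne_estimate(all_pairs).point
        ne_between = ld_ne_estimate(between).point
        corrected = linkage_correction(ne_all, n_chromosomes=4)
        assert ne_all < ne_between
        assert abs(corrected - ne_between) < abs(ne_all - ne_between)
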