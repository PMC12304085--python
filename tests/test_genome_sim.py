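"""Gene dropping, recapitation, mutation overlay and locus subsetting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nebench import genome_sim as gs
from nebench.errors import ConfigError, PedigreeIntegrityError, ShortfallError
from nebench.forward_sim import NO_PARENT, PedigreeTable


@pytest.fixture(scope="module")
def founder_ids(founder_pop):
    ped = founder_pop.pedigree
    return np.flatnonzero(ped.birth_step == 0)  # age-0 founders, equal times


@pytest.fixture(scope="module")
def linked_ancestry(small_sim):
    step40 = small_sim.samples.query("step_sampled == 40")
    ids = step40.id.to_numpy()[:25]
    spec = gs.GenomeSpec(chromosomes=(1e6, 5e5), recombination_rate=1e-8,
                         mutation_rate=1e-7, generation_years=5.8)
    rng = np.random.default_rng(44)
    return gs.drop_genomes(small_sim.pedigree, ids, spec, rng)


class TestDropGenomes:
    def test_zero_recombination_single_segment(self, small_sim):
        ids = small_sim.samples.id.to_numpy()[:10]
        spec = gs.GenomeSpec(chromosomes=(1e6,), recombination_rate=0.0,
                             mutation_rate=0.0, generation_years=5.8)
        anc = gs.drop_genomes(small_sim.pedigree, ids, spec,
                              np.random.default_rng(1))
        segs = anc.segments()
        assert len(segs) == 2 * len(ids)  # one segment per haplotype
        assert (segs.left == 0).all() and (segs.right == 1e6).all()
        assert (segs.founder_haplotype >= 0).all()

    def test_child_of_founders_uses_their_haplotypes(self):
        # two founders and one child
        ped = PedigreeTable(
            sex=np.array([0, 1, 0], dtype=np.int8),
            birth_step=np.array([0, 0, 5], dtype=np.int32),
            deme_birth=np.zeros(3, dtype=np.int16),
            mother=np.array([NO_PARENT, NO_PARENT, 0]),
            father=np.array([NO_PARENT, NO_PARENT, 1]),
            death_step=np.full(3, 99, dtype=np.int32),
            alive_at_end=np.ones(3, dtype=bool),
            end_step=98,
            migrations=pd.DataFrame(columns=["id", "step", "from_deme", "to_deme"]),
        )
        spec = gs.GenomeSpec(chromosomes=(1e7,), recombination_rate=1e-7,
                             mutation_rate=0.0, generation_years=1.0)
        anc = gs.drop_genomes(ped, np.array([2]), spec, np.random.default_rng(2))
        segs = anc.segments()
        assert set(segs.founder_haplotype) <= {0, 1, 2, 3}
        hap0 = segs.query("haplotype == 0")  # maternal copy
        assert set(hap0.founder_haplotype) <= {0, 1}
        hap1 = segs.query("haplotype == 1")
        assert set(hap1.founder_haplotype) <= {2, 3}

    def test_segment_tiling_complete(self, linked_ancestry):
        segs = linked_ancestry.segments()
        for (hap, chrom), g in segs.groupby(["haplotype", "chrom"]):
            g = g.sort_values("left")
            length = linked_ancestry.spec.chromosomes[chrom]
            assert g.left.iloc[0] == 0
            assert g.right.iloc[-1] == length
            assert (g.right.to_numpy()[:-1] == g.left.to_numpy()[1:]).all()

    def test_crossover_counts_poisson(self):
        rng = np.random.default_rng(9)
        counts = np.array([
            len(gs._meiosis_breaks(rng, 1e-8, 1e8)) for _ in range(10_000)
        ])
        assert counts.mean() == pytest.approx(1.0, abs=0.04)
        observed = np.bincount(np.minimum(counts, 5), minlength=6)
        p = np.array([stats.poisson.pmf(k, 1.0) for k in range(5)])
        p = np.append(p, 1 - p.sum())
        _, pval = stats.chisquare(observed, f_exp=p * counts.size)
        assert pval > 0.001

    def test_pedigree_gap_detected(self):
        ped = PedigreeTable(
            sex=np.array([0, 0], dtype=np.int8),
            birth_step=np.array([0, 5], dtype=np.int32),
            deme_birth=np.zeros(2, dtype=np.int16),
            mother=np.array([NO_PARENT, 0]),
            father=np.array([NO_PARENT, NO_PARENT]),  # one parent missing
            death_step=np.full(2, 99, dtype=np.int32),
            alive_at_end=np.ones(2, dtype=bool),
            end_step=98,
            migrations=pd.DataFrame(columns=["id", "step", "from_deme", "to_deme"]),
        )
        spec = gs.GenomeSpec(chromosomes=(1e6,), generation_years=1.0)
        with pytest.raises(PedigreeIntegrityError):
            gs.drop_genomes(ped, np.array([1]), spec, np.random.default_rng(0))


class TestRecapitate:
    def test_single_lineage_trivial(self, founder_pop):
        spec = gs.unlinked_genome_spec(5, generation_years=1.0)
        anc = gs.drop_genomes(founder_pop.pedigree, np.array([0]), spec,
                              np.random.default_rng(0))
        gen = gs.recapitate(anc, 100.0, np.random.default_rng(0))
        ts = gen.tree_sequences[0]
        # 2 haplotypes of one individual: each locus coalesces to one root
        for j in range(5):
            assert ts.at(j + 0.5).num_roots == 1

    def test_invalid_ancestral_ne(self, founder_pop):
        spec = gs.unlinked_genome_spec(2, generation_years=1.0)
        anc = gs.drop_genomes(founder_pop.pedigree, np.array([0]), spec,
                              np.random.default_rng(0))
        with pytest.raises(ConfigError):
            gs.recapitate(anc, 0.0, np.random.default_rng(0))

    def test_pairwise_coalescence_time(self, founder_pop, founder_ids):
        # E[T2] = 2N generations; each unlinked locus is a replicate
        n_anc = 50.0
        spec = gs.unlinked_genome_spec(2500, generation_years=1.0)
        anc = gs.drop_genomes(founder_pop.pedigree, founder_ids[:1], spec,
                              np.random.default_rng(5))
        gen = gs.recapitate(anc, n_anc, np.random.default_rng(5))
        ts = gen.tree_sequences[0]
        leaf_t = ts.node(0).time
        t2 = np.array([ts.node(ts.at(j + 0.5).root).time - leaf_t
                       for j in range(2500)])
        se = t2.std() / np.sqrt(len(t2))
        assert abs(t2.mean() - 2 * n_anc) < 4 * se

    def test_total_tree_length(self, founder_pop, founder_ids):
        # n = 20 lineages: E[total length] = 4N * sum_{i<20} 1/i
        n_anc, n_ind = 40.0, 10
        spec = gs.unlinked_genome_spec(800, generation_years=1.0)
        anc = gs.drop_genomes(founder_pop.pedigree, founder_ids[:n_ind], spec,
                              np.random.default_rng(6))
        gen = gs.recapitate(anc, n_anc, np.random.default_rng(6))
        ts = gen.tree_sequences[0]
        lengths = np.array([ts.at(j + 0.5).total_branch_length for j in range(800)])
        expected = 4 * n_anc * (1.0 / np.arange(1, 2 * n_ind)).sum()
        se = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - expected) < 4 * se

    def test_hudson_fully_coalesces(self, linked_ancestry):
        gen = gs.recapitate(linked_ancestry, 300.0, np.random.default_rng(7))
        for ts in gen.tree_sequences:
            for tree in ts.trees():
                assert tree.num_roots == 1


class TestMutations:
    def test_zero_mutation_rate(self, linked_ancestry):
        gen = gs.recapitate(linked_ancestry, 200.0, np.random.default_rng(8))
        gm = gs.overlay_mutations(gen, np.random.default_rng(8), mutation_rate=0.0)
        assert gm.n_loci == 0

    def test_genotypes_are_haplotype_sums(self, linked_ancestry):
        gen = gs.recapitate(linked_ancestry, 200.0, np.random.default_rng(9))
        gm = gs.overlay_mutations(gen, np.random.default_rng(9))
        np.testing.assert_array_equal(
            gm.genotypes, gm.haplotypes[0::2] + gm.haplotypes[1::2]
        )
        assert gm.genotypes.min() >= 0 and gm.genotypes.max() <= 2

    def test_positions_increasing_within_chromosome(self, linked_ancestry):
        gen = gs.recapitate(linked_ancestry, 200.0, np.random.default_rng(10))
        gm = gs.overlay_mutations(gen, np.random.default_rng(10))
        for c in np.unique(gm.chrom):
            pos = gm.pos[gm.chrom == c]
            assert (np.diff(pos) > 0).all()

    def test_segregating_sites_match_watterson(self, founder_pop, founder_ids):
        # theta per locus = 4 N mu l; E[S] = theta * a_n over many loci
        n_anc, mu, ell, loci = 100.0, 5e-7, 1e3, 4000
        spec = gs.unlinked_genome_spec(loci, locus_length=ell, mutation_rate=mu,
                                       generation_years=1.0)
        anc = gs.drop_genomes(founder_pop.pedigree, founder_ids[:10], spec,
                              np.random.default_rng(11))
        gen = gs.recapitate(anc, n_anc, np.random.default_rng(11))
        gm = gs.overlay_mutations(gen, np.random.default_rng(11))
        theta = 4 * n_anc * mu * ell
        a_n = (1.0 / np.arange(1, 20)).sum()
        assert gm.n_loci == pytest.approx(theta * a_n * loci, rel=0.05)

    def test_variant_count_linear_in_mu(self, founder_pop, founder_ids):
        counts = []
        for mu in (2e-7, 4e-7):
            spec = gs.unlinked_genome_spec(2000, locus_length=1e3,
                                           mutation_rate=mu, generation_years=1.0)
            anc = gs.drop_genomes(founder_pop.pedigree, founder_ids[:10], spec,
                                  np.random.default_rng(12))
            gen = gs.recapitate(anc, 100.0, np.random.default_rng(12))
            gm = gs.overlay_mutations(gen, np.random.default_rng(12))
            counts.append(gm.n_loci)
        assert counts[1] / counts[0] == pytest.approx(2.0, rel=0.1)

    def test_summary_stats_match_msprime_oracle(self, founder_pop, founder_ids):
        # independent cross-check: matched constant-size simulation with the
        # established coalescent simulator
        msprime = pytest.importorskip("msprime")
        n_anc, mu, ell, loci, n_ind = 100.0, 5e-7, 1e3, 1500, 10
        spec = gs.unlinked_genome_spec(loci, locus_length=ell, mutation_rate=mu,
                                       generation_years=1.0)
        anc = gs.drop_genomes(founder_pop.pedigree, founder_ids[:n_ind], spec,
                              np.random.default_rng(13))
        gen = gs.recapitate(anc, n_anc, np.random.default_rng(13))
        gm = gs.overlay_mutations(gen, np.random.default_rng(13))
        nh = 2 * n_ind
        freqs = gm.haplotypes.mean(axis=0)
        pi_mine = float((2 * freqs * (1 - freqs) * nh / (nh - 1)).sum())

        s_ms, pi_ms = 0, 0.0
        for rep in range(loci):
            ts = msprime.sim_ancestry(
                samples=n_ind, population_size=n_anc, sequence_length=ell,
                recombination_rate=0, random_seed=rep + 1,
            )
            ts = msprime.sim_mutations(ts, rate=mu, random_seed=rep + 1,
                                       discrete_genome=False)
            s_ms += ts.num_sites
            pi_ms += ts.diversity(mode="site") * ell
        assert gm.n_loci == pytest.approx(s_ms, rel=0.05)
        assert pi_mine == pytest.approx(pi_ms, rel=0.07)


@pytest.fixture(scope="module")
def gm(founder_pop, founder_ids):
    spec = gs.unlinked_genome_spec(1200, locus_length=2e3, mutation_rate=5e-7,
                                   generation_years=1.0)
    rng = np.random.default_rng(20)
    return gs.simulate_genomes(founder_pop.pedigree, founder_ids[:30], spec,
                               150.0, rng)


class TestSubsetLoci:
    def test_contract(self, gm):
        rng = np.random.default_rng(0)
        sub = gs.subset_loci(gm, 200, 0.05, rng)
        assert sub.n_loci == 200
        assert (sub.maf() >= 0.05).all()

    def test_shortfall_error(self, gm):
        with pytest.raises(ShortfallError):
            gs.subset_loci(gm, 10**6, 0.05, np.random.default_rng(0))

    def test_eligible_set_matches_direct_frequency_filter(self, gm):
        rng = np.random.default_rng(1)
        maf_min = 0.1
        eligible = set()
        for j in range(gm.n_loci):
            g = gm.genotypes[:, j]
            p = g.sum() / (2 * len(g))
            if 0 < min(p, 1 - p) and min(p, 1 - p) >= maf_min:
                eligible.add(gm.locus_names[j])
        n = len(eligible)
        sub = gs.subset_loci(gm, n, maf_min, rng)
        assert set(sub.locus_names) == eligible
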