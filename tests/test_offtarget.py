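"""Flaw-budget site enumeration: identity cases, planted fixtures, and the
oracle/invariant properties (brute-force equivalence, budget monotonicity,
strand symmetry, N handling)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crispri_specificity as cs
from crispri_specificity._seq import revcomp
from crispri_specificity.simulate import PlantSpec, make_planted_genome

from conftest import SPACER20, random_genome, random_spacer


def site_keys(sites):
    return {(s.chromosome, s.start, s.strand, s.seed_flaws, s.nonseed_flaws)
            for s in sites}


class TestEnumerate:
    def test_exact_match_single_site(self, exact_genome, spacer):
        sites = cs.enumerate_sites(exact_genome, spacer, cs.FlawBudget(2, 2, 4))
        assert [(s.start, s.end, s.strand, s.seed_flaws, s.nonseed_flaws)
                for s in sites] == [(4, 24, "+", 0, 0)]
        assert sites[0].pam_sequence == "TGG"

    def test_zero_budget_excludes_any_mismatch(self, spacer):
        mutated = SPACER20[:19] + ("C" if SPACER20[19] != "C" else "G")
        genome = cs.Genome({"chr1": "AAAA" + mutated + "TGG" + "AAAA"})
        assert cs.enumerate_sites(genome, spacer, cs.FlawBudget(0, 0, 0)) == []

    def test_no_pam_no_site(self, spacer):
        genome = cs.Genome({"chr1": "AAAA" + SPACER20 + "TCC" + "AAAA"})
        assert cs.enumerate_sites(genome, spacer, cs.FlawBudget(2, 2, 4)) == []

    def test_chromosome_shorter_than_spacer_yields_nothing(self, spacer):
        genome = cs.Genome({"tiny": "ACGTACGT"})
        assert cs.enumerate_sites(genome, spacer) == []

    def test_seed_longer_than_spacer_rejected(self, exact_genome, spacer):
        with pytest.raises(ValueError, match="seed_length"):
            cs.enumerate_sites(exact_genome, spacer,
                               cs.FlawBudget(seed_length=21))

    def test_ambiguous_spacer_rejected(self):
        with pytest.raises(ValueError, match="unambiguous"):
            cs.Spacer("bad", "ACGTACGTACGTACGTACGN")

    def test_planted_partitions_recovered_and_overbudget_absent(self):
        """2 kb genome with (0,2), (2,0), (2,2) in budget and a (3,0) decoy."""
        rng = np.random.default_rng(11)
        sp_seq = "".join(rng.choice(list("ACGT"), size=20))
        specs = [PlantSpec(sp_seq, "chr1", 100, "+", 0, 2),
                 PlantSpec(sp_seq, "chr1", 600, "+", 2, 0),
                 PlantSpec(sp_seq, "chr1", 1100, "-", 2, 2),
                 PlantSpec(sp_seq, "chr1", 1600, "+", 3, 0)]
        genome, truth = make_planted_genome({"chr1": 2000}, specs, rng_seed=5)
        sites = cs.enumerate_sites(genome, cs.Spacer("g", sp_seq),
                                   cs.FlawBudget(2, 2, 4))
        got = {(s.start, s.strand): (s.seed_flaws, s.nonseed_flaws)
               for s in sites}
        assert got == {(100, "+"): (0, 2), (600, "+"): (2, 0),
                       (1100, "-"): (2, 2)}

    def test_minus_strand_interval_matches_oracle(self):
        rng = np.random.default_rng(3)
        sp_seq = "".join(rng.choice(list("ACGT"), size=20))
        genome, _ = make_planted_genome(
            {"chr1": 500}, [PlantSpec(sp_seq, "chr1", 200, "-", 1, 1)],
            rng_seed=9)
        sp = cs.Spacer("g", sp_seq)
        fast = cs.enumerate_sites(genome, sp)
        slow = cs.brute_force_sites(genome, sp)
        assert fast == slow
        assert any(s.start == 200 and s.end == 220 and s.strand == "-"
                   for s in fast)

    def test_output_sorted_deterministically(self, study):
        sites = cs.enumerate_sites(study.genome, study.spacer, study.budget)
        keys = [(s.chromosome, s.start, s.strand, s.guide_id) for s in sites]
        assert keys == sorted(keys)


class TestBruteForce:
    def test_empty_genome_window(self, spacer):
        genome = cs.Genome({"chr1": "A" * 10})
        assert cs.brute_force_sites(genome, spacer) == []

    def test_refuses_large_genome(self, spacer):
        genome = cs.Genome({"chr1": "A" * (10**6 + 1)})
        with pytest.raises(ValueError, match="exceeds"):
            cs.brute_force_sites(genome, spacer)


class TestPoolSites:
    def test_pool_of_one_is_identity(self, exact_genome, spacer):
        sites = cs.enumerate_sites(exact_genome, spacer)
        assert cs.pool_sites([sites]) == sites

    def test_disjoint_union(self):
        def site(guide, start):
            return cs.OffTargetSite("chr1", start, "+", guide, end=start + 20)
        a = [site("g1", x) for x in (10, 100, 200)]
        b = [site("g2", x) for x in (300, 400)]
        assert len(cs.pool_sites([a, b])) == 5

    def test_shared_locus_kept_per_guide_and_flagged(self):
        def site(guide, start):
            return cs.OffTargetSite("chr1", start, "+", guide, end=start + 20)
        pooled = cs.pool_sites([[site("g1", 50)], [site("g2", 50)]])
        assert len(pooled) == 2
        from crispri_specificity.offtarget import shared_loci
        assert shared_loci(pooled) == {("chr1", 50, "+")}

    def test_duplicate_records_deduplicated(self, exact_genome, spacer):
        sites = cs.enumerate_sites(exact_genome, spacer)
        assert cs.pool_sites([sites, sites]) == sites


class TestProperties:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random(self, seed):
        """Fast scanner and literal oracle agree on random small genomes."""
        rng = np.random.default_rng(seed)
        genome = random_genome(rng, int(rng.integers(60, 400)), n_frac=0.03)
        sp = random_spacer(rng, int(rng.integers(18, 23)))
        budget = cs.FlawBudget(int(rng.integers(0, 4)), int(rng.integers(0, 4)),
                               int(rng.integers(0, 5)),
                               int(rng.integers(0, len(sp) + 1)))
        assert set(cs.enumerate_sites(genome, sp, budget)) == \
            set(cs.brute_force_sites(genome, sp, budget))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_budget_monotonicity(self, seed):
        """sites(A) is a subset of sites(B) when A's caps are all <= B's."""
        rng = np.random.default_rng(seed)
        sp = random_spacer(rng)
        genome, _ = make_planted_genome(
            {"chr1": 1500},
            [PlantSpec(sp.sequence, "chr1", 100 + 500 * k, "+", s, n)
             for k, (s, n) in enumerate([(0, 1), (1, 2), (2, 2)])],
            rng_seed=int(rng.integers(0, 2**31 - 1)))
        small = cs.FlawBudget(int(rng.integers(0, 3)), int(rng.integers(0, 3)),
                              int(rng.integers(0, 4)))
        big = cs.FlawBudget(small.max_seed_flaws + 1,
                            small.max_nonseed_flaws + 1,
                            small.max_total_flaws + 1)
        assert site_keys(cs.enumerate_sites(genome, sp, small)) <= \
            site_keys(cs.enumerate_sites(genome, sp, big))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the genome mirrors the site coordinates."""
        rng = np.random.default_rng(seed)
        sp = random_spacer(rng)
        genome, _ = make_planted_genome(
            {"chr1": 1000},
            [PlantSpec(sp.sequence, "chr1", 300, "+", 1, 1),
             PlantSpec(sp.sequence, "chr1", 700, "-", 2, 0)],
            rng_seed=int(rng.integers(0, 2**31 - 1)))
        n = len(genome["chr1"])
        mirrored = cs.Genome({"chr1": revcomp(genome["chr1"])})
        fwd = cs.enumerate_sites(genome, sp)
        rev = cs.enumerate_sites(mirrored, sp)
        expected = {("chr1", n - s.end, "-" if s.strand == "+" else "+",
                     s.seed_flaws, s.nonseed_flaws) for s in fwd}
        assert site_keys(rev) == expected

    @pytest.mark.parametrize("n_count", [1, 2, 3])
    def test_n_bases_count_as_flaws(self, spacer, n_count):
        """A window with k N's carries at least k total flaws."""
        seq = list(SPACER20)
        for j in range(n_count):
            seq[5 + j] = "N"
        genome = cs.Genome({"chr1": "AAAA" + "".join(seq) + "TGG" + "AAAA"})
        sites = cs.enumerate_sites(genome, spacer, cs.FlawBudget(4, 4, 8))
        at_locus = [s for s in sites if s.start == 4 and s.strand == "+"]
        assert at_locus and at_locus[0].total_flaws >= n_count

    def test_n_in_pam_never_matches(self, spacer):
        genome = cs.Genome({"chr1": "AAAA" + SPACER20 + "TNG" + "AAAA"})
        assert cs.enumerate_sites(genome, spacer, cs.FlawBudget(2, 2, 4)) == []


class TestOnTargetFlag:
    def test_site_near_intended_tss_flagged(self, exact_genome):
        sp = cs.Spacer("sg1", SPACER20, intended_gene="GENE1",
                       intended_tss=("chr1", 30))
        (site,) = cs.enumerate_sites(exact_genome, sp)
        assert site.is_on_target

    def test_site_far_from_intended_tss_not_flagged(self, exact_genome):
        sp = cs.Spacer("sg1", SPACER20, intended_gene="GENE1",
                       intended_tss=("chr2", 30))
        (site,) = cs.enumerate_sites(exact_genome, sp)
        assert not site.is_on_target
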