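import math

import numpy as np
import pytest

from haplopop import synthio, variant_qc
from haplopop.core import MISSING
from haplopop.variant_qc import NotEvaluable


class TestFlagHaploidHets:
    def test_het_in_haploid_flags_locus(self, gm_factory):
        g = gm_factory([[1, 0], [0, 1]], [1, 2],
                       haploid_het=[[True, False], [False, False]])
        res = variant_qc.flag_haploid_hets(g)
        assert res.flags.tolist() == [True, False]

    def test_all_homozygous_no_flags(self, gm_factory):
        g = gm_factory([[1, 0], [0, 1]], [1, 2],
                       haploid_het=[[False, False], [False, False]])
        assert not variant_qc.flag_haploid_hets(g).flags.any()

    def test_no_haploids_not_evaluable(self, gm_factory):
        g = gm_factory([[1, 0]], [2], haploid_het=[[False, False]])
        with pytest.raises(NotEvaluable):
            variant_qc.flag_haploid_hets(g)

    def test_contaminated_sample_masked_not_flagged(self, gm_factory):
        # 10 haploids; one carries hets at 30 loci while the rest are clean:
        # its het positions must go missing without flagging those loci
        n_loci = 40
        het = np.zeros((10, n_loci), dtype=bool)
        het[0, :30] = True
        dosages = np.ones((10, n_loci), dtype=np.int16)
        g = gm_factory(dosages, [1] * 10, haploid_het=het)
        res = variant_qc.flag_haploid_hets(g)
        assert res.contaminated == ["s1"]
        assert not res.flags.any()
        assert (res.masked.dosages[0, :30] == MISSING).all()
        assert (res.masked.dosages[0, 30:] == 1).all()


class TestHetExcess:
    def test_seven_of_ten_flagged(self, gm_factory):
        col = [1] * 7 + [0] * 3
        g = gm_factory(np.array([col]).T, [2] * 10)
        flags, ok = variant_qc.het_excess(g)
        assert flags[0] and ok[0]

    def test_boundary_six_of_ten_not_flagged(self, gm_factory):
        col = [1] * 6 + [0] * 4
        g = gm_factory(np.array([col]).T, [2] * 10)
        flags, _ = variant_qc.het_excess(g)
        assert not flags[0]

    def test_all_homozygous_not_flagged(self, gm_factory):
        g = gm_factory(np.array([[0, 2, 0, 2]]).T, [2] * 4)
        flags, _ = variant_qc.het_excess(g)
        assert not flags[0]

    def test_all_missing_not_evaluable(self, gm_factory):
        g = gm_factory([[MISSING], [MISSING]], [2, 2])
        flags, ok = variant_qc.het_excess(g)
        assert not ok[0] and not flags[0]


class TestReadRatioD:
    def _one_het(self, gm_factory, ad_ref, ad_alt):
        return gm_factory([[1]], [2], depth=[[ad_ref + ad_alt]],
                          ad_ref=[[ad_ref]], ad_alt=[[ad_alt]])

    def test_balanced_reads_zero(self, gm_factory):
        _, _, d = variant_qc.read_ratio_D(self._one_het(gm_factory, 50, 50))
        assert d[0] == pytest.approx(0.0)

    def test_eighty_of_hundred(self, gm_factory):
        # D = (80 - 50) / sqrt(25) = 6
        _, _, d = variant_qc.read_ratio_D(self._one_het(gm_factory, 20, 80))
        assert d[0] == pytest.approx(6.0)

    def test_four_hundred_of_five_hundred_not_flagged(self, gm_factory):
        flags, _, d = variant_qc.read_ratio_D(self._one_het(gm_factory, 100, 400))
        assert d[0] == pytest.approx(150.0 / math.sqrt(125.0))
        assert not flags[0]

    def test_no_heterozygotes_undefined(self, gm_factory):
        g = gm_factory([[0], [2]], [2, 2], depth=[[10], [10]],
                       ad_ref=[[10], [0]], ad_alt=[[0], [10]])
        flags, ok, d = variant_qc.read_ratio_D(g)
        assert np.isnan(d[0]) and not ok[0] and not flags[0]


def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Independent exact HWE p-value by direct combinatorial enumeration."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_minor = min(n_a, 2 * n - n_a)
    denom = math.comb(2 * n, n_minor)

    def prob(het):
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        ways = (math.factorial(n)
                // (math.factorial(hom_minor) * math.factorial(het) * math.factorial(hom_major)))
        return ways * 2**het / denom

    obs = prob(n_ab)
    total = 0.0
    for het in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        p = prob(het)
        if p <= obs * (1 + 1e-12):
            total += p
    return total


class TestHweExact:
    @pytest.mark.parametrize("counts", [(5, 0, 5), (3, 4, 3), (10, 5, 1),
                                        (0, 10, 0), (8, 2, 0), (2, 2, 2)])
    def test_matches_enumeration_oracle(self, counts):
        assert variant_qc.hwe_exact_p(*counts) == pytest.approx(
            hwe_exact_oracle(*counts), abs=1e-12)

    def test_probabilities_sum_to_one_under_null(self):
        # sanity: perfect HWE proportions are never extreme
        assert variant_qc.hwe_exact_p(25, 50, 25) > 0.05


class TestHweMultiPop:
    def _matrix(self, gm_factory, sheet_factory, pop_counts):
        """One locus; pop_counts is a list of (n_aa, n_ab, n_bb) per population."""
        dosages, pops = [], []
        for p, (aa, ab, bb) in enumerate(pop_counts):
            col = [0] * aa + [1] * ab + [2] * bb
            dosages.extend([[c] for c in col])
            pops.extend([f"pop{p}"] * len(col))
        samples = [f"s{i}" for i in range(len(dosages))]
        g = gm_factory(dosages, [2] * len(dosages), samples=samples)
        sheet = sheet_factory(samples, pops)
        return g, sheet

    def test_failing_in_four_of_eight_flagged(self, gm_factory, sheet_factory):
        bad, good = (5, 0, 5), (3, 4, 3)
        g, sheet = self._matrix(gm_factory, sheet_factory, [bad] * 4 + [good] * 4)
        flags, ok, n_fail = variant_qc.hwe_multi_pop(g, sheet)
        assert n_fail[0] == 4 and flags[0]

    def test_failing_in_three_of_eight_not_flagged(self, gm_factory, sheet_factory):
        bad, good = (5, 0, 5), (3, 4, 3)
        g, sheet = self._matrix(gm_factory, sheet_factory, [bad] * 3 + [good] * 5)
        flags, _, n_fail = variant_qc.hwe_multi_pop(g, sheet)
        assert n_fail[0] == 3 and not flags[0]

    def test_perfect_hwe_not_flagged(self, gm_factory, sheet_factory):
        g, sheet = self._matrix(gm_factory, sheet_factory, [(4, 8, 4)] * 8)
        flags, _, _ = variant_qc.hwe_multi_pop(g, sheet)
        assert not flags[0]

    def test_threshold_scales_with_fewer_pops(self, gm_factory, sheet_factory):
        # 4 diploid pops: threshold floor(3*4/8) = 1, so 2 failures flag
        bad, good = (5, 0, 5), (3, 4, 3)
        g, sheet = self._matrix(gm_factory, sheet_factory, [bad] * 2 + [good] * 2)
        flags, _, n_fail = variant_qc.hwe_multi_pop(g, sheet)
        assert n_fail[0] == 2 and flags[0]

    def test_single_population_not_evaluable(self, gm_factory, sheet_factory):
        g, sheet = self._matrix(gm_factory, sheet_factory, [(3, 4, 3)])
        with pytest.raises(NotEvaluable):
            variant_qc.hwe_multi_pop(g, sheet)


class TestWindowScreen:
    def test_rate_above_threshold_excluded(self, gm_factory):
        g = gm_factory(np.zeros((1, 10), dtype=int), [2],
                       positions=np.arange(1, 101, 10))
        err = np.zeros(10, dtype=bool)
        err[:2] = True  # 2/10 = 0.2 > 0.1
        rep = variant_qc.window_screen(err, g)
        assert rep.windows.iloc[0]["excluded"]
        assert not rep.kept_loci.any()
        assert rep.excluded_bp == 250

    def test_boundary_rate_retained(self, gm_factory):
        g = gm_factory(np.zeros((1, 10), dtype=int), [2],
                       positions=np.arange(1, 101, 10))
        err = np.zeros(10, dtype=bool)
        err[0] = True  # exactly 0.1, strict >
        rep = variant_qc.window_screen(err, g)
        assert not rep.windows.iloc[0]["excluded"]
        assert rep.kept_loci.all()

    def test_empty_window_not_evaluated(self, gm_factory):
        g = gm_factory(np.zeros((1, 2), dtype=int), [2], positions=[10, 600])
        rep = variant_qc.window_screen(np.zeros(2, dtype=bool), g)
        # only windows containing SNPs appear; both retained
        assert len(rep.windows) == 2
        assert rep.kept_loci.all()

    def test_matches_brute_force_recount(self):
        cfg = synthio.SimConfig(n_pops=4, samples_per_pop=8, n_loci=2000,
                                loci_per_contig=400, seed=13)
        g, _ = synthio.simulate_nuclear(cfg)
        rng = np.random.default_rng(0)
        err = rng.random(g.n_loci) < 0.15
        rep = variant_qc.window_screen(err, g)
        # independent recount straight from positions
        for row in rep.windows.itertuples():
            in_win = ((g.contigs == row.contig)
                      & (g.positions - 1 >= row.start) & (g.positions - 1 < row.end))
            assert in_win.sum() == row.n_snps
            assert err[in_win].sum() == row.n_flagged
            assert row.excluded == (err[in_win].sum() / in_win.sum() > 0.10)
        kept_expected = np.ones(g.n_loci, dtype=bool)
        for row in rep.windows[rep.windows["excluded"]].itertuples():
            in_win = ((g.contigs == row.contig)
                      & (g.positions - 1 >= row.start) & (g.positions - 1 < row.end))
            kept_expected[in_win] = False
        assert (rep.kept_loci == kept_expected).all()


class TestDepthMissingFilter:
    def test_depth_boundary(self, gm_factory, sheet_factory):
        g = gm_factory([[1, 1]], [2], depth=[[5, 6]])
        sheet = sheet_factory(["s1"], ["p1"])
        out = variant_qc.depth_missing_filter(g, sheet, min_pop_call=0.0,
                                              max_missing=1.0)
        assert out.dosages[0, 0] == MISSING
        assert out.dosages[0, 1] == 1

    def test_haploid_depth_untouched(self, gm_factory, sheet_factory):
        g = gm_factory([[1]], [1], depth=[[2]])
        sheet = sheet_factory(["s1"], ["p1"], ploidy=[1])
        out = variant_qc.depth_missing_filter(g, sheet, min_pop_call=0.0,
                                              max_missing=1.0)
        assert out.dosages[0, 0] == 1

    def test_per_population_call_rate(self, gm_factory, sheet_factory):
        # locus 0 called in 1/4 of pop1 (25% < 50%) but fully in pop2
        dosages = [[MISSING, 0], [MISSING, 0], [MISSING, 0], [0, 0],
                   [0, 0], [0, 0], [0, 0], [0, 0]]
        g = gm_factory(dosages, [2] * 8)
        sheet = sheet_factory([f"s{i + 1}" for i in range(8)],
                              ["p1"] * 4 + ["p2"] * 4)
        out = variant_qc.depth_missing_filter(g, sheet, max_missing=1.0)
        assert out.n_loci == 1

    def test_identity_on_complete_matrix(self, gm_factory, sheet_factory):
        g = gm_factory([[0, 1], [2, 1]], [2, 2], depth=[[9, 9], [9, 9]])
        sheet = sheet_factory(["s1", "s2"], ["p1", "p1"])
        out = variant_qc.depth_missing_filter(g, sheet)
        assert (out.dosages == g.dosages).all()

    def test_idempotent(self):
        cfg = synthio.SimConfig(n_pops=4, samples_per_pop=8, n_loci=400,
                                depth_mean=7.0, seed=21)
        g, _ = synthio.simulate_nuclear(cfg)
        sheet = synthio.build_sheet(cfg)
        once = variant_qc.depth_missing_filter(g, sheet)
        twice = variant_qc.depth_missing_filter(once, sheet)
        assert once.n_loci == twice.n_loci
        assert (once.dosages == twice.dosages).all()


class TestLdPrune:
    def test_duplicated_snp_one_survives(self, gm_factory):
        col = np.array([0, 1, 2, 0, 1, 2, 0, 2])
        g = gm_factory(np.stack([col, col], axis=1), [2] * 8, positions=[100, 200])
        out = variant_qc.ld_prune(g, seed=0)
        assert out.n_loci == 1

    def test_independent_snps_survive(self, gm_factory):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 3, 50), rng.integers(0, 3, 50)
        g = gm_factory(np.stack([a, b], axis=1), [2] * 50, positions=[100, 200])
        assert variant_qc.ld_prune(g, seed=0).n_loci == 2

    def test_deterministic_given_seed(self):
        cfg = synthio.SimConfig(n_pops=3, samples_per_pop=10, n_loci=300, seed=17)
        g, _ = synthio.simulate_nuclear(cfg)
        a = variant_qc.ld_prune(g, seed=42)
        b = variant_qc.ld_prune(g, seed=42)
        assert (a.positions == b.positions).all() and (a.contigs == b.contigs).all()

    def test_monomorphic_skipped(self, gm_factory):
        mono = np.zeros(6, dtype=int)
        poly = np.array([0, 1, 2, 0, 1, 2])
        g = gm_factory(np.stack([mono, poly], axis=1), [2] * 6, positions=[10, 20])
        assert variant_qc.ld_prune(g, seed=0).n_loci == 2


class TestSplitDiploids:
    def test_homozygote_forced(self, gm_factory):
        g = gm_factory([[2, 0]], [2])
        out = variant_qc.split_diploids(g, seed=0)
        assert out.n_samples == 2
        assert (out.dosages == [[1, 0], [1, 0]]).all()

    def test_heterozygote_one_each(self, gm_factory):
        g = gm_factory([[1]], [2])
        out = variant_qc.split_diploids(g, seed=0)
        assert sorted(out.dosages[:, 0].tolist()) == [0, 1]

    def test_allele_counts_conserved_exactly(self):
        cfg = synthio.SimConfig(n_pops=3, samples_per_pop=10, n_loci=500,
                                ploidy_per_pop={"P01": 1}, seed=19)
        g, _ = synthio.simulate_nuclear(cfg)
        out = variant_qc.split_diploids(g, seed=5)
        alt_in, tot_in = g.allele_counts()
        alt_out, tot_out = out.allele_counts()
        assert (alt_in == alt_out).all() and (tot_in == tot_out).all()
        assert (out.ploidy == 1).all()

    def test_missing_propagates(self, gm_factory):
        g = gm_factory([[MISSING]], [2])
        out = variant_qc.split_diploids(g, seed=0)
        assert (out.dosages == MISSING).all()

    def test_haploids_pass_through(self, gm_factory):
        g = gm_factory([[1, 0]], [1])
        out = variant_qc.split_diploids(g, seed=0)
        assert out.samples == ["s1"]
        assert (out.dosages == g.dosages).all()
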