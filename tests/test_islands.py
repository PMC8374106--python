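import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mchh_islands import (
    GeneModel,
    Methylome,
    associate_genes,
    by_adjust,
    call_islands,
    coverage_filter,
    empirical_cutoff_call,
    method_agreement,
)
from mchh_islands import test_window as window_tail_p
from mchh_islands.islands import GeneIslandStatus
from mchh_islands.methylation import Background, ContextLevel
from conftest import make_methylome


def brute_force_tail(k, n, p0):
    """Independent oracle: exact summation of the upper binomial tail."""
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
    return total


def step_up_by(p):
    """Independent oracle: direct Benjamini-Yekutieli step-up formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestWindowTest:
    def test_zero_methylated_reads_give_p_one(self):
        assert window_tail_p(0, 25, 0.1) == 1.0

    def test_all_methylated_closed_form(self):
        assert window_tail_p(10, 10, 0.5) == pytest.approx(2**-10)

    def test_matches_brute_force_summation(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 21))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.5))
            assert window_tail_p(k, n, p0) == pytest.approx(
                brute_force_tail(k, n, p0), rel=1e-10
            )

    def test_zero_coverage_gives_p_one(self):
        assert window_tail_p(0, 0, 0.05) == 1.0

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_degenerate_background_is_an_error(self, p0):
        with pytest.raises(ValueError):
            window_tail_p(1, 10, p0)

    @given(st.integers(1, 200), st.floats(0.01, 0.5))
    def test_monotone_in_methylated_count(self, n, p0):
        ps = [window_tail_p(k, n, p0) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestByAdjust:
    def test_single_p_value_unchanged(self):
        assert by_adjust([0.02]) == pytest.approx([0.02])

    def test_hand_computed_four_values(self):
        # c(4) = 25/12; smallest q = 0.01 * 4 * (25/12) / 1 = 1/12, and the
        # monotone minimum propagates it to every entry
        q = by_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [1 / 12] * 4, rtol=1e-12)

    def test_all_ones_stay_capped(self):
        assert list(by_adjust([1, 1, 1])) == [1, 1, 1]

    def test_empty_input_gives_empty_output(self):
        assert by_adjust([]).size == 0

    def test_matches_direct_step_up_formula(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            np.testing.assert_allclose(by_adjust(p), step_up_by(p), rtol=1e-10)

    def test_by_is_more_conservative_than_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=30)
            _, bh, _, _ = multipletests(p, method="fdr_bh")
            assert np.all(by_adjust(p) >= bh - 1e-12)


def _window_methylome(site_specs):
    """site_specs: list of (chrom, pos, n_meth, n_total) CHH sites."""
    return make_methylome([(c, p, "+", "CHH", m, t) for c, p, m, t in site_specs])


def _bg(p_chh=0.05):
    mk = lambda ctx, p: ContextLevel(ctx, p, 1000, int(p * 10000), 10000)
    return Background({"CG": mk("CG", 0.6), "CHG": mk("CHG", 0.4), "CHH": mk("CHH", p_chh)})


class TestCallIslands:
    def test_window_with_exactly_five_sites_is_never_tested(self):
        # window [0,100): 5 covered sites; window [100,200): 6 covered sites
        sites = [("c", p, 5, 10) for p in range(0, 50, 10)]
        sites += [("c", 100 + p, 5, 10) for p in range(0, 60, 10)]
        meth = _window_methylome(sites)
        genes = [GeneModel("g", "c", 1000, 2000, "+")]
        calls = call_islands(meth, genes, background=_bg())
        assert [c.start for c in calls] == [100]

    def test_significant_window_outside_flank_is_not_an_island(self):
        # gene TSS at 5000 (+): 5' flank [3000, 5000); window at [2900,3000)
        # is 2.0-2.1 kb upstream -> excluded even if highly significant
        sites = [("c", 2900 + p, 10, 10) for p in range(0, 70, 10)]
        meth = _window_methylome(sites)
        genes = [GeneModel("g", "c", 5000, 6000, "+")]
        calls = call_islands(meth, genes, background=_bg())
        (call,) = calls
        assert call.q_value < 0.01 and not call.is_island

    def test_window_overlapping_flank_boundary_is_associated(self):
        # window [2900,3000) overlaps flank [2950,4950) by 50 bp -> island
        sites = [("c", 2900 + p, 10, 10) for p in range(0, 70, 10)]
        meth = _window_methylome(sites)
        genes = [GeneModel("g", "c", 4950, 6000, "+")]
        (call,) = call_islands(meth, genes, background=_bg())
        assert call.is_island and call.assoc == [("g", "5p")]

    def test_calling_invariant_under_chromosome_relabeling(self):
        sites = [("c", 1000 + p, 9, 10) for p in range(0, 70, 10)]
        genes = [GeneModel("g", "c", 1500, 2500, "+")]
        calls_a = call_islands(_window_methylome(sites), genes, background=_bg())
        sites_b = [("q",) + s[1:] for s in sites]
        genes_b = [GeneModel("g", "q", 1500, 2500, "+")]
        calls_b = call_islands(_window_methylome(sites_b), genes_b, background=_bg())
        assert [(c.start, c.p_value, c.is_island) for c in calls_a] == [
            (c.start, c.p_value, c.is_island) for c in calls_b
        ]

    def test_methylated_site_metric_is_stricter(self):
        # 7 covered sites but only 3 carry methylated reads
        sites = [("c", p * 10, (1 if p < 3 else 0), 10) for p in range(7)]
        meth = _window_methylome(sites)
        genes = [GeneModel("g", "c", 1000, 2000, "+")]
        assert len(call_islands(meth, genes, background=_bg())) == 1
        with pytest.raises(ValueError):
            call_islands(meth, genes, background=_bg(), site_metric="methylated")

    def test_no_genes_is_an_error(self):
        meth = _window_methylome([("c", 0, 1, 2)])
        with pytest.raises(ValueError):
            call_islands(meth, [], background=_bg())


class TestCoverageFilter:
    def _meth(self, n_deep, n_shallow):
        # gene at [3000,4000)+ -> 5' flank [1000,3000)
        sites = [("c", 1000 + i * 10, 0, 3) for i in range(n_deep)]
        sites += [("c", 2000 + i * 5, 0, 2) for i in range(n_shallow)]
        return _window_methylome(sites)

    def test_just_under_half_deep_sites_is_excluded(self):
        gene = GeneModel("g", "c", 3000, 4000, "+")
        assert not coverage_filter(gene, self._meth(49, 51))

    def test_just_over_half_deep_sites_is_included(self):
        gene = GeneModel("g", "c", 3000, 4000, "+")
        assert coverage_filter(gene, self._meth(51, 49))

    def test_zero_depth_everywhere_is_excluded(self):
        gene = GeneModel("g", "c", 3000, 4000, "+")
        meth = _window_methylome([("c", 1000 + i, 0, 0) for i in range(100)])
        assert not coverage_filter(gene, meth)

    def test_no_chh_sites_in_flank_is_excluded(self):
        gene = GeneModel("g", "c", 3000, 4000, "+")
        meth = make_methylome([("c", 1500, "+", "CG", 1, 5)])
        assert not coverage_filter(gene, meth)


def _mk_island(chrom, start, end):
    from mchh_islands.islands import IslandCall

    return IslandCall(chrom, start, end, 10, 40, 100, 0.4, 1e-6, 1e-5, is_island=True)


class TestAssociateGenes:
    def test_one_base_overlap_with_flank_counts(self):
        # flank of + gene at 5000: [3000,5000); island [2901,3001) overlaps 1 bp
        gene = GeneModel("g", "c", 5000, 6000, "+")
        (st_,) = associate_genes([_mk_island("c", 2901, 3001)], [gene])
        assert st_.has_5p_island

    def test_minus_strand_upstream_is_physically_right(self):
        # - gene [1000,2000): tss=1999, 5' flank [2000,4000); island at 2500
        gene = GeneModel("g", "c", 1000, 2000, "-")
        (st_,) = associate_genes([_mk_island("c", 2500, 2600)], [gene])
        assert st_.has_5p_island and st_.nearest_island_distance == 501

    def test_coverage_failed_gene_reports_no_islands(self):
        gene = GeneModel("g", "c", 5000, 6000, "+")
        (st_,) = associate_genes(
            [_mk_island("c", 4000, 4100)], [gene], coverage_ok={"g": False}
        )
        assert not st_.coverage_ok and not st_.has_5p_island

    def test_downstream_island_sets_3p_flag(self):
        gene = GeneModel("g", "c", 5000, 6000, "+")
        (st_,) = associate_genes([_mk_island("c", 6500, 6600)], [gene])
        assert st_.has_3p_island and not st_.has_5p_island


class TestEmpiricalCutoff:
    def test_threshold_is_a_closed_lower_bound(self):
        genes = [GeneModel("g", "c", 1000, 2000, "+")]
        at_24 = _window_methylome([("c", p * 10, 24, 100) for p in range(7)])
        at_25 = _window_methylome([("c", p * 10, 25, 100) for p in range(7)])
        assert not any(c.is_island for c in empirical_cutoff_call(at_24, genes))
        assert any(c.is_island for c in empirical_cutoff_call(at_25, genes))

    def test_unmethylated_genome_yields_no_islands(self):
        genes = [GeneModel("g", "c", 1000, 2000, "+")]
        meth = _window_methylome([("c", p * 10, 0, 10) for p in range(20)])
        assert sum(c.is_island for c in empirical_cutoff_call(meth, genes)) == 0

    def test_cutoff_mode_calls_more_at_high_background(self):
        """With a 20% genome background, the fixed 25% cutoff fires on
        background windows that the background-adaptive binomial ignores."""
        rng = np.random.default_rng(42)
        sites = [
            ("c", p, int(rng.binomial(20, 0.2)), 20) for p in range(0, 20000, 8)
        ]
        meth = _window_methylome(sites)
        genes = [GeneModel("g", "c", 8000, 12000, "+")]
        binom_calls = call_islands(meth, genes, background=_bg(p_chh=0.2))
        cut_calls = empirical_cutoff_call(meth, genes)
        assert sum(c.is_island for c in cut_calls) > sum(
            c.is_island for c in binom_calls
        )


class TestMethodAgreement:
    @staticmethod
    def _status(flags):
        return [
            GeneIslandStatus(f"g{i}", True, f, False, float("nan"))
            for i, f in enumerate(flags)
        ]

    def test_identical_designations_agree_fully(self):
        a = self._status([True, False, True])
        assert method_agreement(a, self._status([True, False, True])) == 1.0

    def test_complementary_designations_agree_never(self):
        a = self._status([True, False])
        b = self._status([False, True])
        assert method_agreement(a, b) == 0.0

    def test_differing_gene_universes_are_an_error(self):
        a = self._status([True])
        b = [GeneIslandStatus("other", True, True, False, float("nan"))]
        with pytest.raises(ValueError):
            method_agreement(a, b)

    def test_binomial_and_cutoff_modes_agree_on_simulated_data(self, default_sim):
        sim = default_sim
        binom = call_islands(sim.methylome, sim.genes)
        cut = empirical_cutoff_call(sim.methylome, sim.genes)
        cov = {g.gene_id: True for g in sim.genes}
        a = associate_genes(binom, sim.genes, coverage_ok=cov)
        b = associate_genes(cut, sim.genes, coverage_ok=cov)
        assert 0.7 <= method_agreement(a, b) <= 1.0
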