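import numpy as np
import pandas as pd
import pytest

from mchh_islands import (
    GeneModel,
    RepeatFeature,
    blast_evalue_summary,
    classify_coincidence,
    feltz_miller_cv_test,
    island_te_distances,
    superfamily_enrichment,
    tables,
)
from mchh_islands.io import read_blast_tab
from mchh_islands.islands import IslandCall
from mchh_islands.te import coincidence_by_superfamily


def _expand(df):
    rows = []
    for _, r in df.iterrows():
        rows += [{"superfamily": r["superfamily"], "has_island": True}] * int(r["k"])
        rows += [{"superfamily": r["superfamily"], "has_island": False}] * int(
            r["n"] - r["k"]
        )
    return pd.DataFrame(rows)


class TestSuperfamilyEnrichment:
    @pytest.mark.parametrize("species", sorted(tables.TE_SUPERFAMILY_TABLE))
    def test_reproduces_published_labels(self, species):
        """Re-testing the published per-superfamily counts recovers every
        printed Enriched/Under/NS label."""
        df = tables.reconstruct_superfamily_counts(species)
        res = superfamily_enrichment(_expand(df))
        got = {r.superfamily: r.label for r in res}
        want = dict(zip(df["superfamily"], df["published_label"]))
        assert got == want

    @pytest.mark.parametrize("species", sorted(tables.TE_SUPERFAMILY_TOTALS))
    def test_pooled_proportion_matches_published_total(self, species):
        df = tables.reconstruct_superfamily_counts(species)
        res = superfamily_enrichment(_expand(df))
        n_tot, p_tot = tables.TE_SUPERFAMILY_TOTALS[species]
        assert sum(r.n for r in res) == n_tot
        assert res[0].p0 == pytest.approx(p_tot, abs=5e-4)

    def test_pooled_mean_consistency_identity(self):
        """The count-weighted mean of the per-superfamily proportions equals
        the pooled proportion exactly."""
        df = tables.reconstruct_superfamily_counts("Zea mays")
        res = superfamily_enrichment(_expand(df))
        weighted = sum(r.n * r.proportion for r in res) / sum(r.n for r in res)
        assert weighted == pytest.approx(res[0].p0, rel=1e-12)

    def test_proportion_equal_to_pool_is_ns(self):
        df = pd.DataFrame(
            {"superfamily": ["DTT"] * 10 + ["RLG"] * 10,
             "has_island": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5}
        )
        res = superfamily_enrichment(df)
        assert all(r.label == "NS" and r.p_value == 1.0 for r in res)


class TestFeltzMiller:
    def test_identical_groups_give_zero_statistic(self):
        g = [10.0, 12.0, 9.0, 11.0, 13.0]
        stat, p = feltz_miller_cv_test([g, list(g)])
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_invariant_to_common_rescaling(self, rng):
        a = rng.gamma(5, 2, size=100)
        b = rng.gamma(10, 2, size=100)
        s1, p1 = feltz_miller_cv_test([a, b])
        s2, p2 = feltz_miller_cv_test([a * 7.3, b * 7.3])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_detects_large_cv_difference(self, rng):
        # CVs ~0.2 vs ~0.8 at n=200: overwhelming evidence
        a = rng.normal(10, 2, size=200).clip(0.1)
        b = rng.normal(10, 8, size=200).clip(0.1)
        _, p = feltz_miller_cv_test([a, b])
        assert p < 1e-3

    def test_nonpositive_mean_is_an_error(self):
        with pytest.raises(ValueError):
            feltz_miller_cv_test([[1.0, 2.0], [-3.0, 1.0]])

    def test_single_observation_group_is_an_error(self):
        with pytest.raises(ValueError):
            feltz_miller_cv_test([[1.0], [1.0, 2.0]])


def _pair(islands, tes):
    idx = [f"og{i}" for i in range(len(islands))]
    p = pd.DataFrame(islands, index=idx, columns=["A", "B"], dtype=object)
    t = pd.DataFrame(tes, index=idx, columns=["A", "B"], dtype=object)
    return p, t


class TestCoincidence:
    def test_te_with_island_in_same_species_is_coincident(self):
        p, t = _pair([[True, False]], [[True, False]])
        res = classify_coincidence(p, t)
        assert res.records[0].klass == "coincident" and res.n_coincident == 1

    def test_te_in_other_species_is_dissonant(self):
        p, t = _pair([[True, False]], [[False, True]])
        res = classify_coincidence(p, t)
        assert res.records[0].klass == "dissonant"

    def test_island_in_both_species_is_excluded(self):
        p, t = _pair([[True, True], [True, False]], [[True, False], [True, False]])
        res = classify_coincidence(p, t)
        assert res.records[0].klass == "excluded"
        assert res.n_coincident + res.n_dissonant == 1

    def test_te_in_both_or_neither_is_not_classifiable(self):
        p, t = _pair(
            [[True, False], [False, True], [True, False]],
            [[True, True], [False, False], [True, False]],
        )
        res = classify_coincidence(p, t)
        assert res.n_coincident == 1 and res.n_dissonant == 0

    def test_swapping_species_preserves_classification(self):
        rng = np.random.default_rng(4)
        isl = rng.random((200, 2)) < 0.5
        te = rng.random((200, 2)) < 0.5
        p, t = _pair(isl.tolist(), te.tolist())
        res = classify_coincidence(p, t)
        p2 = p[["B", "A"]]
        t2 = t[["B", "A"]]
        res2 = classify_coincidence(p2, t2)
        assert (res.n_coincident, res.n_dissonant) == (res2.n_coincident, res2.n_dissonant)

    def test_excess_coincidence_is_significant(self, rng):
        isl, te = [], []
        for _ in range(300):
            a = bool(rng.random() < 0.5)
            isl.append([a, not a])
            # TE follows the island 90% of the time
            follow = rng.random() < 0.9
            te.append([a == follow, (not a) == follow])
        res = classify_coincidence(*_pair(isl, te))
        assert res.n_coincident > res.n_dissonant and res.p_value < 0.006

    def test_superfamily_breakdown_flags_planted_bias(self, rng):
        isl, te, fams = [], [], {}
        for i in range(400):
            a = bool(rng.random() < 0.5)
            isl.append([a, not a])
            if i % 2 == 0:  # DTH elements almost always coincident
                coincident = rng.random() < 0.95
                fams[f"og{i}"] = "DTH"
            else:           # RLG elements almost always dissonant
                coincident = rng.random() < 0.05
                fams[f"og{i}"] = "RLG"
            te.append([a == coincident, (not a) == coincident])
        res = classify_coincidence(*_pair(isl, te))
        table = coincidence_by_superfamily(res.records, fams).set_index("superfamily")
        assert table.loc["DTH", "q_value"] < 0.05
        assert table.loc["RLG", "q_value"] < 0.05


class TestBlastSummary:
    def _hits(self, tmp_path, rows):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "".join(
                f"{q}\tte{j}\t95\t100\t1\t0\t1\t100\t1\t100\t{e}\t50\n"
                for j, (q, e) in enumerate(rows)
            )
        )
        return read_blast_tab(p)

    def test_best_evalue_per_query(self, tmp_path):
        hits = self._hits(tmp_path, [("q1", 1e-10), ("q1", 1e-3)])
        per_query, summary = blast_evalue_summary(hits, ["q1", "q2"])
        assert per_query["q1"] == pytest.approx(1e-10)
        assert summary["frac_below_1e-5"] == 0.5

    def test_hitless_query_gets_evalue_one(self, tmp_path):
        hits = self._hits(tmp_path, [("q1", 1e-50)])
        per_query, summary = blast_evalue_summary(hits, ["q1", "q2"])
        assert per_query["q2"] == 1.0
        assert summary["frac_below_1e-40"] == 0.5

    def test_all_hitless_gives_zero_fractions(self, tmp_path):
        hits = self._hits(tmp_path, [])
        _, summary = blast_evalue_summary(hits, ["q1", "q2", "q3"])
        assert summary["frac_below_1e-5"] == 0.0

    def test_unknown_query_id_is_an_error(self, tmp_path):
        hits = self._hits(tmp_path, [("mystery", 1e-10)])
        with pytest.raises(ValueError):
            blast_evalue_summary(hits, ["q1"])


def _island_at(chrom, start, gene_id):
    return IslandCall(chrom, start, start + 100, 10, 40, 100, 0.4, 1e-9, 1e-8,
                      is_island=True, assoc=[(gene_id, "5p")])


class TestIslandTeDistances:
    def test_island_centered_at_te_start_has_zero_edge_distance(self):
        gene = GeneModel("g", "c", 10000, 12000, "+")
        te = RepeatFeature("c", 7050, 9000, "DTT")
        isl = _island_at("c", 7000, "g")  # center 7050 == te.start
        df, cmp = island_te_distances([isl], [te], [gene])
        assert df.loc[0, "dist_te_edge"] == 0

    def test_both_distances_measured_from_midpoint(self):
        gene = GeneModel("g", "c", 10000, 12000, "+")  # tss 10000
        te = RepeatFeature("c", 8900, 11000, "DTM")
        isl = _island_at("c", 9650, "g")  # center 9700
        df, _ = island_te_distances([isl], [te], [gene])
        assert df.loc[0, "dist_te_edge"] == 800  # min(|9700-8900|, |9700-11000|)
        assert df.loc[0, "dist_tss"] == 300

    def test_islands_outside_tes_are_ignored(self):
        gene = GeneModel("g", "c", 10000, 12000, "+")
        te = RepeatFeature("c", 500, 600, "DTT")
        with pytest.raises(ValueError):
            island_te_distances([_island_at("c", 9000, "g")], [te], [gene])

    def test_fixed_tss_offset_has_smaller_cv_than_random_te_offset(self, rng):
        """Islands planted at a constant distance from the TSS but a random
        distance from the TE edge: CV(TSS) < CV(TE edge), significantly."""
        genes, tes, islands = [], [], []
        for i in range(120):
            tss = 20000 * (i + 1)
            genes.append(GeneModel(f"g{i}", "c", tss, tss + 2000, "+"))
            center = tss - 500 - int(rng.integers(0, 100))  # near-fixed TSS offset
            te_start = center - int(rng.integers(300, 1800))
            te_end = center + int(rng.integers(300, 1800))
            tes.append(RepeatFeature("c", te_start, te_end, "DTT"))
            islands.append(_island_at("c", center - 50, f"g{i}"))
        _, cmp = island_te_distances(islands, tes, genes)
        assert cmp.tss_cv < cmp.te_edge_cv
        assert cmp.p_value < 1e-3
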