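"""DMS/DMR calling, low-methylation segmentation, DMV comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from methylchrom import segments as sg
from methylchrom.methylome import MethylomeSample


def sample_from_counts(pos, m, h, ncr=0.0, context="CG"):
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.asarray(pos),
            "strand": "+",
            "context": context,
            "m": np.asarray(m),
            "h": np.asarray(h),
        }
    )
    return MethylomeSample(sites=sites, ncr=ncr)


class TestCallDms:
    def test_identical_pooled_counts_never_significant(self):
        a = sample_from_counts([10, 20], [5, 8], [10, 10])
        out = sg.call_dms([a], [a], fdr=0.01)
        assert np.allclose(out["p"], 1.0)
        assert not out["significant"].any()

    def test_extreme_table_matches_exact_hypergeometric(self):
        # (m,h) = (0,30) vs (30,30): the one-sided tail is 1/C(60,30);
        # the two-sided minimum-likelihood p doubles it (symmetric table)
        a = sample_from_counts([10], [0], [30])
        b = sample_from_counts([10], [30], [30])
        out = sg.call_dms([a], [b])
        expect_one_sided = 1.0 / comb(60, 30, exact=True)
        assert out["p"].iloc[0] == pytest.approx(2 * expect_one_sided, rel=1e-6)
        # agrees with the independent scipy implementation
        _, scipy_p = stats.fisher_exact([[0, 30], [30, 0]])
        assert out["p"].iloc[0] == pytest.approx(scipy_p, rel=1e-6)
        assert bool(out["significant"].iloc[0])

    def test_replicates_are_pooled_within_group(self):
        a1 = sample_from_counts([10], [2], [10])
        a2 = sample_from_counts([10], [3], [10])
        b = sample_from_counts([10], [5], [20])
        out = sg.call_dms([a1, a2], [b])
        assert out["m_a"].iloc[0] == 5 and out["h_a"].iloc[0] == 20
        assert out["p"].iloc[0] == pytest.approx(1.0)  # identical proportions

    def test_site_covered_in_one_group_untested(self):
        a = sample_from_counts([10, 20], [5, 5], [10, 10])
        b = sample_from_counts([10], [5], [10])
        out = sg.call_dms([a], [b])
        assert np.isnan(out.loc[out["pos"] == 20, "p"]).all()

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(5)
        n = 3000
        pos = np.arange(n) * 50
        p_true = rng.uniform(0.3, 0.8, n)
        h = rng.poisson(60, n) + 1
        a = sample_from_counts(pos, rng.binomial(h, p_true), h)
        h2 = rng.poisson(60, n) + 1
        b = sample_from_counts(pos, rng.binomial(h2, p_true), h2)
        out = sg.call_dms([a], [b], fdr=0.01)
        assert out["significant"].mean() <= 0.01 + 3 / n


class TestSegmentDmrs:
    def _dms(self, pos, significant, direction="hypo", q=1e-6):
        n = len(pos)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "m_a": 30, "h_a": 40, "m_b": 5, "h_b": 40,
                "level_a": 75.0, "level_b": 12.5,
                "p": q, "q": q,
                "significant": significant,
                "direction": direction,
            }
        )

    def test_three_sites_within_gap_make_one_region(self):
        dms = self._dms([100, 400, 800], [True] * 3)
        out = sg.segment_dmrs(dms, max_gap=500, min_sites=3, site_width=1)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 100 and out.iloc[0]["end"] == 801
        assert out.iloc[0]["n_dms"] == 3

    def test_two_sites_insufficient(self):
        dms = self._dms([100, 400], [True] * 2)
        assert len(sg.segment_dmrs(dms)) == 0

    def test_long_gap_splits_runs(self):
        # 100,400,1000: gap 600 splits; neither run reaches 3 sites
        dms = self._dms([100, 400, 1000], [True] * 3)
        assert len(sg.segment_dmrs(dms, max_gap=500)) == 0

    def test_direction_split(self):
        dms = pd.concat(
            [
                self._dms([100, 200, 300], [True] * 3, "hypo"),
                self._dms([350, 450, 550], [True] * 3, "hyper"),
            ],
            ignore_index=True,
        )
        out = sg.segment_dmrs(dms)
        assert sorted(out["direction"]) == ["hyper", "hypo"]

    def test_region_levels_are_pooled_over_span(self):
        dms = self._dms([100, 200, 300], [True] * 3)
        out = sg.segment_dmrs(dms)
        assert out.iloc[0]["level_a"] == pytest.approx(75.0)
        assert out.iloc[0]["delta"] == pytest.approx(-62.5)


class TestFilterDmrs:
    def _candidates(self, **kw):
        base = {
            "chrom": "chr1", "start": 0, "end": 500, "n_dms": 4,
            "level_a": 70.0, "level_b": 30.0, "delta": -40.0,
            "q": 1e-6, "p_stouffer": 1e-8, "direction": "hypo",
        }
        base.update(kw)
        return pd.DataFrame([base])

    def test_strict_delta_threshold(self):
        assert len(sg.filter_dmrs(self._candidates(delta=-29.9))) == 0
        assert len(sg.filter_dmrs(self._candidates(delta=-30.0))) == 1

    def test_hypo_kept_when_dropping_hyper(self):
        cand = self._candidates(delta=-45.0, q=1e-6)
        assert len(sg.filter_dmrs(cand, drop_hyper=True)) == 1
        hyper = self._candidates(delta=45.0, direction="hyper")
        assert len(sg.filter_dmrs(hyper, drop_hyper=True)) == 0
        assert len(sg.filter_dmrs(hyper, drop_hyper=False)) == 1

    def test_fdr_threshold(self):
        assert len(sg.filter_dmrs(self._candidates(q=0.02), fdr=0.01)) == 0


class TestSegmentLowMethylation:
    def _sample(self, levels, spacing=60, h=100):
        pos = np.arange(len(levels)) * spacing + 10
        m = (np.asarray(levels) / 100.0 * h).astype(int)
        return sample_from_counts(pos, m, np.full(len(levels), h))

    def test_seven_zero_sites_form_segment(self):
        s = self._sample([0.0] * 7)
        out = sg.segment_low_methylation(s, m=0.3, n=7)
        assert len(out) == 1
        assert out.iloc[0]["n_cg"] == 7

    def test_six_sites_insufficient(self):
        s = self._sample([0.0] * 6)
        assert len(sg.segment_low_methylation(s, m=0.3, n=7)) == 0

    def test_alternating_levels_yield_nothing(self):
        s = self._sample([0.0, 100.0] * 12)
        assert len(sg.segment_low_methylation(s, m=0.3, n=7)) == 0

    def test_single_noisy_site_bridged_inside_low_region(self):
        levels = [0.0] * 6 + [60.0] + [0.0] * 6
        s = self._sample(levels)
        out = sg.segment_low_methylation(s, m=0.3, n=7)
        assert len(out) == 1
        assert out.iloc[0]["n_cg"] == 12
        assert out.iloc[0]["mean_mCG"] <= 30.0

    def test_umr_lmr_split_at_site_count(self):
        s = self._sample([0.0] * 35)
        out = sg.segment_low_methylation(s, m=0.3, n=7, umr_min_cg=30)
        assert out.iloc[0]["klass"] == "UMR"
        s2 = self._sample([0.0] * 20)
        out2 = sg.segment_low_methylation(s2, m=0.3, n=7, umr_min_cg=30)
        assert out2.iloc[0]["klass"] == "LMR"

    def test_zero_coverage_sites_ignored(self):
        s = self._sample([0.0] * 7)
        s.sites.loc[3, "h"] = 0
        s.sites.loc[3, "m"] = 0
        out = sg.segment_low_methylation(s, m=0.3, n=6)
        assert len(out) == 1


class TestCallDmvs:
    def _umrs(self, length, mean, klass="UMR"):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": 10_000, "end": 10_000 + length,
              "n_cg": 60, "mean_mCG": mean, "klass": klass}]
        )

    def test_length_threshold(self):
        assert len(sg.call_dmvs(self._umrs(4_999, 5.0))) == 0
        assert len(sg.call_dmvs(self._umrs(6_000, 14.9))) == 1

    def test_mean_threshold(self):
        assert len(sg.call_dmvs(self._umrs(6_000, 15.1))) == 0

    def test_pmd_mask_removes_overlapping(self):
        umrs = self._umrs(6_000, 5.0)
        pmd = pd.DataFrame([{"chrom": "chr1", "start": 12_000, "end": 13_000}])
        assert len(sg.call_dmvs(umrs, pmd_mask=pmd)) == 0


def brute_force_category(a, b):
    """Independent per-base decision table for the 6-way classification."""
    if b is None:
        return "cKO_unique"
    sa = set(range(a[0], a[1]))
    sb = set(range(b[0], b[1]))
    if not sa & sb:
        return "cKO_unique"
    if sa == sb:
        return "consistent"
    if sb < sa:
        return "expanded"
    if sa < sb:
        return "shrunken"
    return "overhang"


class TestCompareDmvSets:
    @pytest.mark.parametrize(
        "cko,ctrl,expected",
        [
            ((10_000, 20_000), (10_000, 20_000), "consistent"),
            ((10_000, 25_000), (12_000, 20_000), "expanded"),
            ((12_000, 20_000), (10_000, 25_000), "shrunken"),
            ((10_000, 20_000), (15_000, 25_000), "overhang"),
            ((10_000, 20_000), (30_000, 40_000), "cKO_unique"),
        ],
    )
    def test_topology_examples(self, cko, ctrl, expected):
        a = pd.DataFrame([{"chrom": "chr1", "start": cko[0], "end": cko[1]}])
        b = pd.DataFrame([{"chrom": "chr1", "start": ctrl[0], "end": ctrl[1]}])
        table, _ = sg.compare_dmv_sets(a, b)
        assert table[table["condition"] == "cKO"]["category"].iloc[0] == expected

    def test_classifier_equals_brute_force_on_random_pairs(self, rng):
        for _ in range(2000):
            s1, s2 = rng.integers(0, 500, 2)
            l1, l2 = rng.integers(1, 200, 2)
            got = sg._classify_pair(int(s1), int(s1 + l1), int(s2), int(s2 + l2))
            expect = brute_force_category((s1, s1 + l1), (s2, s2 + l2))
            assert got == expect

    def test_categories_exhaustive_and_counts_consistent(self, rng):
        # disjoint-within-set random valleys on a long axis
        def make(n, offset):
            starts = np.cumsum(rng.integers(50, 300, n)) + offset
            ends = starts + rng.integers(10, 45, n)
            return pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends})

        cko = make(30, 0)
        ctrl = make(30, 7)
        table, summary = sg.compare_dmv_sets(cko, ctrl)
        assert len(table) == 60
        assert set(table["category"]) <= set(sg.DMV_CATEGORIES)
        assert summary["count"].sum() == 60

    def test_overlapping_within_one_set_rejected(self):
        bad = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [100, 150]}
        )
        ok = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10}])
        with pytest.raises(ValueError):
            sg.compare_dmv_sets(bad, ok)

    def test_boundary_slack_relaxes_consistency(self):
        a = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 20_000}])
        b = pd.DataFrame([{"chrom": "chr1", "start": 10_050, "end": 19_980}])
        strict, _ = sg.compare_dmv_sets(a, b, slack=0)
        loose, _ = sg.compare_dmv_sets(a, b, slack=100)
        assert strict[strict["condition"] == "cKO"]["category"].iloc[0] != "consistent"
        assert loose[loose["condition"] == "cKO"]["category"].iloc[0] == "consistent"


class TestAnnotateAndSortDmvs:
    def _dmvs(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [10_000, 30_000, 50_000],
                "end": [20_000, 40_000, 60_000],
            }
        )

    def test_dm_overlap_sorts_first_all_else_equal(self):
        dmvs = self._dmvs()
        dm = pd.DataFrame([{"chrom": "chr1", "start": 32_000, "end": 33_000}])
        out = sg.annotate_and_sort_dmvs(dmvs, dm_regions=dm)
        assert out.iloc[0]["start"] == 30_000
        assert bool(out.iloc[0]["overlaps_dm"])

    def test_fraction_dm_matches_per_base(self, rng):
        dmvs = self._dmvs()
        dm = pd.DataFrame(
            {"chrom": "chr1", "start": [12_000, 15_000], "end": [13_000, 16_500]}
        )
        out = sg.annotate_and_sort_dmvs(dmvs, dm_regions=dm)
        covered = np.zeros(70_000, dtype=bool)
        for _, r in dm.iterrows():
            covered[r["start"]:r["end"]] = True
        row = out[out["start"] == 10_000].iloc[0]
        assert row["fraction_dm"] == pytest.approx(
            covered[10_000:20_000].sum() / 10_000
        )

    def test_valley_without_contained_gene_sorts_after(self):
        dmvs = self._dmvs()
        genes = pd.DataFrame(
            [{"chrom": "chr1", "start": 31_000, "end": 35_000,
              "log2fc": 0.5, "status": "up"}]
        )
        out = sg.annotate_and_sort_dmvs(dmvs, de_genes=genes)
        assert out.iloc[0]["start"] == 30_000
        assert out.iloc[0]["mean_gene_logfc"] == pytest.approx(0.5)
        assert np.isnan(out.iloc[1]["mean_gene_logfc"])
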