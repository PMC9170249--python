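"""Expression filtering/DE, gene-body methylation, integration statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylchrom import genes as gn
from methylchrom.methylome import MethylomeSample


def make_counts(rng, n_genes=200, n_samples=4, mu=None, disp=0.05):
    k = 1.0 / disp
    if mu is None:
        mu = rng.lognormal(5, 1, n_genes)
    mat = np.column_stack(
        [rng.negative_binomial(k, k / (k + mu)) for _ in range(n_samples)]
    )
    return pd.DataFrame(
        mat, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestFilterAndNormalize:
    def test_cpm_threshold_boundary(self):
        # libraries of ~1e6, so CPM ~= count: kept iff CPM > 2 in >= 2 samples
        big = 1_000_000
        counts = pd.DataFrame(
            {
                "s1": [3, big, 1],
                "s2": [3, big, 1],
                "s3": [1, big, 1],
                "s4": [1, big, 1],
            },
            index=["at_boundary", "big", "low"],
        )
        res = gn.filter_and_normalize(counts)
        assert "at_boundary" in res["counts"].index  # CPM ~3 in two samples
        assert "low" not in res["counts"].index

    def test_identical_samples_unit_factors(self, rng):
        counts = make_counts(rng, n_samples=1)
        counts = pd.concat([counts] * 4, axis=1)
        counts.columns = list("abcd")
        res = gn.filter_and_normalize(counts)
        assert np.allclose(res["factors"], 1.0)

    def test_doubling_a_library_leaves_normalized_cpm_invariant(self, rng):
        counts = make_counts(rng)
        res1 = gn.filter_and_normalize(counts)
        doubled = counts.copy()
        doubled["s0"] = doubled["s0"] * 2
        res2 = gn.filter_and_normalize(doubled)
        shared = res1["cpm"].index.intersection(res2["cpm"].index)
        assert np.allclose(
            res1["cpm"].loc[shared, "s0"], res2["cpm"].loc[shared, "s0"], rtol=0.02
        )

    def test_all_zero_sample_rejected(self, rng):
        counts = make_counts(rng)
        counts["s0"] = 0
        with pytest.raises(ValueError):
            gn.filter_and_normalize(counts)


class TestCallDe:
    def test_identical_groups_yield_nothing(self, rng):
        counts = make_counts(rng, n_samples=2)
        counts = pd.concat([counts, counts], axis=1)
        counts.columns = list("abcd")
        out = gn.call_de(counts, np.array(["x", "x", "y", "y"]))
        assert (out["status"] == "non-DE").all()

    def test_null_simulation_controls_fdr(self):
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = make_counts(rng, n_genes=250)
            out = gn.call_de(counts, np.array(["x", "x", "y", "y"]), fdr=0.05)
            rates.append((out["status"] != "non-DE").mean())
        assert np.mean(rates) <= 0.10  # <= 2x nominal over the null

    def test_power_on_planted_fold_changes(self):
        # BCV 0.1 (phi 0.01, typical for inbred-mouse replicates) at the
        # expression depth the generator emulates; normalization first, as
        # in the pipeline, so composition bias from DE genes is removed
        rng = np.random.default_rng(11)
        n = 300
        mu = rng.lognormal(np.log(500), 1.0, n)
        k = 1.0 / 0.01
        a = np.column_stack([rng.negative_binomial(k, k / (k + mu))] * 1
                            + [rng.negative_binomial(k, k / (k + mu))])
        mu_b = mu.copy()
        mu_b[:50] *= 2.0  # planted FC 2
        b = np.column_stack([rng.negative_binomial(k, k / (k + mu_b))] * 1
                            + [rng.negative_binomial(k, k / (k + mu_b))])
        counts = pd.DataFrame(
            np.column_stack([a, b]), index=[f"g{i}" for i in range(n)],
            columns=list("abcd"),
        )
        norm = gn.filter_and_normalize(counts)
        out = gn.call_de(
            norm["counts"], np.array(["x", "x", "y", "y"]),
            effective_lib_sizes=norm["effective_lib_sizes"],
        )
        planted = [g for g in out.index if int(g[1:]) < 50]
        power = (out.loc[planted, "status"] == "up").mean()
        assert power >= 0.7
        null = [g for g in out.index if int(g[1:]) >= 50]
        assert (out.loc[null, "status"] != "non-DE").mean() <= 0.10

    def test_status_is_pure_function_of_q_and_fc(self, rng):
        counts = make_counts(rng)
        out = gn.call_de(counts, np.array(["x", "x", "y", "y"]),
                         fdr=0.05, min_fc=1.2)
        rederived = np.where(
            (out["q"] < 0.05) & (out["log2fc"].abs() > np.log2(1.2)),
            np.where(out["log2fc"] > 0, "up", "down"),
            "non-DE",
        )
        assert (out["status"].to_numpy() == rederived).all()


def site_sample(pos, m, h, context="CH", chrom="chr1"):
    sites = pd.DataFrame(
        {
            "chrom": chrom, "pos": np.asarray(pos), "strand": "+",
            "context": context, "m": np.asarray(m), "h": np.asarray(h),
        }
    )
    return MethylomeSample(sites=sites, ncr=0.0)


class TestGeneBodyLevel:
    def _gene(self, strand="+"):
        return pd.Series(
            {"gene_id": "g1", "chrom": "chr1", "strand": strand,
             "tss": 100 if strand == "+" else 400,
             "tes": 400 if strand == "+" else 100}
        )

    def test_pooled_arithmetic(self):
        s = site_sample([150, 300], m=[5, 15], h=[10, 20])
        # 100*20/30
        assert gn.gene_body_level(self._gene(), s, "CH") == pytest.approx(100 * 20 / 30)

    def test_strand_flip_invariant(self):
        s = site_sample([150, 300], m=[5, 15], h=[10, 20])
        assert gn.gene_body_level(self._gene("+"), s, "CH") == pytest.approx(
            gn.gene_body_level(self._gene("-"), s, "CH")
        )

    def test_uncovered_gene_is_missing(self):
        s = site_sample([5_000], m=[1], h=[2])
        assert np.isnan(gn.gene_body_level(self._gene(), s, "CH"))

    def test_identical_samples_zero_delta(self):
        s = site_sample([150, 300], m=[5, 15], h=[10, 20])
        genes = pd.DataFrame([self._gene()])
        d = gn.delta_gene_body(genes, s, s, "CH")
        assert d.iloc[0] == pytest.approx(0.0)


class TestFlankProfile:
    def _genes(self, n=20, strand="+"):
        tss = np.arange(n) * 50_000 + 120_000
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "chr1", "strand": strand,
                "tss": tss, "tes": tss + 5_000 if strand == "+" else tss - 5_000,
            }
        )

    def test_uniform_methylome_gives_flat_profile(self, rng):
        genes = self._genes(5)
        pos = np.sort(rng.choice(1_000_000, 20_000, replace=False))
        s = site_sample(pos, m=np.full(20_000, 3), h=np.full(20_000, 10))
        prof = gn.flank_profile(genes, s, "CH", flank=10_000, bin_size=1_000)
        covered = prof.dropna(subset=["mean"])
        assert np.allclose(covered["mean"], 30.0, atol=1e-9)

    def test_gene_body_elevation_lands_downstream_of_tss(self, rng):
        genes = self._genes(10)
        pos = np.sort(rng.choice(1_000_000, 40_000, replace=False))
        m = np.zeros(len(pos), dtype=int)
        h = np.full(len(pos), 10)
        inside = np.zeros(len(pos), dtype=bool)
        for _, g in genes.iterrows():
            inside |= (pos >= g["tss"]) & (pos < g["tes"])
        m[inside] = 8
        s = site_sample(pos, m, h)
        prof = gn.flank_profile(genes, s, "CH", flank=10_000, bin_size=1_000)
        up = prof[prof["offset"] < -1_000]["mean"].mean()
        down = prof[(prof["offset"] >= 0) & (prof["offset"] < 4_000)]["mean"].mean()
        assert down > up + 50

    def test_minus_strand_orientation(self, rng):
        # for minus-strand genes the body lies at negative genomic offsets
        genes = self._genes(10, strand="-")
        pos = np.sort(rng.choice(1_000_000, 40_000, replace=False))
        m = np.zeros(len(pos), dtype=int)
        h = np.full(len(pos), 10)
        inside = np.zeros(len(pos), dtype=bool)
        for _, g in genes.iterrows():
            inside |= (pos >= g["tes"]) & (pos < g["tss"])
        m[inside] = 8
        s = site_sample(pos, m, h)
        prof = gn.flank_profile(genes, s, "CH", flank=10_000, bin_size=1_000)
        down = prof[(prof["offset"] >= 0) & (prof["offset"] < 4_000)]["mean"].mean()
        up = prof[prof["offset"] < -1_000]["mean"].mean()
        assert down > up + 50  # downstream of TSS in gene orientation

    def test_single_gene_ci_degenerate(self, rng):
        genes = self._genes(1)
        pos = np.sort(rng.choice(1_000_000, 5_000, replace=False))
        s = site_sample(pos, m=np.full(5_000, 3), h=np.full(5_000, 10))
        prof = gn.flank_profile(genes, s, "CH", flank=5_000, bin_size=1_000)
        assert prof["ci_low"].isna().all()


class TestDecileFcCurve:
    def test_bins_partition_exactly(self, rng):
        n = 107
        delta = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        fc = pd.Series(rng.normal(size=n), index=delta.index)
        curve = gn.decile_fc_curve(delta, fc)
        assert curve["n"].sum() == n
        assert curve["n"].max() - curve["n"].min() <= 1

    def test_25_genes_give_deterministic_partition(self, rng):
        idx = [f"g{i:02d}" for i in range(25)]
        delta = pd.Series(rng.normal(size=25), index=idx)
        fc = pd.Series(rng.normal(size=25), index=idx)
        curve = gn.decile_fc_curve(delta, fc)
        assert curve["n"].tolist() == [3, 3, 3, 3, 3, 2, 2, 2, 2, 2]

    def test_planted_negative_coupling_gives_decreasing_curve(self, rng):
        n = 2_000
        delta = pd.Series(rng.uniform(-4, 0, n), index=[f"g{i}" for i in range(n)])
        fc = -0.2 * delta + rng.normal(0, 0.1, n)
        curve = gn.decile_fc_curve(delta, pd.Series(fc.to_numpy(), index=delta.index))
        r = stats.spearmanr(curve["bin"], curve["logfc_mean"])[0]
        assert r == pytest.approx(-1.0)

    def test_independent_inputs_are_flat(self, rng):
        n = 2_000
        delta = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        fc = pd.Series(rng.normal(0, 0.1, n), index=delta.index)
        curve = gn.decile_fc_curve(delta, fc)
        spread = curve["logfc_mean"].max() - curve["logfc_mean"].min()
        assert spread < 5 * curve["logfc_sem"].mean()

    def test_too_few_genes_rejected(self):
        s = pd.Series([1.0] * 5)
        with pytest.raises(ValueError):
            gn.decile_fc_curve(s, s)


class TestExplainableVariance:
    def test_identical_replicates_give_unit_ceiling(self, rng):
        idx = [f"g{i}" for i in range(100)]
        fc = pd.Series(rng.normal(size=100), index=idx)
        delta = pd.Series(rng.normal(size=100), index=idx)
        res = gn.explainable_variance(fc, fc, delta)
        assert res["R2_replicate_ceiling"] == pytest.approx(1.0)

    def test_permuted_delta_explains_nothing(self, rng):
        idx = [f"g{i}" for i in range(2_000)]
        fc1 = pd.Series(rng.normal(size=2_000), index=idx)
        fc2 = fc1 + rng.normal(0, 0.5, 2_000)
        delta = pd.Series(rng.permutation(fc1.to_numpy()), index=idx)
        res = gn.explainable_variance(fc1, fc2, delta)
        assert res["R2_mc"] < 0.01

    def test_noiseless_linear_coupling_saturates_ceiling(self, rng):
        idx = [f"g{i}" for i in range(500)]
        delta = pd.Series(rng.normal(size=500), index=idx)
        fc = -0.3 * delta
        res = gn.explainable_variance(fc, fc, delta)
        assert res["R2_mc"] == pytest.approx(res["R2_replicate_ceiling"])
        assert res["R2_mc"] == pytest.approx(1.0)

    def test_r2_mc_bounded_by_ceiling_under_model(self, rng):
        # the covariate is itself a noisy estimate (as gene-body delta-mC
        # is), so the reproducible fraction bounds what it can explain
        idx = [f"g{i}" for i in range(3_000)]
        signal = pd.Series(rng.normal(size=3_000), index=idx)
        delta = signal + rng.normal(0, 1.0, 3_000)
        fc1 = signal + rng.normal(0, 0.5, 3_000)
        fc2 = signal + rng.normal(0, 0.5, 3_000)
        res = gn.explainable_variance(fc1, fc2, delta)
        assert res["R2_mc"] <= res["R2_replicate_ceiling"] + 0.02


class TestMatchExpressionControls:
    def test_exact_duplicates_give_zero_distance_sd(self, rng):
        tpm = rng.lognormal(2, 1, 50)
        targets = pd.Series(tpm, index=[f"t{i}" for i in range(50)])
        pool = pd.Series(
            np.concatenate([tpm, rng.lognormal(2, 1, 200)]),
            index=[f"p{i}" for i in range(250)],
        )
        matched = gn.match_expression_controls(targets, pool)
        assert matched.attrs["distance_sd"] <= 1e-6 + 0.01

    def test_infeasible_match_reports_achieved_sd(self, rng):
        targets = pd.Series([1.0, 10_000.0], index=["t1", "t2"])
        pool = pd.Series([40.0, 55.0, 70.0], index=["p1", "p2", "p3"])
        with pytest.raises(ValueError, match="sd"):
            gn.match_expression_controls(targets, pool, max_sd_distance=1e-6)

    def test_matched_distribution_close_to_targets(self, rng):
        targets = pd.Series(
            rng.lognormal(3, 0.5, 80), index=[f"t{i}" for i in range(80)]
        )
        pool = pd.Series(
            rng.lognormal(3, 0.8, 2_000), index=[f"p{i}" for i in range(2_000)]
        )
        matched = gn.match_expression_controls(targets, pool, max_sd_distance=0.05)
        ctrl_tpm = pool.loc[matched["control"]]
        p = stats.ks_2samp(np.log(targets), np.log(ctrl_tpm)).pvalue
        assert p > 0.05

    def test_overlapping_sets_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            gn.match_expression_controls(s, s)
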