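"""Tests for survival analysis, rankings, GSEA, enrichment, and formulas."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import gsea_es_bruteforce, hypergeom_upper_tail, km_by_hand
from lncarray import downstream as ds
from lncarray.types import ExpressionDataset


# ---------------------------------------------------------------------------
# grouping


class TestMedianDichotomize:
    def test_even_split(self):
        groups = ds.median_dichotomize([1, 2, 3, 4])
        assert list(groups) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        groups = ds.median_dichotomize([1, 2, 2, 3])
        assert list(groups) == ["low", "low", "low", "high"]

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        perm = rng.permutation(20)
        g1 = ds.median_dichotomize(x)
        g2 = ds.median_dichotomize(x[perm])
        assert list(g1[perm]) == list(g2)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ds.median_dichotomize([2.0] * 6)


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        km = ds.kaplan_meier([1, 2, 3], [0, 0, 0])
        assert km.empty  # no event rows; implicit S = 1 throughout

    def test_two_events_by_hand(self):
        km = ds.kaplan_meier([1.0, 2.0], [1, 1])
        assert list(km["survival"]) == pytest.approx([0.5, 0.0])

    def test_duplication_invariance(self):
        t = [1.0, 3.0, 4.0, 7.0]
        e = [1, 0, 1, 1]
        a = ds.kaplan_meier(t, e)
        b = ds.kaplan_meier(t * 2, e * 2)
        np.testing.assert_allclose(a["survival"], b["survival"])

    def test_matches_hand_oracle_with_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=12).round(2)
        e = rng.integers(0, 2, size=12)
        e[0] = 1
        km = ds.kaplan_meier(t, e)
        oracle = km_by_hand(list(t), list(e))
        np.testing.assert_allclose(km["survival"], [s for _, s in oracle])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=30)
        e = rng.integers(0, 2, size=30)
        e[:3] = 1
        km = ds.kaplan_meier(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            assert kmf.predict(row["time"]) == pytest.approx(row["survival"])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ds.kaplan_meier([-1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# log-rank


class TestLogrank:
    def test_identical_groups_no_signal(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, p = ds.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_record_hand_computation(self):
        # events at t=1 (A) and t=2 (B); B censored at 3, A at 4
        # t=1: n=4, n_A=2, d=1, d_A=1 -> O-E = 1 - 1/2, V = (1/2)(1/2)
        # t=2: n=3, n_A=1, d=1, d_A=0 -> O-E = 0 - 1/3, V = (1/3)(2/3)
        # sum O-E = 1/6, V = 1/4 + 2/9 = 17/36 -> chi2 = (1/36)/(17/36)...
        t = [1.0, 4.0, 2.0, 3.0]
        e = [1, 0, 1, 0]
        g = ["A", "A", "B", "B"]
        chi2, p = ds.logrank_test(t, e, g)
        o_minus_e = (1 - 2 / 4) + (0 - 1 / 3)
        v = (2 / 4) * (2 / 4) + (1 / 3) * (2 / 3)
        assert chi2 == pytest.approx(o_minus_e**2 / v)
        assert p == pytest.approx(float(stats.chi2.sf(chi2, 1)))

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[:5] = 1
        g = np.array(["a"] * 20 + ["b"] * 20)
        chi2, p = ds.logrank_test(t, e, g)
        ref = lifelines_stats.logrank_test(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            ds.logrank_test([1.0, 2.0], [0, 0], ["a", "b"])


# ---------------------------------------------------------------------------
# Cox


class TestCox:
    def _cohort(self, n=80, beta=np.log(2), seed=4):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(beta * g)))
        e = np.ones(n, dtype=int)
        cens = rng.uniform(0, 60, size=n)
        e = (t <= cens).astype(int)
        t = np.minimum(t, cens)
        return t, e, g

    def test_matches_lifelines_without_ties(self):
        lifelines = pytest.importorskip("lifelines")
        t, e, g = self._cohort()
        fit = ds.cox_univariate(t, e, g)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "g": g}), "t", "e"
        )
        assert fit.beta == pytest.approx(cph.params_["g"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["g"], abs=1e-6)
        assert fit.converged

    def test_label_swap_negates_beta(self):
        t, e, g = self._cohort()
        a = ds.cox_univariate(t, e, g)
        b = ds.cox_univariate(t, e, 1 - g)
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)

    def test_string_groups_accepted(self):
        t, e, g = self._cohort()
        labels = np.where(g == 1, "high", "low")
        fit = ds.cox_univariate(t, e, labels)
        ref = ds.cox_univariate(t, e, g)
        assert fit.beta == pytest.approx(ref.beta)

    def test_ci_brackets_hr(self):
        t, e, g = self._cohort()
        fit = ds.cox_univariate(t, e, g)
        assert fit.ci_low <= fit.hr <= fit.ci_high
        assert fit.hr > 0

    def test_null_beta_near_zero_on_average(self):
        betas = []
        for s in range(40):
            t, e, g = self._cohort(beta=0.0, seed=100 + s)
            betas.append(ds.cox_univariate(t, e, g).beta)
        assert abs(np.mean(betas)) < 0.1

    def test_separation_reported_not_converged(self):
        # all events in one group, none in the other: monotone likelihood
        t = np.concatenate([np.linspace(1, 2, 10), np.linspace(10, 20, 10)])
        e = np.array([1] * 10 + [0] * 10)
        g = np.array([1] * 10 + [0] * 10)
        fit = ds.cox_univariate(t, e, g)
        assert not fit.converged

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            ds.cox_univariate([1.0, 2.0], [0, 0], [0, 1])


# ---------------------------------------------------------------------------
# rankings


def _make_dataset(values: np.ndarray, feature_ids, labels=None):
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    if labels is None:
        labels = ["tumor"] * (n // 2) + ["normal"] * (n - n // 2)
    return ExpressionDataset(
        dataset_id="d",
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        labels=pd.Series(labels, index=samples),
        role="validation",
    )


class TestCorrelationRanking:
    def test_perfect_positive_and_negative(self):
        rng = np.random.default_rng(5)
        target = rng.normal(size=12)
        mat = np.vstack([target, -target, rng.normal(size=12)])
        dset = _make_dataset(np.vstack([mat, target]), ["pos", "neg", "noise", "T"])
        rk = ds.correlation_ranking(dset, "T")
        assert rk.iloc[0]["gene"] == "pos"
        assert rk.iloc[0]["score"] == pytest.approx(1.0)
        assert rk.iloc[-1]["gene"] == "neg"
        assert rk.iloc[-1]["score"] == pytest.approx(-1.0)
        assert "T" not in set(rk["gene"])

    def test_constant_gene_flagged_zero(self):
        rng = np.random.default_rng(6)
        target = rng.normal(size=10)
        mat = np.vstack([np.full(10, 3.0), target])
        dset = _make_dataset(mat, ["flat", "T"])
        rk = ds.correlation_ranking(dset, "T")
        row = rk[rk["gene"] == "flat"].iloc[0]
        assert row["score"] == 0.0 and row["constant"]

    def test_missing_target_rejected(self):
        dset = _make_dataset(np.zeros((2, 6)) + np.arange(6), ["a", "b"])
        with pytest.raises(KeyError):
            ds.correlation_ranking(dset, "nope")


class TestSignalToNoise:
    def test_hand_fixture(self):
        # mu = (2, 1), sd = (0.5, 0.5) -> (2-1)/(0.5+0.5) = 1.0, but the
        # 0.2*|mu| floor lifts sd_high to max(0.5, 0.4) = 0.5 -> still 1.0
        high = np.array([1.5, 2.0, 2.5, 2.0])
        low = np.array([0.5, 1.0, 1.5, 1.0])
        vals = pd.DataFrame([np.concatenate([high, low])], index=["g"])
        sd = high.std(ddof=1)
        rk = ds.signal_to_noise_ranking(vals, ["high"] * 4 + ["low"] * 4)
        expected = 1.0 / (max(sd, 0.4) + max(sd, 0.2))
        assert rk.iloc[0]["score"] == pytest.approx(expected)

    def test_equal_classes_score_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        vals = pd.DataFrame([np.concatenate([x, x])], index=["g"])
        rk = ds.signal_to_noise_ranking(vals, ["high"] * 3 + ["low"] * 3)
        assert rk.iloc[0]["score"] == pytest.approx(0.0)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(size=(20, 10)))
        labels = np.array(["high"] * 5 + ["low"] * 5)
        a = ds.signal_to_noise_ranking(vals, labels).set_index("gene")["score"]
        b = ds.signal_to_noise_ranking(vals, np.where(labels == "high", "low", "high")).set_index("gene")["score"]
        np.testing.assert_allclose(a.sort_index(), -b.sort_index())

    def test_small_class_rejected(self):
        vals = pd.DataFrame(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="3 samples"):
            ds.signal_to_noise_ranking(vals, ["high", "high", "low", "low"])


# ---------------------------------------------------------------------------
# GSEA


def _ranked(n=50, seed=8):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    return pd.DataFrame({"gene": [f"g{i}" for i in range(n)], "score": scores})


class TestEnrichmentScore:
    def test_top_gene_unweighted_es_one(self):
        ranked = _ranked(10)
        res = ds.gsea_enrichment_score(ranked, ["g0"], p_weight=0.0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_running_sum_terminates_at_zero(self):
        ranked = _ranked(40)
        for members in (["g0", "g5", "g39"], [f"g{i}" for i in range(40)]):
            res = ds.gsea_enrichment_score(ranked, members)
            if len(members) < 40:
                assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        ranked = _ranked(50)
        members = ["g2", "g11", "g17", "g30", "g48"]
        res = ds.gsea_enrichment_score(ranked, members)
        ref = gsea_es_bruteforce(
            list(ranked["gene"]), list(ranked["score"]), members, p_weight=1.0
        )
        assert res.es == pytest.approx(ref, abs=1e-12)

    def test_bottom_set_negative_es(self):
        ranked = _ranked(50)
        res = ds.gsea_enrichment_score(ranked, [f"g{i}" for i in range(45, 50)])
        assert res.es < 0
        assert set(res.leading_edge) <= {f"g{i}" for i in range(45, 50)}

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no overlap"):
            ds.gsea_enrichment_score(_ranked(10), ["absent"], set_name="S")


class TestGseaPermutation:
    def _dataset(self, seed=9, n_genes=60, shift_genes=10):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n_genes, 20))
        vals[:shift_genes, :10] += 2.0  # enriched in the 'high' class
        genes = [f"g{i}" for i in range(n_genes)]
        labels = ["high"] * 10 + ["low"] * 10
        return pd.DataFrame(vals, index=genes), labels

    def test_seed_determinism(self):
        vals, labels = self._dataset()
        kwargs = dict(n_perm=50, seed=3, positive_class="high")
        a = ds.gsea_permutation_test(vals, labels, ["g0", "g1", "g2"], **kwargs)
        b = ds.gsea_permutation_test(vals, labels, ["g0", "g1", "g2"], **kwargs)
        assert a.p_perm == b.p_perm
        assert a.es == b.es

    def test_planted_set_detected(self):
        vals, labels = self._dataset()
        res = ds.gsea_permutation_test(
            vals, labels, [f"g{i}" for i in range(10)], n_perm=200, seed=0,
            positive_class="high",
        )
        assert res.es > 0
        assert res.p_perm < 0.05
        assert res.nes > 1

    def test_gene_set_scheme_needs_ranking(self):
        with pytest.raises(ValueError, match="ranking"):
            ds.gsea_permutation_test(None, None, ["g1"], scheme="gene_set")

    def test_report_adjusts_across_sets(self):
        vals, labels = self._dataset()
        sets = {
            "planted": [f"g{i}" for i in range(10)],
            "null1": ["g20", "g25", "g30", "g35"],
            "null2": ["g40", "g45", "g50", "g55"],
        }
        rep = ds.gsea_report(vals, labels, sets, n_perm=100, seed=1, positive_class="high")
        assert set(rep["set_name"]) == set(sets)
        assert (rep["p_adj"] >= rep["p_perm"] - 1e-12).all()


# ---------------------------------------------------------------------------
# hypergeometric enrichment


class TestHypergeometricEnrichment:
    def test_hand_computed_tail(self):
        universe = [f"u{i}" for i in range(20)]
        gene_set = {"S": universe[:5]}
        query = universe[:4] + [universe[10]]
        out = ds.hypergeometric_enrichment(query, gene_set, universe)
        expected = hypergeom_upper_tail(4, 20, 5, 5)
        assert out.iloc[0]["p"] == pytest.approx(expected)
        assert expected == pytest.approx(76 / 15504)

    def test_no_overlap_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        out = ds.hypergeometric_enrichment(
            universe[5:], {"S": universe[:3]}, universe
        )
        row = out.iloc[0]
        assert row["k"] == 0
        # k=0 overlap cannot beat chance when K + n <= N
        assert row["p"] == pytest.approx(1.0) or row["p"] > 0.2

    def test_forced_overlap_gives_p_one(self):
        universe = [f"u{i}" for i in range(5)]
        out = ds.hypergeometric_enrichment(universe, {"S": universe}, universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ds.hypergeometric_enrichment(["x"], {"S": ["a"]}, ["a", "b"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ds.hypergeometric_enrichment([], {"S": ["a"]}, [])


# ---------------------------------------------------------------------------
# nearest TSS


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestNearestTss:
    def test_coincident_tss_distance_zero(self):
        lnc = _bed([("chr1", 1000, 2000, "L1", 0, "+")])
        tss = _bed([("chr1", 1000, 3000, "G1", 0, "+")])
        out = ds.distance_to_nearest_tss(lnc, tss)
        assert out.iloc[0]["distance"] == 0

    def test_upstream_negative_hundred(self):
        lnc = _bed([("chr1", 900, 950, "L1", 0, "+")])
        tss = _bed([("chr1", 1000, 1200, "G1", 0, "+")])
        out = ds.distance_to_nearest_tss(lnc, tss)
        assert out.iloc[0]["distance"] == -100

    def test_minus_strand_sign_convention(self):
        # coding gene on '-': TSS at end-1 = 1199; lnc TSS at 1300 is
        # upstream of the gene (beyond its 5' end) -> negative
        lnc = _bed([("chr1", 1300, 1350, "L1", 0, "+")])
        tss = _bed([("chr1", 1000, 1200, "G1", 0, "-")])
        out = ds.distance_to_nearest_tss(lnc, tss)
        assert out.iloc[0]["distance"] == -(1300 - 1199)

    def test_adding_farther_tss_never_changes_result(self):
        lnc = _bed([("chr1", 900, 950, "L1", 0, "+")])
        near = _bed([("chr1", 1000, 1200, "G1", 0, "+")])
        far = _bed(
            [("chr1", 1000, 1200, "G1", 0, "+"), ("chr1", 50_000, 51_000, "G2", 0, "+")]
        )
        a = ds.distance_to_nearest_tss(lnc, near)
        b = ds.distance_to_nearest_tss(lnc, far)
        assert a.iloc[0]["distance"] == b.iloc[0]["distance"]

    def test_missing_chromosome_flagged(self):
        lnc = _bed([("chr9", 900, 950, "L1", 0, "+")])
        tss = _bed([("chr1", 1000, 1200, "G1", 0, "+")])
        out = ds.distance_to_nearest_tss(lnc, tss)
        assert out.iloc[0]["no_tss_on_chrom"]
        assert np.isnan(out.iloc[0]["distance"])

    def test_tss_inside_coding_interval_zero(self):
        lnc = _bed([("chr1", 1100, 1150, "L1", 0, "+")])
        tss = _bed([("chr1", 1000, 1200, "G1", 0, "+")])
        out = ds.distance_to_nearest_tss(lnc, tss)
        assert out.iloc[0]["distance"] == 0


# ---------------------------------------------------------------------------
# utility formulas


class TestFormulas:
    def test_ddct_identity(self):
        assert ds.ddct_fold_change(20, 20, 20, 20) == pytest.approx(1.0)

    def test_ddct_doubling(self):
        # ddCt = -1 -> fold change 2
        assert ds.ddct_fold_change(19, 20, 20, 20) == pytest.approx(2.0)

    def test_ddct_arithmetic(self):
        assert ds.ddct_fold_change(20, 15, 24, 15) == pytest.approx(16.0)

    def test_ddct_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ds.ddct_fold_change(np.nan, 1, 1, 1)

    def test_volume_formula(self):
        assert ds.xenograft_volume(10, 10) == pytest.approx(500.0)
        assert ds.xenograft_volume(0, 5) == 0.0
        assert ds.xenograft_volume(5, 0) == 0.0

    def test_volume_negative_rejected(self):
        with pytest.raises(ValueError):
            ds.xenograft_volume(-1, 5)

    def test_group_comparison_identical_groups(self):
        v = [1.0, 2.0] * 3
        g = ["a", "a", "b", "b", "c", "c"]
        f, p = ds.group_comparison([1.0, 2.0, 1.0, 2.0, 1.0, 2.0], g)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_group_comparison_three_group_hand_f(self):
        # SSB = 16, SSW = 1.5 -> F = (16/2)/(1.5/3) = 16
        f, p = ds.group_comparison(
            [1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"]
        )
        assert f == pytest.approx(16.0)

    def test_two_group_equal_variance_t_squared_is_f(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [3.0, 4.0, 5.0, 6.0]
        t, _ = ds.group_comparison(x + y, ["a"] * 4 + ["b"] * 4)
        f, _ = stats.f_oneway(np.array(x), np.array(y))
        assert t**2 == pytest.approx(f)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            ds.group_comparison([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSurvivalReport:
    def test_planted_hazard_recovered_in_report(self, bundle):
        rep = ds.survival_report(bundle.survival)
        fit = rep["cox"]
        assert fit.converged
        assert fit.hr > 1.0  # planted log HR is positive
        assert rep["logrank_p"] < 0.2
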