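import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from gdtx import (
    BulkSample,
    GeneSignature,
    bulk_signature_score,
    cytolytic_score,
    km_curve,
    logrank_test,
    purity_filter,
    simulate_bulk_cohort,
    survival_pipeline,
    tertile_groups,
)
from gdtx.survival import group_covariate_compare


def _sample(sid, purity=0.65, time=100.0, event=1, **expr):
    return BulkSample(sid, expr or {"X": 1.0}, purity, time, event)


class TestPurityFilter:
    def test_boundaries_closed(self):
        samples = [_sample("a", purity=0.6), _sample("b", purity=0.7),
                   _sample("c", purity=0.59), _sample("d", purity=0.71)]
        kept = purity_filter(samples)
        assert [s.sample_id for s in kept] == ["a", "b"]

    def test_uniform_retention_fraction(self, rng):
        samples = [_sample(f"s{i}", purity=float(rng.uniform()))
                   for i in range(1000)]
        frac = len(purity_filter(samples)) / 1000
        assert abs(frac - 0.10) < 0.03  # ~3 sigma binomial band

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            purity_filter([], lo=0.7, hi=0.6)


class TestBulkSignatureScore:
    def test_single_gene_is_its_zscore(self):
        samples = [_sample(f"s{i}", X=float(v)) for i, v in enumerate([1, 2, 6])]
        sig = GeneSignature("s", {"X": 1.0}, {})
        sc = bulk_signature_score(samples, sig)
        x = np.array([1.0, 2.0, 6.0])
        z = (x - x.mean()) / x.std()
        assert np.allclose(sc.to_numpy(), z)

    def test_weight_normalization(self, rng):
        samples = [
            _sample(f"s{i}", A=float(rng.uniform(1, 9)),
                    B=float(rng.uniform(1, 9)))
            for i in range(20)
        ]
        s1 = bulk_signature_score(samples, GeneSignature("s", {"A": 2.0}, {"B": -1.0}))
        s2 = bulk_signature_score(samples, GeneSignature("s", {"A": 4.0}, {"B": -2.0}))
        assert np.allclose(s1, s2)  # invariant to overall weight scale

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.uniform(1, 9, 30)
        samples = [_sample(f"s{i}", A=float(v)) for i, v in enumerate(vals)]
        scaled = [_sample(f"s{i}", A=float(5 * v + 100)) for i, v in enumerate(vals)]
        sig = GeneSignature("s", {"A": 1.0}, {})
        assert np.allclose(
            bulk_signature_score(samples, sig),
            bulk_signature_score(scaled, sig),
        )

    def test_recovers_planted_latent_score(self):
        sig = GeneSignature(
            "s", {f"U{i}": 1.0 for i in range(25)},
            {f"D{i}": -1.0 for i in range(25)},
        )
        samples, truth = simulate_bulk_cohort(300, sig, beta=0.0, seed=3)
        sc = bulk_signature_score(samples, sig)
        z = np.array([truth.signature_score_true[s.sample_id] for s in samples])
        assert np.corrcoef(sc.to_numpy(), z)[0, 1] > 0.9

    def test_no_gene_present_errors(self):
        with pytest.raises(ValueError):
            bulk_signature_score([_sample("a")], GeneSignature("s", {"NOPE": 1.0}, {}))


class TestCytolyticScore:
    def test_closed_forms(self):
        s = _sample("a", PRF1=4.0, GZMA=9.0)
        assert cytolytic_score([s], offset=0.0)["a"] == pytest.approx(6.0)
        s2 = _sample("b", PRF1=3.0, GZMA=3.0)
        assert cytolytic_score([s2], offset=0.0)["b"] == pytest.approx(3.0)

    def test_offset_rescues_zero(self):
        s = _sample("a", PRF1=0.0, GZMA=100.0)
        got = cytolytic_score([s], offset=0.01)["a"]
        assert got == pytest.approx(np.sqrt(0.01 * 100.01))

    def test_missing_gene(self):
        with pytest.raises(ValueError, match="GZMA"):
            cytolytic_score([_sample("a", PRF1=1.0)])


class TestTertileGroups:
    def test_nine_distinct(self):
        st = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        low, high = tertile_groups(st)
        assert low == ["s0", "s1", "s2"] and high == ["s6", "s7", "s8"]

    def test_191_gives_63_63(self, rng):
        st = pd.Series(rng.normal(size=191), index=[f"s{i:03d}" for i in range(191)])
        low, high = tertile_groups(st)
        assert len(low) == 63 and len(high) == 63
        assert not set(low) & set(high)

    def test_all_ties_split_by_id(self):
        st = pd.Series(np.zeros(6), index=list("fedcba"))
        low, high = tertile_groups(st)
        assert low == ["a", "b"] and high == ["e", "f"]

    def test_too_few(self):
        with pytest.raises(ValueError):
            tertile_groups(pd.Series([1.0, 2.0], index=["a", "b"]))


class TestKMCurve:
    def test_all_events_closed_form(self):
        km = km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_flat(self):
        km = km_curve([1, 2, 3], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(10.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, 40).round(1) + 0.1
        km = km_curve(times, np.ones(40, dtype=int))
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0], [1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lifelines_with_ties_and_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        times = rng.integers(1, 15, n).astype(float)  # heavy ties
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        km = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.event_times, km.survival):
            ref = float(kmf.survival_function_at_times(t).iloc[0])
            assert abs(s - ref) < 1e-12


def perm_logrank_p(g1, g2, n_perm=2000, seed=0):
    """Permutation null for the log-rank statistic by label shuffling."""
    rng = np.random.default_rng(seed)
    t = np.concatenate([g1[0], g2[0]])
    e = np.concatenate([g1[1], g2[1]])
    n1 = len(g1[0])
    obs = logrank_test(g1, g2).chi2
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(t))
        chi = logrank_test((t[idx[:n1]], e[idx[:n1]]),
                           (t[idx[n1:]], e[idx[n1:]])).chi2
        hits += chi >= obs - 1e-12
    return hits / n_perm


class TestLogRank:
    def test_identical_groups(self):
        g = ([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
        res = logrank_test(g, g)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        g1 = (rng.exponential(10, 30), rng.integers(0, 2, 30))
        g2 = (rng.exponential(5, 25), rng.integers(0, 2, 25))
        if g1[1].sum() + g2[1].sum() == 0:
            g1[1][0] = 1
        r12 = logrank_test(g1, g2)
        r21 = logrank_test(g2, g1)
        assert r12.chi2 == pytest.approx(r21.chi2, abs=1e-12)
        assert r12.p == pytest.approx(r21.p, abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(([1.0], [0]), ([2.0], [0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        g1 = (rng.integers(1, 20, 30).astype(float), rng.integers(0, 2, 30))
        g2 = (rng.integers(1, 20, 35).astype(float), rng.integers(0, 2, 35))
        if g1[1].sum() + g2[1].sum() == 0:
            g1[1][0] = 1
        mine = logrank_test(g1, g2)
        ref = ll_logrank(g1[0], g2[0], event_observed_A=g1[1],
                         event_observed_B=g2[1])
        assert mine.chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.p_value, abs=1e-10)

    def test_agrees_with_permutation_null(self):
        rng = np.random.default_rng(4)
        g1 = (rng.exponential(10, 25).round(1) + 0.1, rng.integers(0, 2, 25))
        g2 = (rng.exponential(14, 25).round(1) + 0.1, rng.integers(0, 2, 25))
        p_chi = logrank_test(g1, g2).p
        p_perm = perm_logrank_p(g1, g2, n_perm=2000, seed=1)
        assert abs(p_chi - p_perm) < 0.05


class TestSurvivalPipeline:
    def _signature(self, n=25):
        return GeneSignature(
            "sig", {f"U{i}": 1.0 for i in range(n)},
            {f"D{i}": -1.0 for i in range(n)},
        )

    def test_protective_effect_detected(self):
        sig = self._signature()
        samples, _ = simulate_bulk_cohort(300, sig, beta=-0.8, seed=7)
        res = survival_pipeline(samples, [sig])["sig"]
        assert res.logrank.p < 0.01
        # high-score group dominates at median follow-up
        t_med = np.median([s.time for s in samples])
        assert res.km_high.survival_at(t_med) > res.km_low.survival_at(t_med)

    def test_tertile_sizes_from_filtered_cohort(self):
        sig = self._signature()
        samples, _ = simulate_bulk_cohort(300, sig, beta=0.0, seed=8)
        res = survival_pipeline(samples, [sig])["sig"]
        assert res.logrank.n1 == res.logrank.n2 == 100

    def test_too_few_samples_after_filter(self):
        sig = self._signature()
        samples, _ = simulate_bulk_cohort(
            50, sig, beta=0.0, purity_range=(0.1, 0.2), seed=9
        )
        with pytest.raises(ValueError, match="purity window"):
            survival_pipeline(samples, [sig])


class TestGroupCovariateCompare:
    def test_planted_shift_detected_and_null_flat(self, rng):
        samples = []
        for i in range(60):
            shift = 2.0 if i < 30 else 0.0
            samples.append(_sample(
                f"s{i}", CD8A=float(rng.normal(5 + shift, 1)),
                CD4=float(rng.normal(5, 1)),
            ))
        groups = ([f"s{i}" for i in range(30)], [f"s{i}" for i in range(30, 60)])
        tab = group_covariate_compare(samples, groups, ["CD8A", "CD4"]).set_index(
            "feature"
        )
        assert tab.loc["CD8A", "p"] < 1e-4
        assert tab.loc["CD4", "p"] > 0.01

    def test_empty_feature_list(self):
        samples = [_sample("a"), _sample("b")]
        tab = group_covariate_compare(samples, (["a"], ["b"]), [])
        assert len(tab) == 0
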