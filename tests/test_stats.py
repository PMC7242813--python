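"""Paired battery: t, Cohen's d, Shapiro gate, exact Wilcoxon, Hotelling."""

import itertools

import numpy as np
import pytest
from scipy import stats as sst

from aplysia_swallow.core import PairedAnimalTable
from aplysia_swallow import reference_data as ref
from aplysia_swallow.stats import (analyze_battery, cohens_d, gated_paired_test,
                                   hotelling_f, hotelling_t2_paired, linregress_r2,
                                   paired_t_one_tailed, posthoc_bonferroni,
                                   shapiro_wilk, wilcoxon_signed_rank_exact)


def table(diffs, base=10.0):
    rows = [(str(i), base, base + d, 5, 5) for i, d in enumerate(diffs)]
    return PairedAnimalTable.from_rows("m", rows)


def oracle_wilcoxon(diffs, direction="greater"):
    """Brute-force enumeration of all sign assignments, midranks on ties."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sst.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    count = total = 0
    for signs in itertools.product([False, True], repeat=len(d)):
        w_perm = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if (w_perm >= w) if direction == "greater" else (w_perm <= w):
            count += 1
    return w, count / total


class TestPairedT:
    def test_all_zero_differences(self):
        rep = paired_t_one_tailed(table([0.0] * 5))
        assert rep.statistic == 0.0 and rep.p == pytest.approx(0.5)

    def test_published_cycle_time_statistic(self):
        rep = paired_t_one_tailed(ref.behavioral_durations()["total cycle time"])
        assert rep.statistic == pytest.approx(4.078, rel=0.01)
        assert rep.df == 4
        assert rep.p < 0.05 and rep.one_tailed

    def test_zero_variance_nonzero_mean_boundary_p(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = paired_t_one_tailed(table([1.0] * 4))
        assert rep.p == 0.0


class TestCohensD:
    @pytest.mark.parametrize("measure,expected", [
        ("total cycle time", 2.45), ("inward movement duration", 2.15),
        ("between inward movements duration", 0.79)])
    def test_published_behavioral_effect_sizes(self, measure, expected):
        assert cohens_d(ref.behavioral_durations()[measure]) == pytest.approx(
            expected, abs=0.01)

    @pytest.mark.parametrize("measure,expected", [
        ("B8a/b duration", 3.13), ("B3/B6/B9 duration", 5.16), ("B4/B5 duration", 0.70)])
    def test_published_duration_effect_sizes(self, measure, expected):
        assert cohens_d(ref.burst_durations()[measure]) == pytest.approx(
            expected, rel=0.011)

    def test_identical_conditions_zero(self):
        t = PairedAnimalTable.from_rows("m", [("1", 1.0, 1.0, 2, 2),
                                              ("2", 2.0, 2.0, 2, 2),
                                              ("3", 3.0, 3.0, 2, 2)])
        assert cohens_d(t) == 0.0


class TestShapiroGate:
    def test_published_violation_routes_to_wilcoxon(self):
        t = ref.burst_frequencies()["B4/B5 frequency"]
        w, p = shapiro_wilk(t)
        assert w == pytest.approx(0.74, abs=0.005)
        assert p == pytest.approx(0.025, abs=0.001)
        rep = gated_paired_test(t)
        assert "wilcoxon" in rep.test

    def test_near_normal_null_rejection_rate(self):
        rng = np.random.default_rng(8)
        hits = sum(shapiro_wilk(rng.normal(size=5))[1] < 0.05 for _ in range(500))
        assert hits / 500 == pytest.approx(0.05, abs=0.03)

    def test_smallest_symmetric_sample(self):
        w, p = shapiro_wilk(np.array([-1.0, 0.0, 1.0]))
        assert 0.0 < w <= 1.0 and 0.0 <= p <= 1.0


class TestWilcoxonExact:
    def test_published_b4b5_frequency_example(self):
        diffs = np.array([-3.72, 1.84, 3.44, 3.34, 3.88])
        rep = wilcoxon_signed_rank_exact(diffs)
        assert rep.statistic == 11.0
        assert rep.p == pytest.approx(7 / 32)

    def test_all_positive_extreme(self):
        rep = wilcoxon_signed_rank_exact(np.array([0.5, 1.0, 2.0, 3.0, 4.0]))
        assert rep.statistic == 15.0 and rep.p == pytest.approx(1 / 32)

    def test_matches_enumeration_oracle_random_samples(self, rng):
        for _ in range(25):
            n = rng.integers(3, 11)
            d = np.round(rng.normal(scale=2.0, size=n), 1)
            d = d[d != 0]
            if len(d) < 3:
                continue
            rep = wilcoxon_signed_rank_exact(d)
            w, p = oracle_wilcoxon(d)
            assert rep.statistic == pytest.approx(w)
            assert rep.p == pytest.approx(p)

    def test_zero_differences_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero differences"):
            rep = wilcoxon_signed_rank_exact(np.array([0.0, 1.0, 2.0, -0.5]))
        assert rep.df == 3

    def test_ties_warn_and_stay_exact(self):
        with pytest.warns(UserWarning, match="tied"):
            rep = wilcoxon_signed_rank_exact(np.array([1.0, 1.0, -1.0, 2.0]))
        w, p = oracle_wilcoxon([1.0, 1.0, -1.0, 2.0])
        assert rep.p == pytest.approx(p)


class TestHotelling:
    def test_published_retraction_duration_pair(self):
        """T2/F from the rounded published means land within ~5% of the
        originals (which used unrounded per-swallow data)."""
        t = ref.burst_durations()
        rep = hotelling_t2_paired(t["B8a/b duration"], t["B3/B6/B9 duration"])
        assert rep.statistic == pytest.approx(59.100, rel=0.05)
        assert hotelling_f(rep) == pytest.approx(22.163, rel=0.05)
        assert rep.df == (2, 3)
        assert rep.p < 0.05

    def test_t2_to_f_conversion_factor(self):
        # printed pair confirms F = (n - p) / (p (n - 1)) T2 = (3/8) T2 exactly
        assert 22.163 / 59.100 == pytest.approx(3.0 / 8.0, abs=1e-4)
        t = ref.burst_durations()
        rep = hotelling_t2_paired(t["B8a/b duration"], t["B3/B6/B9 duration"])
        assert hotelling_f(rep) / rep.statistic == pytest.approx(3.0 / 8.0)

    def test_univariate_reduction_to_squared_t(self, rng):
        diffs = rng.normal(1.0, 0.5, size=6)
        rep = hotelling_t2_paired(table(diffs))
        t_rep = paired_t_one_tailed(table(diffs))
        assert rep.statistic == pytest.approx(t_rep.statistic ** 2, rel=1e-12)

    def test_null_rejection_rate(self, rng):
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            d = rng.normal(size=(5, 2))
            rep = hotelling_t2_paired(table(d[:, 0]), table(d[:, 1]))
            hits += rep.p < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)

    def test_singular_covariance_rejected(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            hotelling_t2_paired(table(d), table(2 * d))


class TestBonferroniAndRegression:
    def test_threshold_at_alpha_over_k(self):
        from aplysia_swallow.stats import StatReport
        reps = [StatReport("t", 2.0, 4, 0.024), StatReport("t", 2.0, 4, 0.03)]
        adj = posthoc_bonferroni(reps)
        assert adj[0].significant and not adj[1].significant
        assert adj[0].p == 0.024  # raw p unchanged

    def test_collinear_points_r2_one(self):
        r2, p, n = linregress_r2([1, 2, 3, 4], [2, 4, 6, 8])
        assert r2 == pytest.approx(1.0) and n == 4

    def test_null_r2_distribution(self, rng):
        """Under independence, R2 ~ Beta(1/2, (n-2)/2)."""
        n = 12
        r2s = np.array([linregress_r2(rng.normal(size=n), rng.normal(size=n))[0]
                        for _ in range(400)])
        ks = sst.kstest(r2s, sst.beta(0.5, (n - 2) / 2).cdf)
        assert ks.pvalue > 0.01

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linregress_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBattery:
    def test_published_tables_reproduce_decision_pattern(self):
        """Protraction groups n.s.; retraction groups significant with both
        duration post hocs passing Bonferroni; B4/B5 duration significant;
        B4/B5 frequency routed to Wilcoxon and n.s."""
        report = analyze_battery({**ref.burst_durations(), **ref.burst_frequencies()})
        assert not report["protraction durations"]["hotelling"]["significant"]
        assert report["protraction durations"]["posthoc"] is None
        ret = report["retraction durations"]
        assert ret["hotelling"]["significant"]
        for m, r in ret["posthoc"].items():
            assert r["alpha"] == pytest.approx(0.025)
            assert r["significant"], m
        assert report["B4/B5 duration"]["significant"]
        b4b5f = report["B4/B5 frequency"]
        assert "wilcoxon" in b4b5f["test"] and not b4b5f["significant"]
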