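"""Validation mathematics: aggregation equations, Δ metrics, categorization,
PC1 criterion, cohort statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from kbxfer.dvh import CumulativeDVH, default_dose_axis, mean_dose, v_at_dose
from kbxfer.errors import ConfigError, DataError, ModelError
from kbxfer.validation import (aggregate_predictions, categorize_prediction,
                               cohort_average, cohort_comparison,
                               delta_metrics, pc1_inside,
                               pc1_outside_fraction, proportion_ci,
                               scalar_aggregate, ValidationConfig)

from conftest import band_from_curves, linear_dvh, random_dvh

AXIS = default_dose_axis()


def flat_band(level, half, model_id="m", patient_id="p"):
    """Band around a linear-ish curve at a given level over the mid range."""
    mean = np.clip(1.0 - (1.0 - level) * AXIS / 40.0, 0.0, 1.0)
    mean[0] = 1.0
    lo = np.clip(mean - half, 0.0, 1.0)
    lo[0] = 1.0
    hi = np.clip(mean + half, 0.0, 1.0)
    hi[0] = 1.0
    return band_from_curves(AXIS, lo, mean, hi, model_id, patient_id)


def random_band(rng, model_id="m", patient_id="p"):
    mid = random_dvh(AXIS, rng).volume_fraction
    half = rng.uniform(0.0, 0.1)
    lo = np.clip(mid - half, 0, 1)
    hi = np.clip(mid + half, 0, 1)
    lo[0] = hi[0] = 1.0
    lo = np.maximum.accumulate(lo[::-1])[::-1]
    hi = np.maximum.accumulate(hi[::-1])[::-1]
    return band_from_curves(AXIS, lo, mid, hi, model_id, patient_id)


class TestAggregation:
    def test_identical_bands(self, rng):
        band = random_band(rng)
        m, s = aggregate_predictions([band] * 10)
        np.testing.assert_allclose(m, band.midpoint().volume_fraction,
                                   atol=1e-15)
        np.testing.assert_allclose(s, 0.0, atol=1e-15)

    def test_two_level_closed_form(self):
        a_band = flat_band(0.3, 0.0)
        b_band = flat_band(0.6, 0.0)
        m, s = aggregate_predictions([a_band] * 5 + [b_band] * 5)
        a = a_band.midpoint().volume_fraction
        b = b_band.midpoint().volume_fraction
        np.testing.assert_allclose(m, (a + b) / 2, atol=1e-12)
        np.testing.assert_allclose(s, np.abs(a - b) * np.sqrt(10 / 9) / 2,
                                   atol=1e-12)

    def test_random_vs_two_pass_oracle(self, rng):
        bands = [random_band(rng, model_id=f"m{j}") for j in range(10)]
        m, s = aggregate_predictions(bands)
        M = np.array([b.midpoint().volume_fraction for b in bands])
        mean_o = np.zeros(AXIS.size)
        for row in M:
            mean_o += row
        mean_o /= 10
        var_o = np.zeros(AXIS.size)
        for row in M:
            var_o += (row - mean_o) ** 2
        sd_o = np.sqrt(var_o / 9)
        np.testing.assert_allclose(m, mean_o, atol=1e-12)
        np.testing.assert_allclose(s, sd_o, atol=1e-12)

    def test_fewer_than_two_bands_error(self, rng):
        with pytest.raises(DataError):
            aggregate_predictions([random_band(rng)])

    def test_cohort_average_trivials_and_oracle(self, rng):
        one = (rng.random(AXIS.size), rng.random(AXIS.size))
        m, s = cohort_average([one])
        np.testing.assert_array_equal(m, one[0])
        np.testing.assert_array_equal(s, one[1])
        per = [(rng.random(AXIS.size), rng.random(AXIS.size))
               for _ in range(20)]
        m, s = cohort_average(per)
        m_o = sum(p[0] for p in per) / 20
        s_o = sum(p[1] for p in per) / 20
        np.testing.assert_allclose(m, m_o, atol=1e-12)
        np.testing.assert_allclose(s, s_o, atol=1e-12)

    def test_scalar_aggregate_ignores_nan(self):
        vals = np.array([[1.0, 2.0, np.nan], [3.0, 4.0, 5.0]])
        m, s = scalar_aggregate(vals)
        assert m == pytest.approx((1.5 + 4.0) / 2)
        exp_sd = (np.std([1, 2], ddof=1) + np.std([3, 4, 5], ddof=1)) / 2
        assert s == pytest.approx(exp_sd)


class TestDeltaMetrics:
    def test_equal_curves_zero_inside(self):
        band = flat_band(0.3, 0.05)
        rec = delta_metrics(band.midpoint(), band, 40.0)
        assert rec.delta_mean_dose == pytest.approx(0.0, abs=1e-9)
        assert rec.delta_v20 == pytest.approx(0.0, abs=1e-9)
        assert rec.inside_mean and rec.inside_v20

    def test_boundary_two_gray_inclusive(self):
        """Clinical mean dose exactly 2 Gy above predicted counts inside."""
        pred = linear_dvh(AXIS, 40.0)
        band = band_from_curves(AXIS, pred.volume_fraction,
                                pred.volume_fraction, pred.volume_fraction)
        clin_vf = np.clip(1.0 - AXIS / 44.0, 0.0, 1.0)
        clin = CumulativeDVH(AXIS, clin_vf)
        rec = delta_metrics(clin, band, 40.0)
        assert rec.delta_mean_dose == pytest.approx(2.0, abs=1e-9)
        assert rec.inside_mean
        cfg = ValidationConfig(inclusive_bands=False)
        assert not delta_metrics(clin, band, 40.0, cfg).inside_mean

    def test_constructed_v20_gap_outside(self):
        """Clinical V20Gy = 30%, predicted 24% -> Δ = +6 points, outside."""
        def curve(v20):
            vf = np.ones_like(AXIS)
            sel = AXIS > 0
            vf[sel] = np.clip(1.0 + (v20 - 1.0) * AXIS[sel] / 20.0, 0.0, 1.0)
            vf = np.maximum.accumulate(vf[::-1])[::-1]
            vf[0] = 1.0
            return vf
        clin = CumulativeDVH(AXIS, curve(0.30))
        pred = curve(0.24)
        band = band_from_curves(AXIS, pred, pred, pred)
        assert v_at_dose(clin, 20.0) == pytest.approx(30.0, abs=1e-9)
        rec = delta_metrics(clin, band, 40.0)
        assert rec.delta_v20 == pytest.approx(6.0, abs=1e-9)
        assert not rec.inside_v20

    def test_delta_antisymmetry(self, rng):
        a = random_dvh(AXIS, rng)
        b = random_dvh(AXIS, rng)
        band_b = band_from_curves(AXIS, b.volume_fraction, b.volume_fraction,
                                  b.volume_fraction)
        band_a = band_from_curves(AXIS, a.volume_fraction, a.volume_fraction,
                                  a.volume_fraction)
        r1 = delta_metrics(a, band_b, 40.0)
        r2 = delta_metrics(b, band_a, 40.0)
        assert r1.delta_mean_dose == pytest.approx(-r2.delta_mean_dose,
                                                   abs=1e-12)
        assert r1.delta_v20 == pytest.approx(-r2.delta_v20, abs=1e-12)


class TestProportionCI:
    def test_full_success(self):
        est, lo, hi = proportion_ci(10, 10)
        assert est == 1.0 and hi == pytest.approx(1.0)

    def test_wilson_closed_form(self):
        est, lo, hi = proportion_ci(50, 100)
        z = stats.norm.ppf(0.975)
        p, n = 0.5, 100
        center = (p + z ** 2 / (2 * n)) / (1 + z ** 2 / n)
        half = (z / (1 + z ** 2 / n)) * np.sqrt(p * (1 - p) / n
                                                + z ** 2 / (4 * n ** 2))
        assert lo == pytest.approx(center - half, abs=1e-9)
        assert hi == pytest.approx(center + half, abs=1e-9)
        assert (lo, hi) == (pytest.approx(0.404, abs=5e-3),
                            pytest.approx(0.596, abs=5e-3))

    def test_estimate_inside_interval(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            est, lo, hi = proportion_ci(k, n)
            assert lo - 1e-12 <= est <= hi + 1e-12

    def test_zero_total_error(self):
        with pytest.raises(DataError):
            proportion_ci(0, 0)


class TestCategorization:
    @staticmethod
    def _shifted(band, delta):
        vf = np.clip(band.mean.volume_fraction + delta, 0.0, 1.0)
        vf[0] = 1.0
        vf = np.maximum.accumulate(vf[::-1])[::-1]
        return CumulativeDVH(AXIS, vf)

    def test_fixture_labels(self):
        band = flat_band(0.4, 0.05)
        assert categorize_prediction(band.midpoint(), band, 40.0) == "optimal"
        assert categorize_prediction(self._shifted(band, -0.09), band,
                                     40.0) == "suboptimal"
        assert categorize_prediction(self._shifted(band, 0.09), band,
                                     40.0) == "improved"
        assert categorize_prediction(self._shifted(band, 0.30), band,
                                     40.0) == "failed"

    def test_widening_band_never_demotes_optimal(self, rng):
        cfg = ValidationConfig()
        for _ in range(30):
            band = random_band(rng)
            clin = random_dvh(AXIS, rng)
            label = categorize_prediction(clin, band, 40.0, cfg)
            wide_lo = np.clip(band.lower.volume_fraction - 0.05, 0, 1)
            wide_hi = np.clip(band.upper.volume_fraction + 0.05, 0, 1)
            wide_lo[0] = wide_hi[0] = 1.0
            wide_lo = np.maximum.accumulate(wide_lo[::-1])[::-1]
            wide_hi = np.maximum.accumulate(wide_hi[::-1])[::-1]
            wide = band_from_curves(AXIS, wide_lo,
                                    band.mean.volume_fraction, wide_hi)
            wide_label = categorize_prediction(clin, wide, 40.0, cfg)
            if label == "optimal":
                assert wide_label == "optimal"

    def test_invalid_band_rejected(self, rng):
        band = flat_band(0.4, 0.05)
        bad = band_from_curves(AXIS, band.lower.volume_fraction,
                               band.mean.volume_fraction,
                               band.upper.volume_fraction)
        bad.lower, bad.upper = bad.upper, bad.lower
        with pytest.raises(ModelError):
            categorize_prediction(band.midpoint(), bad, 40.0)


class TestPC1Criterion:
    class FakeResults:
        def __init__(self, p10, p90):
            self.pc1_percentiles = (p10, p90)

    def test_boundary_inclusive(self):
        res = self.FakeResults(-1.0, 2.0)
        assert pc1_inside(res, 2.0)
        assert pc1_inside(res, -1.0)
        assert not pc1_inside(res, 2.0001)
        assert pc1_inside(res, 5.0, mode="upper_only") is False
        assert pc1_inside(res, -50.0, mode="upper_only")

    def test_median_of_uniform_training(self):
        train = np.arange(1.0, 101.0)
        res = self.FakeResults(np.percentile(train, 10),
                               np.percentile(train, 90))
        assert pc1_inside(res, 50.0)

    def test_against_sort_interpolate_oracle(self, rng):
        """Flags equal an independently coded percentile oracle."""
        def oracle_pct(xs, q):
            xs = sorted(xs)
            h = (len(xs) - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
        for _ in range(200):
            train = rng.normal(size=int(rng.integers(5, 40)))
            res = self.FakeResults(np.percentile(train, 10),
                                   np.percentile(train, 90))
            x = float(rng.normal())
            p10, p90 = oracle_pct(train, 10), oracle_pct(train, 90)
            assert pc1_inside(res, x) == (p10 <= x <= p90)
            assert pc1_inside(res, x, "upper_only") == (x <= p90)

    def test_outside_fraction_monotone_in_window(self, rng):
        train = rng.normal(size=50)
        tests = rng.normal(size=100)
        fracs = []
        for (qlo, qhi) in ((20, 80), (10, 90), (2, 98)):
            res = self.FakeResults(np.percentile(train, qlo),
                                   np.percentile(train, qhi))
            fracs.append(pc1_outside_fraction(res, tests))
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            pc1_inside(self.FakeResults(0, 1), 0.5, mode="sideways")


class TestCohortComparison:
    def test_identical_samples_mw(self):
        _, p = cohort_comparison([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0],
                                 "mann_whitney")
        assert p > 0.8

    def test_complete_separation_mw(self):
        u, p = cohort_comparison([1.0, 2.0, 3.0], [101.0, 102.0, 103.0],
                                 "mann_whitney")
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # 2/C(6,3) exact minimum

    def test_mann_whitney_vs_enumeration_oracle(self, rng):
        for _ in range(30):
            n, m = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            a, b = rng.normal(size=n), rng.normal(size=m)
            stat, p = cohort_comparison(a, b, "mann_whitney")
            ranks = stats.rankdata(np.concatenate([a, b]))
            obs = ranks[:n].sum() - n * (n + 1) / 2
            us = [ranks[list(c)].sum() - n * (n + 1) / 2
                  for c in itertools.combinations(range(n + m), n)]
            us = np.array(us)
            p_o = min(1.0, 2 * min((us >= obs).mean(), (us <= obs).mean()))
            assert p == pytest.approx(p_o, abs=1e-6)

    def test_wilcoxon_vs_sign_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            a, b = rng.normal(size=n), rng.normal(size=n)
            stat, p = cohort_comparison(a, b, "wilcoxon_signed_rank")
            d = a - b
            d = d[d != 0]
            r = stats.rankdata(np.abs(d))
            obs = r[d > 0].sum()
            ws = np.array([(r * np.array(sg)).sum() for sg in
                           itertools.product([0, 1], repeat=d.size)])
            p_o = min(1.0, 2 * min((ws >= obs).mean(), (ws <= obs).mean()))
            assert p == pytest.approx(p_o, abs=1e-6)

    def test_welch_vs_closed_form(self, rng):
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(4, 9)))
            b = rng.normal(1.0, 2.0, size=int(rng.integers(4, 9)))
            t, p = cohort_comparison(a, b, "welch_t")
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            t_o = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va ** 2 / (a.size - 1)
                                   + vb ** 2 / (b.size - 1))
            p_o = 2 * stats.t.sf(abs(t_o), df)
            assert t == pytest.approx(t_o, abs=1e-9)
            assert p == pytest.approx(p_o, abs=1e-9)

    def test_wilcoxon_degenerate_and_unpaired(self):
        with pytest.raises(DataError):
            cohort_comparison([1.0, 2.0], [1.0, 2.0], "wilcoxon_signed_rank")
        with pytest.raises(DataError):
            cohort_comparison([1.0, 2.0], [1.0], "wilcoxon_signed_rank")
        with pytest.raises(ConfigError):
            cohort_comparison([1.0], [2.0], "median_split")
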