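"""KB predictor: parameter recovery, prediction bands, bookkeeping,
serialization."""

import warnings

import numpy as np
import pytest

from kbxfer.dvh import CumulativeDVH, default_dose_axis
from kbxfer.errors import DataError, ModelError, SchemaVersionError
from kbxfer.geometry import GeometryPCA
from kbxfer.model import KBConfig, KBPlanModel, KBPlanResults

from conftest import summary_from_overlap

AXIS = default_dose_axis()


def bump_component(center=25.0, width=8.0):
    """A smooth normalized DVH-variation shape vanishing at dose 0."""
    c = np.exp(-0.5 * ((AXIS - center) / width) ** 2)
    c[0] = 0.0
    return c / np.linalg.norm(c)


def base_curve():
    # headroom below 1 so planted perturbations never hit the clip
    v = 0.95 / (1.0 + np.exp((AXIS - 25.0) / 6.0))
    v /= v[0] / 0.95
    v[0] = 1.0
    return v


def planted_cohort(n, noise_sd, rng, coef=(0.04, 0.025)):
    """Cohort whose DVHs depend linearly on geometry PC1 with known
    coefficients (in the geometry-score basis the model itself will refit,
    which is deterministic)."""
    overlaps = rng.uniform(0.02, 0.35, size=n)
    sums = [summary_from_overlap(float(ov), patient_id=f"p{i}")
            for i, ov in enumerate(overlaps)]
    gpca = GeometryPCA().fit(sums)
    g1 = np.array([gpca.transform(s).pc1 for s in sums])
    comp = bump_component()
    base = base_curve()
    scores = coef[0] + coef[1] * g1 + rng.normal(0.0, noise_sd, size=n)
    dvhs = []
    for i, s in enumerate(scores):
        vf = np.clip(base + s * comp, 0.0, 1.0)
        vf = np.maximum.accumulate(vf[::-1])[::-1]
        vf[0] = 1.0
        dvhs.append(CumulativeDVH(AXIS, vf, organ="IPSI_LUNG",
                                  patient_id=f"p{i}"))
    return sums, dvhs, scores


class TestTraining:
    def test_noiseless_coefficient_recovery(self, rng):
        sums, dvhs, _ = planted_cohort(80, 0.0, rng)
        res = KBPlanModel(sums, dvhs, config=KBConfig()).fit()
        assert res.dvh_components.shape[0] == 1
        # the intercept is absorbed by DVH centering; the slope and the full
        # predictions are identified
        comp = bump_component()
        sign = np.sign(res.dvh_components[0] @ comp)
        assert sign * res.coefficients[1, 0] == pytest.approx(0.025, abs=1e-6)
        assert np.all(res.residual_sd < 1e-8)
        band = res.predict_band(sums[5], band_multiplier=0.0)
        np.testing.assert_allclose(band.mean.volume_fraction,
                                   dvhs[5].volume_fraction, atol=1e-6)

    def test_residual_sd_recovery_under_noise(self):
        rng = np.random.default_rng(7)
        truth = 0.012
        sums, dvhs, _ = planted_cohort(80, truth, rng)
        res = KBPlanModel(sums, dvhs).fit()
        assert res.residual_sd[0] == pytest.approx(truth, rel=0.15)

    def test_identical_cohort_degenerate_warning(self):
        sums = [summary_from_overlap(0.1 + 0.01 * i, patient_id=f"p{i}")
                for i in range(72)]
        dvh = CumulativeDVH(AXIS, base_curve(), organ="IPSI_LUNG")
        with pytest.warns(UserWarning):
            res = KBPlanModel(sums, [dvh] * 72).fit()
        assert np.all(res.residual_sd < 1e-10)

    def test_planted_outlier_logged_and_removed(self):
        rng = np.random.default_rng(3)
        sums, dvhs, _ = planted_cohort(80, 0.004, rng)
        comp = bump_component()
        vf = np.clip(base_curve() + 0.3 * comp, 0.0, 1.0)  # ~10 SD outlier
        vf = np.maximum.accumulate(vf[::-1])[::-1]
        vf[0] = 1.0
        dvhs[17] = CumulativeDVH(AXIS, vf, organ="IPSI_LUNG",
                                 patient_id="p17")
        res = KBPlanModel(sums, dvhs).fit()
        assert [e["patient_id"] for e in res.outlier_log] == ["p17"]
        assert res.n_train == 79

    def test_minimum_cohort_enforced(self, rng):
        sums, dvhs, _ = planted_cohort(80, 0.0, rng)
        with pytest.raises(DataError, match="70"):
            KBPlanModel(sums[:50], dvhs[:50]).fit()

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(11)
        overlaps = rng.uniform(0.02, 0.35, size=80)
        sums = [summary_from_overlap(float(ov),
                                     curvature=float(rng.uniform(0.8, 1.2)),
                                     ptv=float(rng.uniform(400, 1200)))
                for ov in overlaps]
        base = base_curve()
        comps = [bump_component(15, 5), bump_component(28, 7),
                 bump_component(38, 4)]
        dvhs = []
        for _ in range(80):
            vf = base + sum(float(rng.normal(0, 0.02)) * c for c in comps)
            vf = np.maximum.accumulate(np.clip(vf, 0, 1)[::-1])[::-1]
            vf[0] = 1.0
            dvhs.append(CumulativeDVH(AXIS, vf, organ="IPSI_LUNG"))
        res = KBPlanModel(sums, dvhs,
                          config=KBConfig(dvh_components=3,
                                          outlier_threshold=50.0)).fit()
        assert res.n_train == 80  # indices stay aligned with the inputs
        errs = []
        for k in (1, 2, 3):
            dev = [np.abs(res.reconstruct_training_dvh(i, k)
                          - dvhs[i].volume_fraction).max()
                   for i in range(len(dvhs))]
            errs.append(np.mean(dev))
        assert errs[0] >= errs[1] >= errs[2]


@pytest.fixture(scope="module")
def fitted_noisy():
    rng = np.random.default_rng(5)
    sums, dvhs, _ = planted_cohort(80, 0.008, rng)
    return KBPlanModel(sums, dvhs, model_id="inst").fit(), sums


@pytest.fixture(scope="module")
def fitted_varied_volumes():
    rng = np.random.default_rng(9)
    sums, dvhs, _ = planted_cohort(80, 0.005, rng)
    # give the cohort a realistic spread of joint target volumes
    sums = [summary_from_overlap(s.overlap_fraction,
                                 ptv=float(rng.lognormal(np.log(650), 0.4)),
                                 patient_id=s.patient_id) for s in sums]
    return KBPlanModel(sums, dvhs).fit()


class TestPrediction:
    @pytest.fixture
    def fitted(self, fitted_noisy):
        return fitted_noisy

    def test_zero_multiplier_collapses_band(self, fitted):
        res, sums = fitted
        band = res.predict_band(sums[0], band_multiplier=0.0)
        np.testing.assert_array_equal(band.lower.volume_fraction,
                                      band.upper.volume_fraction)

    def test_band_invariants(self, fitted):
        res, sums = fitted
        band = res.predict_band(sums[3])
        for curve in (band.lower, band.mean, band.upper):
            assert curve.volume_fraction[0] == 1.0
            assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
            assert curve.volume_fraction.min() >= 0.0
        assert np.all(band.lower.volume_fraction
                      <= band.upper.volume_fraction + 1e-12)

    def test_prediction_deterministic_bitwise(self, fitted):
        res, sums = fitted
        a = res.predict_band(sums[7]).mean.volume_fraction
        b = res.predict_band(sums[7]).mean.volume_fraction
        np.testing.assert_array_equal(a, b)

    def test_degenerate_model_predicts_training_mean(self):
        sums = [summary_from_overlap(0.05 + 0.003 * i, patient_id=f"p{i}")
                for i in range(72)]
        dvh = CumulativeDVH(AXIS, base_curve(), organ="IPSI_LUNG")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = KBPlanModel(sums, [dvh] * 72).fit()
        band = res.predict_band(sums[10])
        np.testing.assert_allclose(band.mean.volume_fraction, base_curve(),
                                   atol=1e-9)
        np.testing.assert_allclose(band.upper.volume_fraction,
                                   band.lower.volume_fraction, atol=1e-9)

    def test_serialization_roundtrip_bitwise(self, fitted, tmp_path):
        res, sums = fitted
        path = tmp_path / "model.json"
        res.save(path)
        res2 = KBPlanResults.load(path)
        b1 = res.predict_band(sums[2])
        b2 = res2.predict_band(sums[2])
        for a, b in ((b1.lower, b2.lower), (b1.mean, b2.mean),
                     (b1.upper, b2.upper)):
            np.testing.assert_array_equal(a.volume_fraction, b.volume_fraction)

    def test_old_schema_version_rejected(self, fitted):
        import json
        res, _ = fitted
        doc = json.loads(res.to_json())
        doc["schema_version"] = 0
        with pytest.raises(SchemaVersionError, match="version"):
            KBPlanResults.from_json(json.dumps(doc))


class TestJointTargetRange:
    @pytest.fixture
    def fitted(self, fitted_varied_volumes):
        return fitted_varied_volumes

    def test_closed_interval_at_boundary(self, fitted):
        lo, hi = fitted.target_volume_range
        assert fitted.joint_target_in_range(lo)
        assert fitted.joint_target_in_range(hi)
        assert not fitted.joint_target_in_range(hi * 1.001)

    def test_cohort_counting(self, fitted):
        lo, hi = fitted.target_volume_range
        vols = [lo - 1.0] * 10 + [0.5 * (lo + hi)] * 10
        assert fitted.cohort_in_range_percentage(vols) == 50.0

    def test_in_range_fraction_decreases_with_test_volume(self, fitted):
        """Three-point monotone sweep of the test-cohort volume mean."""
        rng = np.random.default_rng(21)
        fractions = []
        for mean_vol in (700.0, 1150.0, 1800.0):
            vols = rng.lognormal(np.log(mean_vol), 0.45, size=200)
            fractions.append(fitted.cohort_in_range_percentage(vols))
        assert fractions[0] > fractions[1] > fractions[2]


def test_pc1_percentiles_match_linear_interpolation(rng):
    sums, dvhs, _ = planted_cohort(80, 0.005, rng)
    res = KBPlanModel(sums, dvhs).fit()
    pc1 = res.train_geometry[:, 0]
    assert res.pc1_percentiles[0] == pytest.approx(
        np.percentile(pc1, 10.0), abs=1e-12)
    assert res.pc1_percentiles[1] == pytest.approx(
        np.percentile(pc1, 90.0), abs=1e-12)
    assert res.pc1_percentiles[0] <= res.pc1_percentiles[1]


def test_summary_renders(rng):
    sums, dvhs, _ = planted_cohort(80, 0.005, rng)
    res = KBPlanModel(sums, dvhs, organ="IPSI_LUNG", model_id="inst_1").fit()
    text = res.summary()
    assert "IPSI_LUNG" in text and "inst_1" in text
    assert "80" in text
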