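"""Validation mathematics for inter-consortium model transfer.

Given clinical DVHs and the prediction bands of several institution models,
this module computes:

* per-patient aggregation across models — the mean of the 10 midpoint
  curves and their pointwise sample SD (denominator n-1) — and the cohort
  averages of both (the DVH_int / SD_int inter-institute variability
  curves);
* Δ accuracy metrics, Δ = clinical − predicted (positive when the clinical
  dose/volume exceeds the prediction), with the ±2 Gy mean-dose and
  ±5 percentage-point V20Gy accuracy bands and Wilson 95% CIs on the
  proportions inside them;
* the four-way categorization of each prediction against its band over the
  20%–80%-of-prescription dose range (optimal / suboptimal / improved /
  failed);
* the PC1 percentile transferability criterion; and
* the rank-based cohort comparison tests (Mann–Whitney U, Welch t,
  Wilcoxon signed-rank).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .dvh import CumulativeDVH, mean_dose, v_at_dose
from .errors import ConfigError, DataError, ModelError
from .geometry import GeometryScores
from .model import KBPlanResults, PredictionBand

CATEGORIES = ("optimal", "suboptimal", "improved", "failed")


@dataclass
class DeltaRecord:
    """Clinical-minus-predicted accuracy deltas for one (patient, model)."""

    patient_id: str
    model_id: str
    delta_mean_dose: float      # Gy
    delta_v20: float            # percentage points
    inside_mean: bool = False   # |Δ mean dose| within the ±2 Gy band
    inside_v20: bool = False    # |Δ V20Gy| within the ±5 point band


@dataclass
class ValidationConfig:
    """Declared knobs of the validation stage."""

    mean_dose_band_gy: float = 2.0
    v20_band_points: float = 5.0
    inclusive_bands: bool = True          # |Δ| equal to the band counts as inside
    eval_range: tuple[float, float] = (0.20, 0.80)   # fraction of prescription
    optimal_inside_fraction: float = 0.90
    fail_gap_threshold: float = 0.10      # mean volume-fraction gap
    pc1_mode: str = "two_sided"           # or "upper_only"


# ---------------------------------------------------------------------------
# Aggregation across models and patients
# ---------------------------------------------------------------------------

def aggregate_predictions(bands: list[PredictionBand]
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient aggregation over institution models.

    Each model's point prediction is the midpoint (lower+upper)/2 of its
    band; returns the pointwise arithmetic mean of these curves and their
    pointwise sample standard deviation (denominator n-1).
    """
    if len(bands) < 2:
        raise DataError("need at least 2 model bands for a sample SD")
    axis = bands[0].mean.dose_axis
    mids = []
    for b in bands:
        if not np.allclose(b.mean.dose_axis, axis):
            raise DataError("all bands must share one dose axis")
        mids.append(b.midpoint().volume_fraction)
    M = np.array(mids)
    return M.mean(axis=0), M.std(axis=0, ddof=1)


def cohort_average(per_patient: list[tuple[np.ndarray, np.ndarray]]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level inter-institute variability curves.

    The cohort mean DVH is the average over patients of the per-patient
    model-mean curves; the cohort SD curve is the average over patients of
    the per-patient model SDs (both pointwise).
    """
    if not per_patient:
        raise DataError("cohort_average needs at least one patient")
    means = np.array([m for m, _ in per_patient])
    sds = np.array([s for _, s in per_patient])
    if means.ndim != 2:
        raise DataError("per-patient curves must share one dose axis")
    return means.mean(axis=0), sds.mean(axis=0)


def scalar_aggregate(values: np.ndarray) -> tuple[float, float]:
    """The same mean/SD recipe applied to scalar predictions: per-patient
    mean and sample SD over models, then averaged over patients.

    ``values`` has shape (n_patients, n_models); entries may be NaN for
    excluded (failed) records and are ignored pairwise.
    """
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        per_patient_mean = np.nanmean(values, axis=1)
        per_patient_sd = np.nanstd(values, axis=1, ddof=1)
    return float(np.nanmean(per_patient_mean)), float(np.nanmean(per_patient_sd))


# ---------------------------------------------------------------------------
# Δ accuracy metrics
# ---------------------------------------------------------------------------

def delta_metrics(cdvh: CumulativeDVH, band: PredictionBand,
                  prescription: float,
                  config: ValidationConfig | None = None) -> DeltaRecord:
    """Δ = clinical − predicted for mean dose (Gy) and V20Gy (points).

    The predicted scalar is the metric of the band's midpoint curve; a
    positive Δ means the clinical dose/volume exceeds the prediction.
    """
    cfg = config or ValidationConfig()
    if not np.allclose(cdvh.dose_axis, band.mean.dose_axis):
        raise DataError("clinical DVH and band must share one dose axis")
    mid = band.midpoint()
    d_mean = mean_dose(cdvh) - mean_dose(mid)
    d_v20 = v_at_dose(cdvh, 20.0, prescription) - v_at_dose(mid, 20.0, prescription)
    if cfg.inclusive_bands:
        ins_m = abs(d_mean) <= cfg.mean_dose_band_gy
        ins_v = abs(d_v20) <= cfg.v20_band_points
    else:
        ins_m = abs(d_mean) < cfg.mean_dose_band_gy
        ins_v = abs(d_v20) < cfg.v20_band_points
    return DeltaRecord(patient_id=cdvh.patient_id or band.patient_id,
                       model_id=band.model_id,
                       delta_mean_dose=float(d_mean), delta_v20=float(d_v20),
                       inside_mean=bool(ins_m), inside_v20=bool(ins_v))


def proportion_ci(inside_count: int, total: int,
                  alpha: float = 0.05) -> tuple[float, float, float]:
    """Binomial proportion with its Wilson score interval.

    Returns (estimate, lower, upper) at the 1-alpha level.
    """
    if total <= 0:
        raise DataError("proportion needs a positive total count")
    if not 0 <= inside_count <= total:
        raise DataError("inside_count must lie in [0, total]")
    est = inside_count / total
    lo, hi = proportion_confint(inside_count, total, alpha=alpha, method="wilson")
    return est, float(lo), float(hi)


# ---------------------------------------------------------------------------
# Band categorization
# ---------------------------------------------------------------------------

def categorize_prediction(cdvh: CumulativeDVH, band: PredictionBand,
                          prescription: float,
                          config: ValidationConfig | None = None) -> str:
    """Four-way label of a clinical DVH against a prediction band.

    Evaluated at every axis point with dose between 20% and 80% of the
    prescription: *optimal* if the clinical curve lies within [lower,
    upper] at >= 90% of points; otherwise *failed* if the mean
    volume-fraction gap to the nearest band edge over out-of-band points
    exceeds 0.10 (the band "strongly disagrees"); otherwise *suboptimal*
    (majority of out-of-band points below the band — the clinical plan
    spares less than predicted achievable) or *improved* (above).
    Failed records are excluded from the downstream Δ analysis.
    """
    cfg = config or ValidationConfig()
    lo = band.lower.volume_fraction
    up = band.upper.volume_fraction
    if np.any(lo > up + 1e-9):
        raise ModelError("invalid band: lower exceeds upper")
    axis = cdvh.dose_axis
    lo_d, hi_d = (cfg.eval_range[0] * prescription, cfg.eval_range[1] * prescription)
    sel = (axis >= lo_d - 1e-9) & (axis <= hi_d + 1e-9)
    if not sel.any():
        raise ConfigError("evaluation range contains no dose axis points")
    v = cdvh.volume_fraction[sel]
    lo, up = lo[sel], up[sel]
    tol = 1e-9
    below = v < lo - tol
    above = v > up + tol
    inside = ~(below | above)
    if inside.mean() >= cfg.optimal_inside_fraction:
        return "optimal"
    gaps = np.where(below, lo - v, np.where(above, v - up, 0.0))
    out = below | above
    if gaps[out].mean() > cfg.fail_gap_threshold:
        return "failed"
    return "suboptimal" if below.sum() >= above.sum() else "improved"


# ---------------------------------------------------------------------------
# PC1 transferability criterion
# ---------------------------------------------------------------------------

def pc1_inside(results: KBPlanResults, scores: GeometryScores | float,
               mode: str = "two_sided") -> bool:
    """Whether a test patient's geometry PC1 falls inside the model's
    training percentile window (closed bounds).

    ``two_sided`` uses the 10th–90th percentile band; ``upper_only`` only
    requires PC1 <= the 90th percentile.
    """
    if results.pc1_percentiles is None:
        raise ModelError("model carries no training PC1 percentiles")
    pc1 = scores.pc1 if isinstance(scores, GeometryScores) else float(scores)
    p10, p90 = results.pc1_percentiles
    if mode == "two_sided":
        return p10 <= pc1 <= p90
    if mode == "upper_only":
        return pc1 <= p90
    raise ConfigError(f"unknown PC1 mode {mode!r}")


def pc1_outside_fraction(results: KBPlanResults, pc1_values,
                         mode: str = "two_sided") -> float:
    """Fraction of test patients whose PC1 falls outside the window."""
    flags = [pc1_inside(results, v, mode) for v in pc1_values]
    return 1.0 - sum(flags) / len(flags)


# ---------------------------------------------------------------------------
# Cohort comparison statistics
# ---------------------------------------------------------------------------

def cohort_comparison(values_a, values_b, test: str) -> tuple[float, float]:
    """Two-sided cohort comparison: (statistic, p value).

    ``mann_whitney`` ranks with midranks for ties (exact null when both
    samples are small and tie-free); ``welch_t`` uses unequal-variance
    degrees of freedom; ``wilcoxon_signed_rank`` requires paired samples
    and uses the exact null for n <= 25 tie-free differences, else the
    normal approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon_signed_rank":
        if a.shape != b.shape:
            raise DataError("wilcoxon requires paired equal-length samples")
        diff = a - b
        if np.all(diff == 0):
            raise DataError("all paired differences are zero; "
                            "wilcoxon signed-rank is degenerate")
        nz = diff[diff != 0]
        exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
        method = "exact" if exact_ok else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return float(res.statistic), float(res.pvalue)
    raise ConfigError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------

@dataclass
class TransferReport:
    """Per-record table plus cohort-level aggregates for one validation arm.

    ``records`` has one row per (patient, model) with Δ metrics, the
    category label, PC1 and its inside flag.  Aggregates carry the
    model-averaged / cohort-averaged DVH and SD curves, the accuracy-band
    proportions with Wilson CIs, per-model PC1-outside fractions and any
    cohort test p-values attached by the caller.
    """

    records: pd.DataFrame
    dose_axis: np.ndarray
    dvh_mean_per_patient: dict = field(default_factory=dict)
    sigma_per_patient: dict = field(default_factory=dict)
    dvh_int: np.ndarray | None = None
    sd_int: np.ndarray | None = None
    mean_dose_matrix: pd.DataFrame | None = None   # patient x model, failed=NaN
    v20_matrix: pd.DataFrame | None = None
    mean_dose_int: float = np.nan
    mean_dose_sd_int: float = np.nan
    v20_int: float = np.nan
    v20_sd_int: float = np.nan
    proportions: dict = field(default_factory=dict)
    category_counts: dict = field(default_factory=dict)
    pc1_outside_by_model: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    config: ValidationConfig = field(default_factory=ValidationConfig)

    def summary(self) -> str:
        n = len(self.records)
        lines = ["Transferability validation report", "=" * 60,
                 f"records (patient x model): {n}"]
        total = sum(self.category_counts.values()) or 1
        lines.append("categories: " + ", ".join(
            f"{c}: {self.category_counts.get(c, 0)} "
            f"({100 * self.category_counts.get(c, 0) / total:.1f}%)"
            for c in CATEGORIES))
        for name, (est, lo, hi) in self.proportions.items():
            lines.append(f"{name}: {100 * est:.1f}%  "
                         f"(95% CI {100 * lo:.1f}-{100 * hi:.1f}%)")
        lines.append(f"lung mean dose (model-averaged): "
                     f"{self.mean_dose_int:.2f} +/- {self.mean_dose_sd_int:.2f} Gy")
        lines.append(f"lung V20Gy (model-averaged):     "
                     f"{self.v20_int:.1f} +/- {self.v20_sd_int:.1f} %")
        if self.pc1_outside_by_model:
            lines.append("PC1 outside fraction by model: " + ", ".join(
                f"{m}: {f:.2f}" for m, f in sorted(self.pc1_outside_by_model.items())))
        for name, (stat, p) in self.tests.items():
            lines.append(f"test {name}: statistic={stat:.4g}, p={p:.4g}")
        return "\n".join(lines)


def validate_transfer(clinical: dict[str, CumulativeDVH],
                      bands: dict[tuple[str, str], PredictionBand],
                      models: dict[str, KBPlanResults],
                      pc1_scores: dict[str, float],
                      prescription: float,
                      config: ValidationConfig | None = None) -> TransferReport:
    """Run the full per-record and aggregate validation for one test arm.

    Parameters
    ----------
    clinical : dict patient_id -> clinical cumulative DVH (one organ).
    bands : dict (patient_id, model_id) -> PredictionBand.
    models : dict model_id -> fitted results (for the PC1 criterion).
    pc1_scores : dict patient_id -> per-model-agnostic PC1 is *not* enough:
        PC1 is computed in each model's own geometry basis, so this maps
        ``(patient_id, model_id)`` -> PC1 when keyed by tuple, or
        ``patient_id`` -> PC1 when a shared basis is in use.
    prescription : float, Gy.
    """
    cfg = config or ValidationConfig()
    patient_ids = sorted(clinical)
    model_ids = sorted(models)
    rows = []
    per_patient_curves = {}
    md_matrix = np.full((len(patient_ids), len(model_ids)), np.nan)
    v20_matrix = np.full((len(patient_ids), len(model_ids)), np.nan)
    for i, pid in enumerate(patient_ids):
        cdvh = clinical[pid]
        patient_bands = []
        for j, mid in enumerate(model_ids):
            band = bands[(pid, mid)]
            patient_bands.append(band)
            cat = categorize_prediction(cdvh, band, prescription, cfg)
            rec = delta_metrics(cdvh, band, prescription, cfg)
            key = (pid, mid) if (pid, mid) in pc1_scores else pid
            pc1 = float(pc1_scores[key])
            inside = pc1_inside(models[mid], pc1, cfg.pc1_mode)
            rows.append({"patient_id": pid, "model_id": mid,
                         "delta_mean_dose": rec.delta_mean_dose,
                         "delta_v20": rec.delta_v20,
                         "inside_mean": rec.inside_mean,
                         "inside_v20": rec.inside_v20,
                         "category": cat, "pc1": pc1, "pc1_inside": inside})
            if cat != "failed":
                mid_curve = band.midpoint()
                md_matrix[i, j] = mean_dose(mid_curve)
                v20_matrix[i, j] = v_at_dose(mid_curve, 20.0, prescription)
        per_patient_curves[pid] = aggregate_predictions(patient_bands)
    records = pd.DataFrame(rows)

    dvh_int, sd_int = cohort_average([per_patient_curves[p] for p in patient_ids])
    md_int, md_sd_int = scalar_aggregate(md_matrix)
    v20_int, v20_sd_int = scalar_aggregate(v20_matrix)

    ok = records[records["category"] != "failed"]
    proportions = {
        "delta_mean_dose_within_2gy": proportion_ci(int(ok["inside_mean"].sum()),
                                                    len(ok)),
        "delta_v20_within_5pts": proportion_ci(int(ok["inside_v20"].sum()),
                                               len(ok)),
    }
    category_counts = {c: int((records["category"] == c).sum()) for c in CATEGORIES}
    pc1_out = {mid: 1.0 - records.loc[records["model_id"] == mid,
                                      "pc1_inside"].mean()
               for mid in model_ids}
    axis = next(iter(clinical.values())).dose_axis
    return TransferReport(records=records, dose_axis=axis,
                          dvh_mean_per_patient={p: c[0] for p, c
                                                in per_patient_curves.items()},
                          sigma_per_patient={p: c[1] for p, c
                                             in per_patient_curves.items()},
                          dvh_int=dvh_int, sd_int=sd_int,
                          mean_dose_matrix=pd.DataFrame(
                              md_matrix, index=patient_ids, columns=model_ids),
                          v20_matrix=pd.DataFrame(
                              v20_matrix, index=patient_ids, columns=model_ids),
                          mean_dose_int=md_int, mean_dose_sd_int=md_sd_int,
                          v20_int=v20_int, v20_sd_int=v20_sd_int,
                          proportions=proportions,
                          category_counts=category_counts,
                          pc1_outside_by_model=pc1_out, config=cfg)
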