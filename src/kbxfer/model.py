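"""Knowledge-based DVH prediction: PCA + principal-component regression.

The estimator mirrors the published knowledge-based planning recipe: the
training cohort's cumulative DVHs are decomposed by PCA; each retained DVH
principal-component score is regressed (ordinary least squares, with
intercept) on the patient's geometry PCA scores; a new patient's DVH is
reconstructed from the predicted scores, and a prediction band is obtained
by shifting each predicted score by ±k residual standard deviations and
enveloping the rebuilt curves.

Usage follows the Model/Results convention::

    model = KBPlanModel(summaries, dvhs, organ="IPSI_LUNG")
    res = model.fit()
    band = res.predict_band(new_summary)
    print(res.summary())

The fitted results also carry the training bookkeeping the transferability
audit needs: the 10th/90th percentiles of training geometry PC1, the
training joint-target-volume range, and the outlier-elimination log.
"""

from __future__ import annotations

import base64
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .dvh import CumulativeDVH
from .errors import ConfigError, DataError, ModelError, SchemaVersionError
from .geometry import GeometryPCA, GeometryScores, GeometrySummary

SCHEMA_VERSION = 1

#: Minimum training-cohort size for a valid model.
MIN_TRAIN_DEFAULT = 70


@dataclass
class KBConfig:
    """Tunable knobs of the KB estimator.

    ``band_multiplier`` k scales the prediction band (1.28 ~ an 80%
    two-sided normal interval per retained component); ``outlier_threshold``
    is the absolute studentized-residual cut beyond which a training patient
    is dropped, with a single refit pass.
    """

    min_train: int = MIN_TRAIN_DEFAULT
    dvh_components: int | None = None
    geometry_components: int | None = None
    explained_variance_target: float = 0.95
    max_components: int = 5
    band_multiplier: float = 1.28
    outlier_threshold: float = 3.0


@dataclass
class PredictionBand:
    """Lower/mean/upper predicted cumulative DVHs for one patient."""

    lower: CumulativeDVH
    mean: CumulativeDVH
    upper: CumulativeDVH
    model_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        lo, mi, up = (self.lower.volume_fraction, self.mean.volume_fraction,
                      self.upper.volume_fraction)
        if np.any(lo > mi + 1e-9) or np.any(mi > up + 1e-9):
            raise ModelError("prediction band must satisfy lower <= mean <= upper")

    def midpoint(self) -> CumulativeDVH:
        """The (lower+upper)/2 curve — the per-model point prediction used
        by the aggregation equations."""
        vf = 0.5 * (self.lower.volume_fraction + self.upper.volume_fraction)
        return CumulativeDVH(self.mean.dose_axis, vf, organ=self.mean.organ,
                             patient_id=self.patient_id)


def _postprocess_curve(vf: np.ndarray) -> np.ndarray:
    """Project a raw reconstructed curve onto valid cumulative DVHs:
    clip to [0,1], then enforce non-increase by a running maximum taken
    from the high-dose end (the minimal-change repair), then pin V(0)=1."""
    vf = np.clip(vf, 0.0, 1.0)
    vf = np.maximum.accumulate(vf[::-1])[::-1]
    vf[0] = 1.0
    return vf


class KBPlanModel:
    """Per-institution knowledge-based DVH model for one organ.

    Parameters
    ----------
    summaries : list of GeometrySummary
        Training patients' geometry covariates.
    dvhs : list of CumulativeDVH
        The matching clinical cumulative DVHs, all on one shared dose axis.
    organ : str
        Structure label this model predicts.
    model_id : str
        Identifier (typically the training institution).
    config : KBConfig
    """

    def __init__(self, summaries: list[GeometrySummary],
                 dvhs: list[CumulativeDVH], organ: str = "IPSI_LUNG",
                 model_id: str = "", config: KBConfig | None = None) -> None:
        if len(summaries) != len(dvhs):
            raise DataError("summaries and DVHs must pair one-to-one")
        self.summaries = list(summaries)
        self.dvhs = list(dvhs)
        self.organ = organ
        self.model_id = model_id
        self.config = config or KBConfig()
        axis0 = dvhs[0].dose_axis
        for d in dvhs[1:]:
            if d.dose_axis.shape != axis0.shape or not np.allclose(d.dose_axis, axis0):
                raise DataError("all training DVHs must share one dose axis")
        self.dose_axis = axis0.copy()

    def fit(self) -> "KBPlanResults":
        cfg = self.config
        n = len(self.summaries)
        if n < cfg.min_train:
            raise DataError(
                f"training cohort has {n} patients; the model-set criterion "
                f"requires more than {cfg.min_train - 1} (got < {cfg.min_train})")
        fit1 = self._fit_once(self.summaries, self.dvhs)
        outliers = self._find_outliers(fit1)
        log = []
        if outliers:
            keep = [i for i in range(n) if i not in {o[0] for o in outliers}]
            for i, t in outliers:
                log.append({
                    "patient_id": self.summaries[i].patient_id or f"train_{i}",
                    "reason": "studentized DVH-PC residual "
                              f"|t|={t:.2f} > {cfg.outlier_threshold}",
                })
            fit1 = self._fit_once([self.summaries[i] for i in keep],
                                  [self.dvhs[i] for i in keep])
        fit1["outlier_log"] = log
        return KBPlanResults(model=self, **fit1)

    # -- internals ---------------------------------------------------------

    def _fit_once(self, summaries, dvhs) -> dict:
        cfg = self.config
        Y = np.array([d.volume_fraction for d in dvhs])
        n = Y.shape[0]
        dvh_mean = Y.mean(axis=0)
        Yc = Y - dvh_mean
        _, svals, Vt = np.linalg.svd(Yc, full_matrices=False)
        var = svals ** 2 / (n - 1)
        total = var.sum()
        if total < 1e-24:
            warnings.warn("training DVHs have (near-)zero variance; "
                          "degenerate model", stacklevel=3)
            k = 1
        elif cfg.dvh_components is not None:
            k = min(cfg.dvh_components, Vt.shape[0])
        else:
            ratio = np.cumsum(var) / total
            k = min(int(np.searchsorted(ratio, cfg.explained_variance_target) + 1),
                    cfg.max_components, Vt.shape[0])
        dvh_components = Vt[:k]
        S = Yc @ dvh_components.T                     # (n, k) DVH PC scores

        gpca = GeometryPCA(n_components=cfg.geometry_components,
                           explained_variance_target=cfg.explained_variance_target,
                           max_components=cfg.max_components).fit(summaries)
        G = gpca.transform_many(summaries)            # (n, g)
        X = np.column_stack([np.ones(n), G])
        coef, _, rank, _ = np.linalg.lstsq(X, S, rcond=None)
        if rank < X.shape[1]:
            warnings.warn(
                f"rank-deficient geometry design (rank {rank} < {X.shape[1]}); "
                "minimum-norm solution used", stacklevel=3)
        resid = S - X @ coef
        dof = max(n - rank, 1)
        residual_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
        if np.all(residual_sd < 1e-12):
            warnings.warn("zero residual variance in DVH-PC regression",
                          stacklevel=3)

        pc1 = G[:, 0]
        p10, p90 = np.percentile(pc1, [10.0, 90.0])  # linear order-statistic interp
        vols = np.array([s.ptv_volume for s in summaries])
        return {
            "dvh_mean": dvh_mean,
            "dvh_components": dvh_components,
            "geometry_basis": gpca,
            "coefficients": coef,
            "residual_sd": residual_sd,
            "design_rank": int(rank),
            "train_scores": S,
            "train_geometry": G,
            "pc1_percentiles": (float(p10), float(p90)),
            "target_volume_range": (float(vols.min()), float(vols.max())),
            "n_train": n,
        }

    def _find_outliers(self, fit: dict) -> list[tuple[int, float]]:
        """Patients whose studentized DVH-PC residual exceeds the cut."""
        X = np.column_stack([np.ones(fit["train_geometry"].shape[0]),
                             fit["train_geometry"]])
        resid = fit["train_scores"] - X @ fit["coefficients"]
        # leverage from the pseudo-inverse hat diagonal
        XtX_inv = np.linalg.pinv(X.T @ X)
        h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        h = np.clip(h, 0.0, 1.0 - 1e-9)
        sd = np.where(fit["residual_sd"] > 1e-12, fit["residual_sd"], np.inf)
        t = np.abs(resid) / (sd[None, :] * np.sqrt(1.0 - h)[:, None])
        tmax = t.max(axis=1)
        cut = self.config.outlier_threshold
        return [(int(i), float(tmax[i])) for i in np.nonzero(tmax > cut)[0]]


class KBPlanResults:
    """Fitted KB model: bases, regression map, residual scales, and the
    training bookkeeping used by the transferability audit."""

    def __init__(self, model: KBPlanModel, dvh_mean, dvh_components,
                 geometry_basis: GeometryPCA, coefficients, residual_sd,
                 design_rank, train_scores, train_geometry, pc1_percentiles,
                 target_volume_range, n_train, outlier_log) -> None:
        self.model = model
        self.organ = model.organ
        self.model_id = model.model_id
        self.config = model.config
        self.dose_axis = model.dose_axis
        self.dvh_mean = np.asarray(dvh_mean, dtype=float)
        self.dvh_components = np.asarray(dvh_components, dtype=float)
        self.geometry_basis = geometry_basis
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.residual_sd = np.asarray(residual_sd, dtype=float)
        self.design_rank = int(design_rank)
        self.train_scores = np.asarray(train_scores, dtype=float)
        self.train_geometry = np.asarray(train_geometry, dtype=float)
        self.pc1_percentiles = tuple(float(x) for x in pc1_percentiles)
        self.target_volume_range = tuple(float(x) for x in target_volume_range)
        self.n_train = int(n_train)
        self.outlier_log = list(outlier_log)

    # -- prediction --------------------------------------------------------

    def geometry_scores(self, summary: GeometrySummary) -> GeometryScores:
        return self.geometry_basis.transform(summary)

    #: Allowed extrapolation beyond the training DVH-PC score range, as a
    #: fraction of the training span per side.
    score_margin: float = 0.5

    def predict_scores(self, summary: GeometrySummary) -> np.ndarray:
        """Predicted DVH PC scores, confined to a moderate extrapolation of
        the training score range (half the training span beyond either
        end).

        The clip keeps predictions tied to the span of training experience:
        a patient far outside the model's geometry distribution (which the
        PC1 criterion flags separately) gets a bounded extrapolation of
        training-like DVHs rather than an arbitrary one.
        """
        g = self.geometry_scores(summary).pc_scores
        s = self.coefficients[0] + g @ self.coefficients[1:]
        lo = self.train_scores.min(axis=0)
        hi = self.train_scores.max(axis=0)
        span = hi - lo
        return np.clip(s, lo - self.score_margin * span,
                       hi + self.score_margin * span)

    def predict_band(self, summary: GeometrySummary,
                     band_multiplier: float | None = None) -> PredictionBand:
        """Predicted DVH band for a new patient.

        The mean curve rebuilds the DVH from predicted PC scores; lower and
        upper envelope the curves rebuilt with each score shifted by
        ±k·residual_sd, which collapses to mean ∓/± k·Σ sd_c·|component_c|
        pointwise.  All three curves are projected back onto valid
        cumulative DVHs.
        """
        k = self.config.band_multiplier if band_multiplier is None else band_multiplier
        if k < 0:
            raise ConfigError("band multiplier must be >= 0")
        s = self.predict_scores(summary)
        mean_vf = self.dvh_mean + s @ self.dvh_components
        half = k * (self.residual_sd @ np.abs(self.dvh_components))
        lo = _postprocess_curve(mean_vf - half)
        mi = _postprocess_curve(mean_vf)
        up = _postprocess_curve(mean_vf + half)
        axis = self.dose_axis
        mk = lambda v: CumulativeDVH(axis, v, organ=self.organ,
                                     patient_id=summary.patient_id)
        return PredictionBand(mk(lo), mk(mi), mk(up), model_id=self.model_id,
                              patient_id=summary.patient_id)

    # -- transferability bookkeeping ---------------------------------------

    def joint_target_in_range(self, ptv_volume: float) -> bool:
        """True iff the volume lies in the closed training range."""
        lo, hi = self.target_volume_range
        return lo <= ptv_volume <= hi

    def cohort_in_range_percentage(self, ptv_volumes) -> float:
        """Percent of test patients whose joint target volume is in range."""
        flags = [self.joint_target_in_range(v) for v in ptv_volumes]
        return 100.0 * sum(flags) / len(flags)

    def reconstruct_training_dvh(self, index: int, n_components: int | None = None
                                 ) -> np.ndarray:
        """Project training DVH ``index`` onto the leading components and back."""
        k = self.dvh_components.shape[0] if n_components is None else n_components
        s = self.train_scores[index, :k]
        return self.dvh_mean + s @ self.dvh_components[:k]

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Knowledge-based DVH model",
            "=" * 60,
            f"organ:                {self.organ}",
            f"model id:             {self.model_id or '-'}",
            f"training patients:    {self.n_train}"
            + (f"  ({len(self.outlier_log)} outlier(s) removed)"
               if self.outlier_log else ""),
            f"DVH components:       {self.dvh_components.shape[0]}",
            f"geometry components:  {self.coefficients.shape[0] - 1}",
            f"band multiplier k:    {cfg.band_multiplier}",
            f"residual SD per PC:   "
            + ", ".join(f"{s:.4g}" for s in self.residual_sd),
            f"geometry PC1 10th/90th pct: "
            f"{self.pc1_percentiles[0]:.4g} / {self.pc1_percentiles[1]:.4g}",
            f"joint target volume range (cc): "
            f"{self.target_volume_range[0]:.1f} - {self.target_volume_range[1]:.1f}",
        ]
        for entry in self.outlier_log:
            lines.append(f"  excluded {entry['patient_id']}: {entry['reason']}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        gb = self.geometry_basis
        doc = {
            "schema_version": SCHEMA_VERSION,
            "organ": self.organ,
            "model_id": self.model_id,
            "config": asdict(self.config),
            "n_train": self.n_train,
            "design_rank": self.design_rank,
            "pc1_percentiles": list(self.pc1_percentiles),
            "target_volume_range": list(self.target_volume_range),
            "outlier_log": self.outlier_log,
            "arrays": {name: _enc(arr) for name, arr in {
                "dose_axis": self.dose_axis,
                "dvh_mean": self.dvh_mean,
                "dvh_components": self.dvh_components,
                "coefficients": self.coefficients,
                "residual_sd": self.residual_sd,
                "train_scores": self.train_scores,
                "train_geometry": self.train_geometry,
                "geometry_mean": gb.mean_,
                "geometry_sd": gb.sd_,
                "geometry_keep": gb.keep_.astype(np.float64),
                "geometry_components": gb.components_,
                "geometry_explained_variance": gb.explained_variance_,
            }.items()},
        }
        return json.dumps(doc, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "KBPlanResults":
        doc = json.loads(text)
        ver = doc.get("schema_version")
        if ver != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"model schema version {ver!r} is not supported "
                f"(expected {SCHEMA_VERSION}); re-train or migrate the model")
        arrays = {k: _dec(v) for k, v in doc["arrays"].items()}
        gb = GeometryPCA()
        gb.mean_ = arrays["geometry_mean"]
        gb.sd_ = arrays["geometry_sd"]
        gb.keep_ = arrays["geometry_keep"].astype(bool)
        gb.components_ = arrays["geometry_components"]
        gb.explained_variance_ = arrays["geometry_explained_variance"]
        cfg = KBConfig(**doc["config"])
        shell = KBPlanModel.__new__(KBPlanModel)
        shell.organ = doc["organ"]
        shell.model_id = doc["model_id"]
        shell.config = cfg
        shell.dose_axis = arrays["dose_axis"]
        shell.summaries = []
        shell.dvhs = []
        return cls(model=shell, dvh_mean=arrays["dvh_mean"],
                   dvh_components=arrays["dvh_components"], geometry_basis=gb,
                   coefficients=arrays["coefficients"],
                   residual_sd=arrays["residual_sd"],
                   design_rank=doc["design_rank"],
                   train_scores=arrays["train_scores"],
                   train_geometry=arrays["train_geometry"],
                   pc1_percentiles=doc["pc1_percentiles"],
                   target_volume_range=doc["target_volume_range"],
                   n_train=doc["n_train"], outlier_log=doc["outlier_log"])

    @classmethod
    def load(cls, path) -> "KBPlanResults":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _enc(arr: np.ndarray) -> dict:
    a = np.ascontiguousarray(np.asarray(arr, dtype=np.float64))
    return {"shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _dec(blob: dict) -> np.ndarray:
    raw = base64.b64decode(blob["data"])
    return np.frombuffer(raw, dtype=np.float64).reshape(blob["shape"]).copy()
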