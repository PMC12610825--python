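"""Anatomical covariates for knowledge-based DVH prediction.

A patient's geometry is summarised by organ/target volumes, the fraction of
the organ inside the PTV, and a signed distance-to-target histogram (DTH):
the distribution of Euclidean distances from organ voxels to the PTV
surface, negative inside the PTV.  A PCA over standardized (DTH, log-volume,
overlap) feature vectors yields per-patient geometry scores; the first
score, PC1, is the handle used to flag patients that lie outside a model's
training envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dvh import StructureMask
from .errors import (ConfigError, DataError, EmptyStructureError,
                     GridMismatchError, ModelError)

#: Default DTH bin edges: 2 mm bins from -50 mm (inside PTV) to +150 mm.
DEFAULT_DTH_EDGES = np.arange(-50.0, 152.0, 2.0)


@dataclass
class GeometrySummary:
    """Geometric covariates of one organ of one patient.

    ``dth`` is a normalized histogram (mass sums to 1) of signed distance
    from organ voxels to the PTV surface on ``dth_edges``; its mass at
    negative distances equals ``overlap_fraction`` up to one bin.
    """

    ptv_volume: float          # cc
    organ_volume: float        # cc
    overlap_fraction: float    # organ volume inside PTV / organ volume
    out_of_field_fraction: float
    dth: np.ndarray
    dth_edges: np.ndarray = field(default_factory=lambda: DEFAULT_DTH_EDGES.copy())
    patient_id: str = ""
    organ: str = ""

    def __post_init__(self) -> None:
        self.dth = np.asarray(self.dth, dtype=float)
        self.dth_edges = np.asarray(self.dth_edges, dtype=float)
        if self.dth.size != self.dth_edges.size - 1:
            raise ConfigError("DTH length must match its bin edges")
        if self.ptv_volume <= 0 or self.organ_volume <= 0:
            raise ConfigError("volumes must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigError("overlap_fraction must lie in [0, 1]")
        if abs(self.dth.sum() - 1.0) > 1e-9:
            raise ConfigError("DTH mass must sum to 1")

    def feature_vector(self) -> np.ndarray:
        """Raw (unstandardized) feature vector: DTH ++ log-volumes ++ overlap."""
        return np.concatenate([
            self.dth,
            [np.log(self.ptv_volume), np.log(self.organ_volume),
             self.overlap_fraction],
        ])


@dataclass
class GeometryScores:
    """Coordinates of one patient in a trained geometry PCA basis."""

    pc_scores: np.ndarray
    patient_id: str = ""

    @property
    def pc1(self) -> float:
        return float(self.pc_scores[0])


def signed_distance_histogram(ptv: StructureMask, organ: StructureMask,
                              bin_edges: np.ndarray = DEFAULT_DTH_EDGES,
                              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                              ) -> np.ndarray:
    """Normalized histogram of signed distances from organ voxels to the PTV.

    Distances are Euclidean (mm, via a distance transform honouring voxel
    spacing), negative for organ voxels inside the PTV, and clamped to the
    histogram range ends.
    """
    if ptv.voxels.shape != organ.voxels.shape:
        raise GridMismatchError("PTV and organ masks must share one grid")
    if ptv.voxel_count == 0:
        raise EmptyStructureError("PTV mask is empty")
    if organ.voxel_count == 0:
        raise EmptyStructureError(f"organ {organ.name!r} mask is empty")
    outside = ndimage.distance_transform_edt(~ptv.voxels, sampling=spacing)
    inside = ndimage.distance_transform_edt(ptv.voxels, sampling=spacing)
    signed = np.where(ptv.voxels, -inside, outside)
    d = signed[organ.voxels]
    d = np.clip(d, bin_edges[0], bin_edges[-1] - 1e-9)
    hist, _ = np.histogram(d, bins=bin_edges)
    return hist / d.size


def summarize_geometry(ptv: StructureMask, organ: StructureMask,
                       spacing: tuple[float, float, float],
                       bin_edges: np.ndarray = DEFAULT_DTH_EDGES,
                       field_edge_mm: float = 30.0,
                       patient_id: str = "") -> GeometrySummary:
    """Build the full GeometrySummary for one (PTV, organ) pair of masks.

    ``out_of_field_fraction`` is the DTH mass beyond ``field_edge_mm`` from
    the PTV surface — a proxy for the organ portion outside the tangential
    fields.
    """
    dth = signed_distance_histogram(ptv, organ, bin_edges, spacing)
    voxvol = float(np.prod(spacing)) / 1000.0
    overlap_vox = int((ptv.voxels & organ.voxels).sum())
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return GeometrySummary(
        ptv_volume=ptv.voxel_count * voxvol,
        organ_volume=organ.voxel_count * voxvol,
        overlap_fraction=overlap_vox / organ.voxel_count,
        out_of_field_fraction=float(dth[centers > field_edge_mm].sum()),
        dth=dth,
        dth_edges=np.asarray(bin_edges, dtype=float),
        patient_id=patient_id,
        organ=organ.name,
    )


class GeometryPCA:
    """PCA basis over standardized geometry feature vectors.

    Features are standardized by training mean/SD; zero-variance features
    are dropped (with a warning) and recorded.  Component signs are fixed so
    that the loading on ``overlap_fraction`` is >= 0 (falling back to the
    largest-magnitude loading when overlap is degenerate), which keeps PC1
    percentile bounds comparable across retrainings.

    Parameters
    ----------
    n_components : int or None
        Retained components; ``None`` keeps the smallest number explaining
        >= ``explained_variance_target`` of training variance, capped at
        ``max_components``.
    """

    def __init__(self, n_components: int | None = None,
                 explained_variance_target: float = 0.95,
                 max_components: int = 5,
                 dth_sd_floor: float = 0.05) -> None:
        self.n_components = n_components
        self.explained_variance_target = explained_variance_target
        self.max_components = max_components
        self.dth_sd_floor = dth_sd_floor
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None
        self.components_: np.ndarray | None = None
        self.explained_variance_: np.ndarray | None = None
        self.explained_variance_ratio_: np.ndarray | None = None
        self.dropped_features_: list[int] = []

    @property
    def fitted(self) -> bool:
        return self.components_ is not None

    def fit(self, summaries: list[GeometrySummary]) -> "GeometryPCA":
        X = np.array([s.feature_vector() for s in summaries])
        n, p = X.shape
        want = self.n_components or 1
        if n < want + 2:
            raise DataError(
                f"need at least n_components + 2 = {want + 2} patients, got {n}")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        # DTH bins are commensurable mass fractions; flooring their
        # standardization SD at a fraction of the block RMS keeps
        # sparsely-varying bins from dominating the scaled space (and keeps
        # extrapolated scores directionally meaningful).
        n_dth = summaries[0].dth.size
        dth_sd = self.sd_[:n_dth]
        rms = float(np.sqrt(np.mean(dth_sd ** 2)))
        if rms > 0 and self.dth_sd_floor > 0:
            self.sd_[:n_dth] = np.where(dth_sd > 1e-12,
                                        np.maximum(dth_sd,
                                                   self.dth_sd_floor * rms),
                                        dth_sd)
        self.keep_ = self.sd_ > 1e-12
        self.dropped_features_ = list(np.nonzero(~self.keep_)[0])
        if self.dropped_features_:
            warnings.warn(
                f"{len(self.dropped_features_)} zero-variance geometry "
                "feature(s) dropped before PCA", stacklevel=2)
        Z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        # SVD of the centered standardized matrix = eigendecomposition of
        # the sample covariance (ddof=1 scaling applied to the variances).
        _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
        var = svals ** 2 / (n - 1)
        if self.n_components is not None:
            k = min(self.n_components, Vt.shape[0])
        else:
            ratio = var / var.sum()
            k = int(np.searchsorted(np.cumsum(ratio),
                                    self.explained_variance_target) + 1)
            k = min(k, self.max_components, Vt.shape[0])
        comps = Vt[:k]
        comps = self._fix_signs(comps)
        self.components_ = comps
        self.explained_variance_ = var[:k]
        self.explained_variance_ratio_ = var[:k] / var.sum()
        return self

    def _fix_signs(self, comps: np.ndarray) -> np.ndarray:
        kept = np.nonzero(self.keep_)[0]
        # overlap_fraction is the last raw feature
        overlap_raw = self.mean_.size - 1
        pos = np.nonzero(kept == overlap_raw)[0]
        out = comps.copy()
        for i, c in enumerate(out):
            if pos.size and abs(c[pos[0]]) > 1e-12:
                ref = c[pos[0]]
            else:
                ref = c[np.argmax(np.abs(c))]
            if ref < 0:
                out[i] = -c
        return out

    def transform(self, summary: GeometrySummary) -> GeometryScores:
        """Project one patient's standardized features onto the basis."""
        if not self.fitted:
            raise ModelError("geometry PCA is not fitted")
        x = summary.feature_vector()
        if x.size != self.mean_.size:
            raise DataError(
                f"feature vector length {x.size} != training length "
                f"{self.mean_.size}")
        z = (x[self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        return GeometryScores(self.components_ @ z, patient_id=summary.patient_id)

    def transform_many(self, summaries: list[GeometrySummary]) -> np.ndarray:
        """Score matrix (n_patients, n_components)."""
        return np.array([self.transform(s).pc_scores for s in summaries])
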