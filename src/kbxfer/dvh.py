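"""Cumulative dose-volume histograms and scalar dose-volume metrics.

The cumulative convention throughout the package is inclusive:
``V(d)`` is the fraction of the structure's volume receiving a dose of at
least ``d`` Gy.  All model-facing DVHs live on one shared uniform dose axis
(default 0-60 Gy at 0.1 Gy bins for a 40 Gy prescription) so that curves
from different patients and models can be averaged and decomposed by PCA
without resampling at every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyStructureError, GridMismatchError

logger = logging.getLogger(__name__)

#: Structure labels understood by the pipeline.
KNOWN_STRUCTURES = ("PTV", "IPSI_LUNG", "CONTRA_LUNG", "HEART", "CONTRA_BREAST")

DEFAULT_BIN_WIDTH = 0.1  # Gy
DEFAULT_AXIS_MAX = 60.0  # Gy, 1.5 x a 40 Gy prescription


def default_dose_axis(bin_width: float = DEFAULT_BIN_WIDTH,
                      axis_max: float = DEFAULT_AXIS_MAX) -> np.ndarray:
    """Shared uniform dose axis (bin edges, Gy) used by every model stage."""
    n = int(round(axis_max / bin_width))
    return np.linspace(0.0, axis_max, n + 1)


@dataclass
class DoseDistribution:
    """A 3D absorbed-dose grid with voxel geometry and prescription metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Absorbed dose per voxel in Gy; finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths in mm along each axis; strictly positive.
    prescription : float
        Prescribed dose in Gy (default regimen: 40 Gy in 15 fractions).
    fractions : int
        Number of treatment fractions.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    prescription: float = 40.0
    fractions: int = 15

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigError("dose grid must be 3-dimensional")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ConfigError("dose values must be finite and >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError("voxel spacing must be three positive lengths (mm)")
        if self.prescription <= 0:
            raise ConfigError("prescription must be positive")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class StructureMask:
    """A boolean organ/target mask congruent with a dose grid."""

    name: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ConfigError("structure mask must be 3-dimensional")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def volume_cc(self, spacing: tuple[float, float, float]) -> float:
        return self.voxel_count * float(np.prod(spacing)) / 1000.0


@dataclass
class CumulativeDVH:
    """A cumulative DVH on a uniform dose axis.

    ``volume_fraction[k]`` is the fraction of structure volume receiving at
    least ``dose_axis[k]`` Gy; it starts at 1, is non-increasing, and is
    clipped to [0, 1].
    """

    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    organ: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_axis.shape != self.volume_fraction.shape:
            raise ConfigError("dose_axis and volume_fraction must align")
        _check_uniform_axis(self.dose_axis)
        v = self.volume_fraction
        if abs(v[0] - 1.0) > 1e-9:
            raise ConfigError("cumulative DVH must start at volume fraction 1")
        if np.any(np.diff(v) > 1e-12):
            raise ConfigError("cumulative DVH must be non-increasing")
        if v[-1] < -1e-12 or np.any(v > 1 + 1e-12):
            raise ConfigError("volume fractions must lie in [0, 1]")

    @property
    def bin_width(self) -> float:
        return float(self.dose_axis[1] - self.dose_axis[0])


@dataclass
class DVHMetrics:
    """Scalar dose-volume metrics extracted from one cumulative DVH.

    ``v_at_dose`` maps each requested threshold (Gy as float, or a string
    like ``"95%"`` meaning percent of prescription) to the percent volume
    receiving at least that dose.  ``d_at_volume`` maps a volume percentile
    to the minimum dose (Gy) received by the hottest that-much of the
    structure.
    """

    mean_dose: float
    v_at_dose: dict = field(default_factory=dict)
    d_at_volume: dict = field(default_factory=dict)


def _check_uniform_axis(axis: np.ndarray) -> None:
    if axis.ndim != 1 or axis.size < 2:
        raise ConfigError("dose axis needs at least two edges")
    if abs(axis[0]) > 1e-12:
        raise ConfigError("dose axis must start at 0 Gy")
    steps = np.diff(axis)
    if steps[0] <= 0 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ConfigError("dose axis must be uniformly spaced")


def compute_cumulative_dvh(dose: DoseDistribution, mask: StructureMask,
                           bin_width: float = DEFAULT_BIN_WIDTH,
                           axis_max: float | None = None) -> CumulativeDVH:
    """Compute a cumulative DVH by voxel counting.

    The value at bin edge ``d`` is the number of masked voxels with dose
    >= ``d`` (inclusive) divided by the masked voxel count — exact, with no
    partial-volume weighting: the mask is authoritative.

    Parameters
    ----------
    bin_width : float
        Uniform dose bin width in Gy.
    axis_max : float, optional
        Top of the dose axis; defaults to the smallest multiple of
        ``bin_width`` strictly above the maximum masked dose.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    if dose.values.shape != mask.voxels.shape:
        raise GridMismatchError(
            f"dose grid {dose.values.shape} and mask {mask.voxels.shape} differ")
    doses = dose.values[mask.voxels]
    if doses.size == 0:
        raise EmptyStructureError(f"structure {mask.name!r} has no voxels")
    if axis_max is None:
        axis_max = (np.floor(doses.max() / bin_width) + 1) * bin_width
    n_bins = int(round(axis_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    # counts[k] = voxels in [edges[k], edges[k+1]); a dose exactly on an edge
    # falls in the bin to its right, so the reversed cumulative sum counts
    # doses >= edge inclusively.  Doses above the axis top stay in the tail.
    counts = np.histogram(doses, bins=np.append(edges, np.inf))[0]
    at_least = counts[::-1].cumsum()[::-1]
    vf = at_least[:-1] / doses.size
    vf = np.append(vf, (doses >= edges[-1]).sum() / doses.size)
    return CumulativeDVH(edges, vf, organ=mask.name)


def resample_dvh(dvh: CumulativeDVH, target_axis: np.ndarray) -> CumulativeDVH:
    """Linearly interpolate a cumulative DVH onto a new uniform axis.

    Values beyond the source maximum dose are 0; monotonicity is preserved
    because linear interpolation of a non-increasing curve is non-increasing.
    """
    target_axis = np.asarray(target_axis, dtype=float)
    _check_uniform_axis(target_axis)
    vf = np.interp(target_axis, dvh.dose_axis, dvh.volume_fraction,
                   left=dvh.volume_fraction[0], right=0.0)
    return CumulativeDVH(target_axis, vf, organ=dvh.organ,
                         patient_id=dvh.patient_id)


def _v_at(dvh: CumulativeDVH, dose_gy: float) -> float:
    """Percent volume receiving >= dose_gy, by linear interpolation."""
    return 100.0 * float(np.interp(dose_gy, dvh.dose_axis, dvh.volume_fraction,
                                   right=0.0))


def _d_at(dvh: CumulativeDVH, volume_pct: float) -> float:
    """Minimum dose (Gy) to the hottest volume_pct of the structure.

    Returns the largest dose at which the interpolated cumulative curve is
    still >= the target fraction (tie-break on flat segments: largest dose).
    """
    t = volume_pct / 100.0
    vf = dvh.volume_fraction
    if t > vf[0]:
        logger.info("requested D at %.3g%% volume exceeds V(0); returning 0 Gy",
                    volume_pct)
        return 0.0
    idx = np.nonzero(vf >= t)[0]
    i = int(idx[-1])
    if i == vf.size - 1:
        return float(dvh.dose_axis[-1])
    d0, d1 = dvh.dose_axis[i], dvh.dose_axis[i + 1]
    v0, v1 = vf[i], vf[i + 1]
    # v1 < t <= v0 here, so the segment is strictly decreasing
    return float(d0 + (v0 - t) / (v0 - v1) * (d1 - d0))


def _resolve_threshold(threshold, prescription: float) -> float:
    """A numeric threshold is Gy; '95%' means 95% of the prescription."""
    if isinstance(threshold, str):
        if not threshold.endswith("%"):
            raise ConfigError(f"dose threshold {threshold!r} not understood")
        return float(threshold[:-1]) / 100.0 * prescription
    return float(threshold)


def dvh_metrics(dvh: CumulativeDVH, prescription: float,
                v_thresholds: list | None = None,
                d_percentiles: list | None = None) -> DVHMetrics:
    """Scalar metrics of a cumulative DVH.

    The mean dose is the integral of the cumulative curve over dose
    (trapezoid on the bin grid) — an identity of the cumulative form.
    V-metrics use linear interpolation of the curve; D-metrics invert it.
    """
    mean_dose = float(np.trapezoid(dvh.volume_fraction, dvh.dose_axis))
    v_map = {}
    for thr in (v_thresholds or []):
        v_map[thr] = _v_at(dvh, _resolve_threshold(thr, prescription))
    d_map = {}
    for pct in (d_percentiles or []):
        d_map[pct] = _d_at(dvh, float(pct))
    return DVHMetrics(mean_dose=mean_dose, v_at_dose=v_map, d_at_volume=d_map)


def mean_dose(dvh: CumulativeDVH) -> float:
    """Mean dose (Gy) from the cumulative-curve integral."""
    return float(np.trapezoid(dvh.volume_fraction, dvh.dose_axis))


def v_at_dose(dvh: CumulativeDVH, threshold, prescription: float = 40.0) -> float:
    """Percent volume receiving at least the threshold (Gy or '% of Rx')."""
    return _v_at(dvh, _resolve_threshold(threshold, prescription))


def d_at_volume(dvh: CumulativeDVH, volume_pct: float) -> float:
    """Minimum dose to the hottest ``volume_pct`` percent of the structure."""
    return _d_at(dvh, volume_pct)
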