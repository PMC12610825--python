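"""File formats: DVH/band CSV exchange, dose/mask containers, report JSON.

All CSV numeric payloads are written with 17 significant digits so a
write -> read round trip reproduces float64 arrays bitwise.  The report
JSON is canonicalized (sorted keys, floats fixed to 12 significant digits)
so byte-level determinism is testable.
"""

from __future__ import annotations

import csv
import hashlib
import json

import numpy as np

from .dvh import CumulativeDVH, DoseDistribution, StructureMask
from .errors import DataError
from .model import PredictionBand

DVH_HEADER = ["patient_id", "organ", "dose_Gy", "volume_fraction"]
BAND_HEADER = ["patient_id", "organ", "model_id", "dose_Gy",
               "lower", "mean", "upper"]
_FMT = "%.17g"


# ---------------------------------------------------------------------------
# DVH CSV exchange format
# ---------------------------------------------------------------------------

def write_dvh_csv(dvhs: list[CumulativeDVH], path) -> None:
    """One row per bin edge: patient_id,organ,dose_Gy,volume_fraction."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DVH_HEADER)
        for dvh in dvhs:
            for d, v in zip(dvh.dose_axis, dvh.volume_fraction):
                w.writerow([dvh.patient_id, dvh.organ, _FMT % d, _FMT % v])


def read_dvh_csv(path) -> list[CumulativeDVH]:
    """Parse the DVH exchange CSV; malformed rows raise line-numbered errors."""
    groups: dict[tuple[str, str], list[tuple[float, float]]] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != DVH_HEADER:
            raise DataError(f"{path}: line 1: expected header "
                            f"{','.join(DVH_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise DataError(f"{path}: line {lineno}: expected 4 fields, "
                                f"got {len(row)}")
            pid, organ, d, v = row
            try:
                pair = (float(d), float(v))
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            key = (pid, organ)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(pair)
    out = []
    for pid, organ in order:
        arr = np.array(groups[(pid, organ)])
        out.append(CumulativeDVH(arr[:, 0], arr[:, 1], organ=organ,
                                 patient_id=pid))
    return out


# ---------------------------------------------------------------------------
# Prediction band CSV
# ---------------------------------------------------------------------------

def write_bands_csv(bands: list[PredictionBand], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(BAND_HEADER)
        for b in bands:
            axis = b.mean.dose_axis
            for i, d in enumerate(axis):
                w.writerow([b.patient_id, b.mean.organ, b.model_id, _FMT % d,
                            _FMT % b.lower.volume_fraction[i],
                            _FMT % b.mean.volume_fraction[i],
                            _FMT % b.upper.volume_fraction[i]])


def read_bands_csv(path) -> list[PredictionBand]:
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != BAND_HEADER:
            raise DataError(f"{path}: line 1: expected header "
                            f"{','.join(BAND_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 7:
                raise DataError(f"{path}: line {lineno}: expected 7 fields, "
                                f"got {len(row)}")
            try:
                vals = [float(x) for x in row[3:]]
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            key = tuple(row[:3])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(vals)
    out = []
    for key in order:
        pid, organ, mid = key
        arr = np.array(groups[key])
        axis = arr[:, 0]
        mk = lambda col: CumulativeDVH(axis, arr[:, col], organ=organ,
                                       patient_id=pid)
        out.append(PredictionBand(mk(1), mk(2), mk(3), model_id=mid,
                                  patient_id=pid))
    return out


# ---------------------------------------------------------------------------
# Dose/mask container (HDF5)
# ---------------------------------------------------------------------------

def write_patient_container(path, dose: DoseDistribution,
                            masks: dict[str, StructureMask]) -> None:
    """Single-file hierarchical container: datasets ``dose``, ``spacing``,
    one boolean dataset per structure; metadata ``prescription_Gy`` and
    ``fractions``."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("dose", data=dose.values)
        f.create_dataset("spacing", data=np.asarray(dose.spacing))
        f.attrs["prescription_Gy"] = dose.prescription
        f.attrs["fractions"] = dose.fractions
        g = f.create_group("structures")
        for name, mask in masks.items():
            g.create_dataset(name, data=mask.voxels)


def read_patient_container(path) -> tuple[DoseDistribution,
                                          dict[str, StructureMask]]:
    import h5py
    with h5py.File(path, "r") as f:
        dose = DoseDistribution(values=f["dose"][()],
                                spacing=tuple(f["spacing"][()]),
                                prescription=float(f.attrs["prescription_Gy"]),
                                fractions=int(f.attrs["fractions"]))
        masks = {name: StructureMask(name, f["structures"][name][()])
                 for name in f["structures"]}
    return dose, masks


# ---------------------------------------------------------------------------
# Canonical report JSON
# ---------------------------------------------------------------------------

def _canonical(obj):
    """Round floats to 12 significant digits and unwrap numpy types so the
    serialized report is byte-deterministic."""
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_canonical(v) for v in np.asarray(obj).tolist()] \
            if isinstance(obj, np.ndarray) else [_canonical(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if np.isnan(x):
            return None
        return float(f"{x:.12g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def dump_report_json(doc: dict, path=None) -> str:
    """Canonical JSON text (sorted keys, fixed float format)."""
    text = json.dumps(_canonical(doc), sort_keys=True, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(doc: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    return hashlib.sha256(
        json.dumps(_canonical(doc), sort_keys=True).encode()).hexdigest()[:16]
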