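import numpy as np
import pytest

from kbxfer.dvh import CumulativeDVH, default_dose_axis
from kbxfer.geometry import GeometrySummary
from kbxfer.model import PredictionBand
from kbxfer.simulate import make_dth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def axis():
    return default_dose_axis()


def linear_dvh(axis, d_max=50.0, patient_id="", organ="IPSI_LUNG"):
    """V(d) = 1 - d/d_max clipped at 0 — the closed-form test curve."""
    vf = np.clip(1.0 - axis / d_max, 0.0, 1.0)
    return CumulativeDVH(axis, vf, organ=organ, patient_id=patient_id)


def random_dvh(axis, rng, organ="IPSI_LUNG", patient_id=""):
    """A random valid cumulative DVH: sorted decreasing values from 1."""
    steps = rng.random(axis.size - 1)
    vf = np.concatenate([[1.0], 1.0 - np.cumsum(steps) / steps.sum()])
    vf = np.clip(vf, 0.0, 1.0)
    return CumulativeDVH(axis, vf, organ=organ, patient_id=patient_id)


def band_from_curves(axis, lower, mean, upper, model_id="m", patient_id="p"):
    mk = lambda v: CumulativeDVH(axis, v, organ="IPSI_LUNG",
                                 patient_id=patient_id)
    return PredictionBand(mk(lower), mk(mean), mk(upper), model_id=model_id,
                          patient_id=patient_id)


def summary_from_overlap(overlap, curvature=1.0, ptv=677.5, organ_vol=1500.0,
                         center=8.0, patient_id=""):
    """GeometrySummary from the parametric DTH family."""
    dth = make_dth(overlap, curvature, center)
    return GeometrySummary(ptv_volume=ptv, organ_volume=organ_vol,
                           overlap_fraction=overlap,
                           out_of_field_fraction=0.0, dth=dth,
                           patient_id=patient_id, organ="IPSI_LUNG")
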