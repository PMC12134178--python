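import numpy as np
import pytest

from qf3suite import binding_inference as bi
from qf3suite import synthetic_data as sd


@pytest.fixture
def binding_config():
    """Paper-scale binding-mode generator: donor 1-3 uM, acceptor 0-50 uM
    log-uniform, curve amplitude 0.2 rad, Kd 16.3 uM, per-ROI noise 0.01."""
    return sd.GeneratorConfig(
        seed=1,
        kd_uM=16.3,
        e_fret=sd.e_fret_for_delta_omega_max(0.2),
    )


@pytest.fixture
def collision_config():
    return sd.GeneratorConfig(seed=1, mode="collision")


def curve_from_points(x, y):
    """BindingCurve wrapper around explicit (x, y) points (one ROI each)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return bi.BindingCurve(
        free_acceptor_uM=x,
        delta_omega_mean=y,
        sem=np.zeros_like(x),
        n_rois=np.ones_like(x),
        bin_index=np.arange(x.size, dtype=float),
    )


@pytest.fixture
def make_curve():
    return curve_from_points
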