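import numpy as np
import pytest

from nucratio.synthgen import (NoiseModel, Nucleus, PartitionParams,
                               SceneTruth, make_scatter_scene, render_scene)

#: calibration used throughout the test scenes: probe in mild depletion
#: (readout near-linear in site abundance), ~1e4 photons/nucleus/channel
BASE_PARAMS = PartitionParams(m_tot=20.0, s_tot=0.0, kd=1.0,
                              v_n=1.0, v_c=19.0, alpha=3000.0)


@pytest.fixture(scope="session")
def base_params() -> PartitionParams:
    return BASE_PARAMS


@pytest.fixture(scope="session")
def small_scene() -> SceneTruth:
    """Five well-separated nuclei on a small frame."""
    return make_scatter_scene(5, s_tot_mean=5.0, s_tot_sd=0.4,
                              shape=(224, 224), seed=11)


@pytest.fixture(scope="session")
def rendered_small(small_scene, base_params):
    stack = render_scene(small_scene, base_params, NoiseModel(),
                         n_z=3, seed=42)
    return stack


@pytest.fixture()
def single_nucleus_scene():
    def make(radius=8.0, s_tot=5.0, shape=(96, 96), budget=1e4,
             phase="interphase"):
        nuc = Nucleus(id=1, y=(shape[0] - 1) / 2, x=(shape[1] - 1) / 2,
                      radius_px=radius, s_tot=s_tot,
                      standard_budget=budget, phase=phase)
        return SceneTruth(nuclei=[nuc], shape=shape)
    return make
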