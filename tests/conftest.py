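import numpy as np
import pytest

import capillux as cx


@pytest.fixture(scope="session")
def short_kymo_params():
    """A 2-s kymograph at study geometry, low noise."""
    return cx.KymoSimParams(duration_s=2.0, noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def short_kymo(short_kymo_params):
    kymo, markers, arrivals = cx.simulate_kymograph(short_kymo_params)
    return kymo, markers, arrivals


@pytest.fixture(scope="session")
def noiseless_single_cell():
    """One cell, no noise, no eye motion: fully deterministic render."""
    params = cx.KymoSimParams(
        duration_s=0.2,
        noise_sd=0.0,
        eye_motion=cx.EyeMotionParams(amplitude_um=0.0, drift_um_s=0.0),
        seed=0,
    )
    arrivals = np.array([1500.0])
    kymo, markers = cx.render_kymograph(arrivals, params)
    return kymo, markers, params


@pytest.fixture(scope="session")
def flat_bscan_fixture():
    """Noiseless flat-boundary B-scan: ILM 60, OS-RPE 170, 2 um/px."""
    params = cx.OctSimParams(n_cols=60, n_rows=220, speckle_sd=0.0, seed=0)
    bscan, ilm, rpe = cx.simulate_bscan(params)
    return bscan, ilm, rpe, params
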