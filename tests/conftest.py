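import numpy as np
import pytest

from mbgrowth import CurveSpec, RawWell, simulate_curve


@pytest.fixture
def noiseless_single_phase():
    """Noise-free single-exponential curve on a zero blank: growth at
    0.46 1/h from 5 h to 20 h, hard plateau afterwards, 9-min cycles.

    The plateau level is never reached inside phase 1, so the exponential
    segment is exact. Returns (RawWell, TruthRecord)."""
    spec = CurveSpec(blank_level=0.0, noise_sd=0.0, c0=0.02, mu1=0.46,
                     t_lag=5.0, t_phase1_end=20.0, plateau=40.0,
                     t_total=30.0, seed=0)
    return simulate_curve(spec)


@pytest.fixture
def simple_well():
    """Short hand-written well: flat blank at 10, then a jump."""
    t = np.arange(8) * 0.15
    bs = np.array([10.0, 10.0, 10.0, 10.0, 10.0, 12.0, 15.0, 20.0])
    return RawWell(well_id="A01", time=t, backscatter=bs)
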