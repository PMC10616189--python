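import numpy as np
import pytest

from xicalign.model import Xic, XicGroup


@pytest.fixture
def gaussian_group():
    """Single-precursor XIC group with one clean Gaussian peak at 60 s."""

    def make(run_id="runA", apex=60.0, sigma=5.0, amps=(1000.0, 700.0, 400.0),
             start=0.0, step=3.4, n=36, noise_sd=0.0, seed=0, baseline=0.0):
        rng = np.random.default_rng(seed)
        t = start + step * np.arange(n)
        traces = []
        for a in amps:
            v = baseline + a * np.exp(-((t - apex) ** 2) / (2 * sigma**2))
            if noise_sd:
                v = np.clip(v + rng.normal(0, noise_sd, n), 0, None)
            traces.append(Xic(t, v))
        return XicGroup("PEPX/2", run_id, [f"y{k+3}" for k in range(len(amps))], traces)

    return make
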