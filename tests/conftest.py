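import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import piecewisefc as pfc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_epochs(seed=0, C=3, T=64, N=12, fs=128.0, t0=-0.1):
    """A tiny valid EpochedEEG with random data and balanced-ish labels."""
    g = np.random.default_rng(seed)
    labels = np.array([0, 0, 1, 1] * (N // 4) + [0] * (N % 4))
    return pfc.EpochedEEG(
        data=g.standard_normal((C, T, N)),
        fs=fs,
        labels=labels[:N],
        channel_names=[f"ch{i}" for i in range(C)],
        t0=t0,
        subject_id=f"s{seed}",
    )


@pytest.fixture()
def epochs():
    return small_epochs()


@pytest.fixture(scope="session")
def planted_dataset():
    """Session-shared dataset: 10 subjects, 6 channels, one theta coupling
    planted target-only at pi/2 lag in [0.2, 0.5] s."""
    params = pfc.SimulationParams(
        M=10, C=6, N=60, fs=250.0,
        couplings=[pfc.PlantedCoupling(pair=(0, 1), band_center=6.5,
                                       phase_lag=np.pi / 2,
                                       window=(0.2, 0.5),
                                       condition="target")],
        snr=3.0, seed=7,
    )
    return pfc.simulate_dataset(params)


@pytest.fixture(scope="session")
def planted_windowed(planted_dataset):
    """Windowed per-condition wPLI for the shared planted dataset."""
    dataset, truth = planted_dataset
    gen = np.random.default_rng(99)
    per = [pfc.subject_connectivity(s, "theta", rng=gen) for s in dataset]
    scheme = pfc.make_fixed_windows((0.0, 0.8), 0.1)
    return pfc.stack_windowed(per, scheme), truth
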