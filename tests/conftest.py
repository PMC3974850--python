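import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sparklet import AcquisitionParams, CellMask, Movie, SynthConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionParams:
    """Short recording on a small frame for fast unit tests."""
    return AcquisitionParams(n_frames=300, frame_rate=150.0, pixel_size=0.4,
                             frame_shape=(96, 96))


@pytest.fixture(scope="session")
def one_cell_cfg() -> SynthConfig:
    return SynthConfig(n_cells=1, sites_per_cell=1, site_rate=0.0,
                       global_event_rate=0.0, noise_sd=0.0, rng_seed=7)


def constant_movie(value: float = 500.0, n_frames: int = 120,
                   shape=(32, 32)) -> tuple[Movie, CellMask]:
    acq = AcquisitionParams(n_frames=n_frames, frame_shape=shape)
    data = np.full((n_frames,) + shape, value, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    labels[4:-4, 4:-4] = 1
    return Movie(data, acq), CellMask(labels, pixel_size=acq.pixel_size)
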