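import numpy as np
import pytest

from scaphonet.geometry import OrientedBox, normalize_angle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_boxes(rng, n, span=100.0, wmin=2.0, wmax=40.0):
    """Seeded random normalized oriented boxes."""
    out = []
    for _ in range(n):
        out.append(normalize_angle(OrientedBox(
            cx=float(rng.uniform(0, span)), cy=float(rng.uniform(0, span)),
            w=float(rng.uniform(wmin, wmax)), h=float(rng.uniform(wmin, wmax)),
            theta=float(rng.uniform(-np.pi, np.pi)))))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic phantom cohort shared by cheap tests."""
    from scaphonet.phantom import PhantomConfig, generate_cohort
    return generate_cohort(PhantomConfig(n_fracture=6, n_normal=6, seed=7))


@pytest.fixture(scope="session")
def small_crops(small_cohort):
    from scaphonet.phantom import make_crop_dataset
    records, _ = small_cohort
    crops, tfs = make_crop_dataset(records, 0.25, 64)
    return crops, tfs
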