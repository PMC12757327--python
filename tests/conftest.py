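import numpy as np
import pytest

import mrcomplete as mc


@pytest.fixture(scope="session")
def carton_train():
    """64 procedural carton clouds — the desk-scale training set."""
    return mc.carton_dataset(64, seed=0)


@pytest.fixture(scope="session")
def carton_gan(carton_train):
    """Desk-preset pretrained carton GAN (200 epochs, batch 32, seed 0).

    Session-scoped: pretraining takes minutes and several tests share it.
    """
    cfg = mc.TrainConfig.desk(seed=0, class_tag="carton")
    return mc.pretrain_gan(carton_train, cfg)


@pytest.fixture(scope="session")
def carton_cases(carton_gan):
    """Eight held-out cartons, half-space-cropped and completed.

    Each entry is ``(truth, partial, result)`` with the partial kept in
    the truth's normalized frame. Completions run 300 inversion
    iterations — the experiments' convergence budget (see the methods
    note); other settings are the defaults.
    """
    rng = np.random.default_rng(100)
    cases = []
    for i in range(8):
        truth = mc.carton_dataset(1, seed=200 + i)[0]
        normal = rng.standard_normal(3)
        normal /= np.linalg.norm(normal)
        partial = mc.simulate_partial_scan(
            truth, mc.ScanSpec(occlusion=("halfspace", normal, 0.0), seed=i)
        )
        res = mc.invert(
            carton_gan.generator, carton_gan.discriminators, partial,
            mc.InversionConfig(seed=i, n_iterations=300), truth=truth,
        )
        cases.append((truth, partial, res))
    return cases


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, scale=1.0):
    return rng.uniform(-scale, scale, size=(n, 3))
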