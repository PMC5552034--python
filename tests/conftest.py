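import numpy as np
import pytest

import sstcoach as sc


@pytest.fixture(scope="session")
def templates():
    return sc.build_face_templates()


@pytest.fixture(scope="session")
def smile_model(templates):
    happy, neutral = sc.gen_smile_training_set(seed=11, templates=templates)
    return sc.train_smile_model(happy, neutral)


@pytest.fixture(scope="session")
def cohort():
    return sc.gen_cohort(n_models=12, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_frame(points, t=0.0, yaw=0.0, pitch=0.0):
    return sc.LandmarkFrame(points=np.asarray(points, float), t=t, yaw=yaw, pitch=pitch)
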