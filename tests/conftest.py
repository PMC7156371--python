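import numpy as np
import pytest

import chewgear as cg


@pytest.fixture(scope="session")
def rec_noiseless():
    """Default noiseless recording (with scene drift) plus pipeline result."""
    rec = cg.build_recording(
        cg.SyntheticScenario(
            noise_sigma_mm=0.0, drift_translation_mm=0.5, drift_rotation_deg=0.5
        )
    )
    res = cg.run_pipeline_data(rec.config, rec.dataset, rec.landmarks)
    return rec, res


@pytest.fixture(scope="session")
def rec_noisy():
    """Recording at the study's marker precision (sigma = 0.15 mm)."""
    rec = cg.build_recording(
        cg.SyntheticScenario(
            noise_sigma_mm=0.15, seed=3, drift_translation_mm=0.5, drift_rotation_deg=0.5
        )
    )
    res = cg.run_pipeline_data(rec.config, rec.dataset, rec.landmarks)
    return rec, res


@pytest.fixture(scope="session")
def rec_plain():
    """Noiseless, drift-free recording: the lab frame is already cranial and
    trajectories are exactly the generator's closed forms (no filter pass)."""
    return cg.build_recording(
        cg.SyntheticScenario(
            noise_sigma_mm=0.0, drift_translation_mm=0.0, drift_rotation_deg=0.0
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
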