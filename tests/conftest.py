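import numpy as np
import pytest
from hypothesis import settings

import scoliosim as ss

# Property tests must be reproducible run to run.
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_model():
    """Undeformed base model at the reference anthropometrics."""
    return ss.build_base_model(14.0, "Female", 161.2, 47.5)


@pytest.fixture(scope="session")
def subject_geometry():
    """A right-convex main-thoracic curve (apex T8, Cobb 22 deg)."""
    return ss.generate_curve(apex="T8", cobb_target=22.0, convexity="right", height_cm=161.2)


@pytest.fixture(scope="session")
def ais_model(base_model, subject_geometry):
    return ss.apply_subject(base_model, subject_geometry)


@pytest.fixture(scope="session")
def twin_model(ais_model):
    return ss.make_undeformed_twin(ais_model)


@pytest.fixture(scope="session")
def standing_result(ais_model):
    posture = ss.standing_posture(ais_model)
    result = ss.solve(ss.assemble_system(ais_model, posture, None))
    return posture, result


@pytest.fixture(scope="session")
def twin_standing_result(twin_model):
    posture = ss.standing_posture(twin_model)
    result = ss.solve(ss.assemble_system(twin_model, posture, None))
    return posture, result


def make_rect_landmarks(
    level="T8",
    center_sag=(0.0, 100.0),
    center_fro=(0.0, 100.0),
    half_len=15.0,
    half_height=10.0,
    spinous_dz=0.0,
):
    """Axis-aligned rectangular vertebra landmarks (zero rotations)."""
    cx, cy = center_sag
    cz, _ = center_fro
    sag = {
        "UA": np.array([cx + half_len, cy + half_height]),
        "UP": np.array([cx - half_len, cy + half_height]),
        "LA": np.array([cx + half_len, cy - half_height]),
        "LP": np.array([cx - half_len, cy - half_height]),
    }
    fro = {
        "UL": np.array([cz + half_len, cy + half_height]),
        "UR": np.array([cz - half_len, cy + half_height]),
        "LL": np.array([cz + half_len, cy - half_height]),
        "LR": np.array([cz - half_len, cy - half_height]),
    }
    return ss.VertebraLandmarks(
        level=level, sagittal=sag, frontal=fro, spinous=np.array([cz + spinous_dz, cy])
    )
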