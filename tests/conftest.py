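import math

import numpy as np
import pytest

from acsftune import (
    AngleTerm,
    BondTerm,
    ConformerSwitch,
    CutoffSpec,
    Frame,
    OscillatorSpec,
    generate_trajectory,
)


def water_geometry(r_oh: float = 0.96, angle_deg: float = 104.5) -> Frame:
    """Planar triatomic: O at origin, two H at r_oh with the given inner angle."""
    t = math.radians(angle_deg)
    return Frame(
        ("O", "H", "H"),
        np.array(
            [[0.0, 0.0, 0.0], [r_oh, 0.0, 0.0], [r_oh * math.cos(t), r_oh * math.sin(t), 0.0]]
        ),
    )


@pytest.fixture
def water_frame() -> Frame:
    return water_geometry()


@pytest.fixture
def hard_cutoff() -> CutoffSpec:
    return CutoffSpec(7.0, "hard")


@pytest.fixture
def soft_cutoff() -> CutoffSpec:
    return CutoffSpec(7.0, "soft")


@pytest.fixture
def water_spec() -> OscillatorSpec:
    """Oscillating water: O–H ~ N(0.96, 0.03²) Å, angle ~ N(104.5°, 3°)."""
    return OscillatorSpec(
        water_geometry(),
        bonds=(BondTerm(0, 1, 0.96, 0.03), BondTerm(0, 2, 0.96, 0.03)),
        angles=(AngleTerm(1, 0, 2, math.radians(104.5), math.radians(3.0)),),
        seed=0,
    )


@pytest.fixture
def water_trajectory(water_spec) -> "Trajectory":
    return generate_trajectory(water_spec, 400, seed=11)


@pytest.fixture
def two_conformer_spec() -> OscillatorSpec:
    """Triatomic hopping between O–H 0.96 Å/104.5° and 1.15 Å/115° conformers."""
    return OscillatorSpec(
        water_geometry(0.96, 104.5),
        bonds=(BondTerm(0, 1, None, 0.02), BondTerm(0, 2, None, 0.02)),
        angles=(AngleTerm(1, 0, 2, None, math.radians(3.0)),),
        conformer=ConformerSwitch(water_geometry(1.15, 115.0), 0.5),
        seed=0,
    )


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return Q, t


def apply_rigid(frame: Frame, Q: np.ndarray, t: np.ndarray) -> Frame:
    return Frame(frame.elements, frame.coordinates @ Q.T + t)
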