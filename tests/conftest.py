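import numpy as np
import pytest

import stiffarm as sa
from stiffarm.calibration import SamplingGrid, calibrate
from stiffarm.lookup_table import (build_initial_table, finalize_table,
                                   verify_table)

ALL_S = tuple(float(s) for s in range(3, 14))


@pytest.fixture(scope="session")
def default_arm():
    return sa.make_default_arm()


@pytest.fixture(scope="session")
def calib20(default_arm):
    """Sparse (20 deg) calibration with the full stiffness range."""
    grid = SamplingGrid((15.0, 85.0, 20.0), (20.0, 130.0, 20.0), ALL_S)
    return calibrate(default_arm, grid)


@pytest.fixture(scope="session")
def table20(default_arm, calib20):
    """Final (verified, achieved-keyed) table from the 20 deg calibration."""
    table = build_initial_table(calib20)
    achieved, ok, _ = verify_table(table, default_arm)
    return finalize_table(table, achieved, ok)


@pytest.fixture(scope="session")
def calib10_s8(default_arm):
    grid = SamplingGrid((15.0, 85.0, 10.0), (20.0, 130.0, 10.0), (8.0,))
    return calibrate(default_arm, grid)


def random_equation_system(rng):
    """A physically signed random 2-joint system (3-6 electrode columns).

    Columns follow the muscle sign structure: a column holds either the
    flexion or the extension row of each joint it spans, flexion entries
    positive, extension negative; about a third of eligible columns are
    biarticular.
    """
    from stiffarm.torque_solver import EquationSystem
    m = int(rng.integers(3, 7))
    A = np.zeros((4, m))
    for j in range(m):
        both = m >= 4 and rng.random() < 0.3
        joints = [0, 1] if both else [int(rng.integers(0, 2))]
        flex = rng.random() < 0.5
        for jt in joints:
            mag = rng.uniform(5.0, 45.0)
            A[2 * jt + (0 if flex else 1), j] = mag if flex else -mag
    S = rng.uniform(2.0, 14.0)
    pf = rng.uniform(0.0, 3.0, 2)
    pe = -rng.uniform(0.0, 3.0, 2)
    x = np.array([S - pf[0], -S - pe[0], S - pf[1], -S - pe[1]])
    return EquationSystem(x, A, S, np.array([50.0, 75.0]),
                          tuple(f"e{k}" for k in range(m)))
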