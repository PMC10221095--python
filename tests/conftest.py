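"""Shared fixtures: small synthetic systems with known ground truth."""

import numpy as np
import pytest

from rampclamp.structures import Atom, Structure
from rampclamp.synthetic import (
    InterfaceSpec,
    WT_INTERFACE_PAIRS,
    build_complex,
    jitter_trajectory,
)


@pytest.fixture(scope="session")
def wt_spec():
    return InterfaceSpec()


@pytest.fixture(scope="session")
def wt_complex(wt_spec):
    cplx, gt = build_complex(wt_spec, seed=0)
    return cplx, gt


@pytest.fixture(scope="session")
def small_spec():
    return InterfaceSpec(pairs=WT_INTERFACE_PAIRS[:4])


@pytest.fixture(scope="session")
def small_complex(small_spec):
    return build_complex(small_spec, seed=0)


@pytest.fixture(scope="session")
def wt_trajectory(wt_complex, wt_spec):
    cplx, gt = wt_complex
    traj, truth = jitter_trajectory(cplx, gt, wt_spec, n_frames=300, seed=11)
    return traj, truth


@pytest.fixture()
def two_chain_structure():
    """Minimal 2-chain, 6-atom structure for IO and partition tests."""
    atoms = [
        Atom(1, "N", "N", "GLY", 1, "A", [0.0, 0.0, 0.0]),
        Atom(2, "CA", "C", "GLY", 1, "A", [1.5, 0.0, 0.0]),
        Atom(3, "O", "O", "GLY", 1, "A", [2.2, 1.1, 0.3]),
        Atom(4, "N", "N", "ALA", 2, "B", [0.0, 4.0, 0.0]),
        Atom(5, "CA", "C", "ALA", 2, "B", [1.5, 4.0, 0.0]),
        Atom(6, "O", "O", "ALA", 2, "B", [2.2, 5.1, 0.3]),
    ]
    return Structure(atoms)


def random_rigid_motion(rng):
    """A uniformly random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t
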