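"""Shared fixtures: small analytic media and the two full synthetic
experiments (session-scoped; they back the acceptance checks)."""

import numpy as np
import pytest

from fusmrt import experiment, phantoms


@pytest.fixture()
def gel_medium_small():
    """Small all-gelatin block, 1 mm isotropic, centered origin."""
    shape = (24, 24, 24)
    spacing = (1e-3, 1e-3, 1e-3)
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    return phantoms.build_homogeneous_phantom(shape, spacing,
                                              gel_z_extent=-1.0, origin=origin)


@pytest.fixture()
def gel_medium_mid():
    """Mid-size all-gelatin block for diffusion/fit experiments."""
    shape = (48, 48, 56)
    spacing = (1e-3, 1e-3, 1.5e-3)
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    return phantoms.build_homogeneous_phantom(shape, spacing,
                                              gel_z_extent=-1.0, origin=origin)


def gaussian_q(medium, q0=5e5, sigma=(1e-3, 1e-3, 4e-3), center=(0, 0, 0)):
    xs = [medium.axis_coords(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    return q0 * np.exp(-((X - center[0]) ** 2) / (2 * sigma[0] ** 2)
                       - ((Y - center[1]) ** 2) / (2 * sigma[1] ** 2)
                       - ((Z - center[2]) ** 2) / (2 * sigma[2] ** 2))


@pytest.fixture(scope="session")
def homogeneous_result():
    """Full-size homogeneous-gelatin experiment (40 W / 28.7 s, R = 7,
    3 repeats) at the default study conditions."""
    return experiment.run_experiment(None, seed=20160922, base="homogeneous")


@pytest.fixture(scope="session")
def skull_result():
    """Full-size skull-shell experiment (125 W / 23.9 s, aberration-corrected,
    R = 7, 3 repeats) at the default study conditions."""
    return experiment.run_experiment(None, seed=20160922, base="skull")
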