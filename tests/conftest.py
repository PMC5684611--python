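"""Shared fixtures: small phantoms and one full surrogate run, computed once."""

import numpy as np
import pytest

from elfdosim import (
    UniformFieldSource,
    build_homogeneous_ellipsoid,
    build_homogeneous_sphere,
    solve_scalar_potential,
)
from elfdosim.pipeline import make_e99_forward
from elfdosim.validation import AdaptiveFitTrace, adaptive_fit


@pytest.fixture(scope="session")
def sphere_small():
    """30 mm homogeneous sphere at 3 mm voxels — cheap solver fixture."""
    return build_homogeneous_sphere(0.03, sigma=0.1, voxel_size_m=0.003)


@pytest.fixture(scope="session")
def sphere_small_solution(sphere_small):
    return solve_scalar_potential(
        sphere_small, UniformFieldSource(theta_deg=0.0, phi_deg=0.0)
    )


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Homogeneous triaxial ellipsoid, ~60^3 grid at 2 mm voxels."""
    return build_homogeneous_ellipsoid((0.04, 0.05, 0.058), sigma=0.1, voxel_size_m=0.002)


@pytest.fixture(scope="session")
def ellipsoid_adaptive_run(ellipsoid_phantom):
    """Adaptive surrogate fit of CNS E99th for the ellipsoid phantom.

    Returns (results, report, design, trace); shared across validation and
    acceptance tests because each forward solve is the expensive step.
    """
    forward = make_e99_forward(ellipsoid_phantom, label=1)
    trace = AdaptiveFitTrace()
    res, report, design = adaptive_fit(forward, threshold=5.0, p0=5, trace=trace)
    return res, report, design, trace
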