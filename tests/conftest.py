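"""Shared fixtures: meshes, operator bundles and baseline simulation runs.

Everything heavy is session-scoped so the three baseline eye infusions and
the three verification-sphere infusions are computed once per test run.
"""

import numpy as np
import pytest

from iopsim import (
    BASELINE_GEOMETRY,
    CORNEA_BASELINE,
    FAST,
    INTERMEDIATE,
    SCLERA_BASELINE,
    SLOW,
    SphericalShellSpec,
    assemble_system,
    build_geometry,
    generate_mesh,
    make_material,
    simulate_infusion,
    spherical_geometry,
)

SPHERE_RADIUS = 12.0
SPHERE_THICKNESS = 1.0  # h/R = 1/12, membrane regime


@pytest.fixture(scope="session")
def sphere_mesh():
    return generate_mesh(build_geometry(spherical_geometry(SPHERE_RADIUS, SPHERE_THICKNESS)), 0.3)


@pytest.fixture(scope="session")
def sphere_material():
    return make_material(1.1, 0.265, 0.35, 68.0)


@pytest.fixture(scope="session")
def sphere_spec(sphere_material):
    return SphericalShellSpec(SPHERE_RADIUS, SPHERE_THICKNESS, sphere_material)


@pytest.fixture(scope="session")
def sphere_bundle(sphere_mesh, sphere_material):
    return assemble_system(sphere_mesh, sphere_material, sphere_material)


@pytest.fixture(scope="session")
def sphere_runs(sphere_mesh, sphere_material, sphere_bundle):
    """Uniform-sphere infusions at the three rates."""
    return {
        p.name: simulate_infusion(
            sphere_mesh, sphere_material, sphere_material, p, bundle=sphere_bundle
        )
        for p in (FAST, INTERMEDIATE, SLOW)
    }


@pytest.fixture(scope="session")
def eye_section():
    return build_geometry(BASELINE_GEOMETRY)


@pytest.fixture(scope="session")
def eye_mesh(eye_section):
    return generate_mesh(eye_section, 0.25)


@pytest.fixture(scope="session")
def eye_bundle(eye_mesh):
    return assemble_system(eye_mesh, CORNEA_BASELINE, SCLERA_BASELINE)


@pytest.fixture(scope="session")
def baseline_eye_runs(eye_mesh, eye_bundle):
    """Baseline-material eye infusions at the three rates (default mesh/steps)."""
    return {
        p.name: simulate_infusion(
            eye_mesh, CORNEA_BASELINE, SCLERA_BASELINE, p, bundle=eye_bundle
        )
        for p in (FAST, INTERMEDIATE, SLOW)
    }


@pytest.fixture(scope="session")
def oracle_engine():
    from iopsim import OracleEngine

    return OracleEngine()


def nearly_elastic(e_modulus: float, nu: float = 0.49):
    """Material whose branches are numerically negligible (elastic limit)."""
    from iopsim.materials import ViscoelasticMaterial

    return ViscoelasticMaterial(
        equilibrium_modulus=e_modulus,
        branch_moduli=(1e-12, 1e-12),
        time_constants=(0.35, 68.0),
        poisson_ratio=nu,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
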