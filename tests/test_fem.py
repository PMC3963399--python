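"""Axisymmetric FE solver: statics, cavity coupling, time stepping, fields."""

import numpy as np
import pytest

from iopsim import (
    CORNEA_BASELINE,
    FAST,
    MMHG_IN_MPA,
    SCLERA_BASELINE,
    InfusionProtocol,
    SolverError,
    ThermalAnalogParams,
    assemble_system,
    build_geometry,
    compute_fields,
    enclosed_volume,
    generate_mesh,
    mesh_convergence_study,
    oracle_pressure,
    simulate_infusion,
    solve_elastic,
    spherical_geometry,
    thermal_analog_power,
    volume_change_linearized,
)
from conftest import SPHERE_RADIUS, SPHERE_THICKNESS, nearly_elastic

R_IN = SPHERE_RADIUS - SPHERE_THICKNESS / 2
R_OUT = SPHERE_RADIUS + SPHERE_THICKNESS / 2


def _lame_pressure(dv, a=R_IN, b=R_OUT, e=1.0, nu=0.49):
    """Exact thick-walled-sphere pressure for a cavity volume change (MPa)."""
    ua_per_p = (a**3 / (e * (b**3 - a**3))) * ((1 - 2 * nu) * a + (1 + nu) * b**3 / (2 * a**2))
    return dv / (4 * np.pi * a**2 * ua_per_p)


def test_elastic_sphere_matches_lame(sphere_bundle):
    p_mmhg, _ = solve_elastic(sphere_bundle, 1.0, 1.0, 15.0)
    assert p_mmhg * MMHG_IN_MPA == pytest.approx(_lame_pressure(15.0), rel=0.005)


def test_enclosed_volume_closed_forms(sphere_mesh):
    assert enclosed_volume(sphere_mesh) == pytest.approx(4 / 3 * np.pi * R_IN**3, rel=1e-6)
    # uniform radial inflation: dV = 4 pi a^2 u to first order
    center = np.array([0.0, sphere_mesh.section.scleral_center_z])
    rel = sphere_mesh.points - center
    u = 1e-3 * rel / np.linalg.norm(rel, axis=1, keepdims=True)
    dv = volume_change_linearized(sphere_mesh, u)
    assert dv == pytest.approx(4 * np.pi * R_IN**2 * 1e-3, rel=1e-3)


def test_coupling_vector_is_volume_gradient(sphere_mesh, sphere_bundle, rng):
    """g . u equals the linearised boundary-integral volume change, and the
    displaced-configuration volume to first order, for random fields."""
    u = 1e-4 * rng.standard_normal((sphere_mesh.n_nodes, 2))
    gu = float(sphere_bundle.g @ u.ravel())
    assert gu == pytest.approx(volume_change_linearized(sphere_mesh, u), rel=1e-12, abs=1e-15)
    exact = enclosed_volume(sphere_mesh, u) - enclosed_volume(sphere_mesh)
    assert gu == pytest.approx(exact, rel=2e-3)


def test_zero_modulus_rejected(sphere_bundle):
    with pytest.raises(SolverError):
        solve_elastic(sphere_bundle, 0.0, 0.0, 15.0)


@pytest.mark.parametrize("name", ["fast", "intermediate", "slow"])
def test_fe_matches_membrane_oracle_within_3_percent(sphere_runs, sphere_spec, name):
    """The independent closed-form thin-shell solution verifies the FE
    pressure history at every step, for all three rates."""
    res = sphere_runs[name]
    ref = oracle_pressure(sphere_spec, res.protocol, res.time[1:])
    dev = np.abs(res.diop_mmhg[1:] / ref - 1.0)
    assert dev.max() < 0.03


@pytest.mark.parametrize("name", ["fast", "intermediate", "slow"])
def test_volume_fidelity_every_step(baseline_eye_runs, name):
    res = baseline_eye_runs[name]
    assert np.abs(res.volume_residual).max() < 1e-3 * res.protocol.total_volume
    # second-order geometric gap stays below 0.1% of the infused volume too
    assert np.abs(res.geometric_volume_gap[-1]) < 1e-3 * res.protocol.total_volume


def test_pressure_history_invariants(baseline_eye_runs):
    for res in baseline_eye_runs.values():
        assert res.diop_mmhg[0] == 0.0
        assert res.injected_volume[0] == 0.0
        assert np.all(np.diff(res.diop_mmhg) >= -1e-10)
        assert res.iop_mmhg.min() >= res.protocol.baseline_iop


def test_rate_ordering_of_final_elevation(baseline_eye_runs):
    assert (
        baseline_eye_runs["fast"].final_diop
        > baseline_eye_runs["intermediate"].final_diop
        > baseline_eye_runs["slow"].final_diop
    )


def test_linearity_half_volume_halves_pressure(sphere_mesh, sphere_material, sphere_bundle):
    full = simulate_infusion(sphere_mesh, sphere_material, sphere_material, FAST, bundle=sphere_bundle)
    half_proto = InfusionProtocol(rate=FAST.rate / 2, duration=FAST.duration, name="fast")
    half = simulate_infusion(
        sphere_mesh, sphere_material, sphere_material, half_proto, bundle=sphere_bundle
    )
    np.testing.assert_allclose(half.diop_mmhg, 0.5 * full.diop_mmhg, rtol=1e-9, atol=1e-12)


def test_time_step_convergence(sphere_mesh, sphere_material, sphere_bundle):
    res1 = simulate_infusion(sphere_mesh, sphere_material, sphere_material, FAST, bundle=sphere_bundle)
    res2 = simulate_infusion(
        sphere_mesh, sphere_material, sphere_material, FAST, dt=0.005, bundle=sphere_bundle
    )
    assert abs(res2.final_diop / res1.final_diop - 1) < 0.005


def test_elastic_limit_is_rate_independent(sphere_mesh, sphere_bundle):
    """With negligible branch moduli the response matches a static elastic
    solve at each volume level and is identical across rates."""
    mat = nearly_elastic(0.265)
    bundle = assemble_system(sphere_mesh, mat, mat, disc=sphere_bundle.disc)
    finals = []
    for proto in (FAST, InfusionProtocol(rate=0.1, duration=150.0, name="slow")):
        res = simulate_infusion(sphere_mesh, mat, mat, proto, bundle=bundle)
        finals.append(res.final_diop)
        p_static, _ = solve_elastic(bundle, 0.265, 0.265, proto.total_volume)
        assert res.final_diop == pytest.approx(p_static, rel=0.005)
    assert finals[0] == pytest.approx(finals[1], rel=1e-9)


def test_limit_behaviour_fast_and_slow_durations(sphere_mesh, sphere_material, sphere_bundle):
    """Duration << tau_s approaches the E_inst elastic solve (5%); duration
    >> tau_l approaches the E_equ solve (10% at 20x tau_l)."""
    m = sphere_material
    very_fast = InfusionProtocol(rate=15.0 / 0.01, duration=0.01, name="impulse")
    res = simulate_infusion(sphere_mesh, m, m, very_fast, dt=0.001, bundle=sphere_bundle)
    p_inst, _ = solve_elastic(sphere_bundle, 1.1, 1.1, 15.0)
    assert abs(res.final_diop / p_inst - 1) < 0.05

    very_slow = InfusionProtocol(rate=15.0 / 1360.0, duration=1360.0, name="creep")
    res = simulate_infusion(sphere_mesh, m, m, very_slow, dt=1360 / 150, bundle=sphere_bundle)
    p_equ, _ = solve_elastic(sphere_bundle, 0.265, 0.265, 15.0)
    assert abs(res.final_diop / p_equ - 1) < 0.10


def test_timestep_validation(sphere_mesh, sphere_material, sphere_bundle):
    with pytest.raises(ValueError):
        simulate_infusion(
            sphere_mesh, sphere_material, sphere_material, FAST, dt=0.5, bundle=sphere_bundle
        )
    with pytest.raises(ValueError):
        simulate_infusion(
            sphere_mesh, sphere_material, sphere_material, FAST, dt=-0.01, bundle=sphere_bundle
        )


def test_fields_zero_at_start_and_domain_checked(sphere_runs):
    res = sphere_runs["fast"]
    f0 = compute_fields(res, 0.0)
    assert np.all(f0["von_mises_MPa"] == 0)
    assert np.all(f0["principal_strain_1"] == 0)
    assert np.all(f0["displacement"] == 0)
    with pytest.raises(ValueError):
        compute_fields(res, 2.0)  # beyond the 1 s fast infusion


def test_sphere_von_mises_matches_membrane(sphere_runs):
    """Equibiaxial membrane state: mid-wall von Mises equals p R / (2 h)."""
    res = sphere_runs["fast"]
    t_end = float(res.time[-1])
    f = compute_fields(res, t_end)
    c = res.mesh.element_centroids()
    center = np.array([0.0, res.mesh.section.scleral_center_z])
    rad = np.linalg.norm(c - center, axis=1)
    mid = np.abs(rad - SPHERE_RADIUS) < SPHERE_THICKNESS / 6
    p = res.final_diop * MMHG_IN_MPA
    expected = p * SPHERE_RADIUS / (2 * SPHERE_THICKNESS)
    assert f["von_mises_MPa"][mid].mean() == pytest.approx(expected, rel=0.03)


def test_eye_fields_show_material_contrast(baseline_eye_runs):
    """Corneal and scleral stresses differ and vary through the thickness."""
    res = baseline_eye_runs["fast"]
    f = compute_fields(res, float(res.time[-1]))
    vm = f["von_mises_MPa"]
    mesh = res.mesh
    vm_cornea = vm[mesh.region == "cornea"].mean()
    vm_sclera = vm[mesh.region == "sclera"].mean()
    assert abs(vm_sclera - vm_cornea) > 0.2 * min(vm_sclera, vm_cornea)
    # through-thickness variation at the equator exceeds 5% of the mid-wall value
    c = mesh.element_centroids()
    sec = mesh.section
    theta = np.arctan2(c[:, 0], c[:, 1] - sec.scleral_center_z)
    band = np.abs(theta - np.pi / 2) < 0.05
    spread = vm[band].max() - vm[band].min()
    assert spread > 0.05 * vm[band].mean()


def test_axis_probes_displace_axially(baseline_eye_runs):
    res = baseline_eye_runs["fast"]
    snap = res.snapshot_at(res.time[-1])
    axis = res.mesh.node_sets["axis_of_symmetry"]
    np.testing.assert_allclose(snap.displacement[axis, 0], 0.0, atol=1e-15)


def test_mesh_convergence_study(eye_section):
    probes = [
        (0.0, -0.5),  # corneal apex, mid-thickness
        (0.0, -23.5),  # posterior pole region
        (12.4, -13.1),  # equator
        (5.0, -1.6),  # paracentral cornea
        (9.5, -5.5),  # anterior sclera
    ]
    sizes = [0.5, 0.42, 0.35, 0.3, 0.25]
    table = mesh_convergence_study(
        eye_section, sizes, probes, FAST, CORNEA_BASELINE, SCLERA_BASELINE
    )
    assert len(table) == 5
    assert table["n_elements"].is_monotonic_increasing
    # the two finest densities agree to < 1% in final dIOP
    assert table["rel_change_dIOP"].iloc[-1] < 0.01
    # repeated density reproduces identical results
    rep = mesh_convergence_study(
        eye_section, [0.4, 0.4], probes[:2], FAST, CORNEA_BASELINE, SCLERA_BASELINE
    )
    assert rep["dIOP_end_mmHg"].iloc[0] == rep["dIOP_end_mmHg"].iloc[1]
    # a probe outside the shell is rejected by name
    with pytest.raises(ValueError, match="probe 0"):
        mesh_convergence_study(
            eye_section, [0.4], [(6.0, -30.0)], FAST, CORNEA_BASELINE, SCLERA_BASELINE
        )


def test_thermal_analog_power_relation():
    assert thermal_analog_power(ThermalAnalogParams(volumetric_rate=0.0)) == 0.0
    p1 = thermal_analog_power(ThermalAnalogParams(volumetric_rate=15e-9))
    p2 = thermal_analog_power(ThermalAnalogParams(volumetric_rate=30e-9))
    assert p2 == pytest.approx(2 * p1, rel=1e-14)
    # pinned reference: 15 uL/s with the LDPE-like filler property set
    assert p1 == pytest.approx(79.35, rel=1e-12)


def test_spatial_convergence_fe_vs_finer_mesh(sphere_material):
    """Refining the verification sphere changes the pressure by well under 1%."""
    sec = build_geometry(spherical_geometry(SPHERE_RADIUS, SPHERE_THICKNESS))
    finals = []
    for size in (0.45, 0.3):
        mesh = generate_mesh(sec, size)
        res = simulate_infusion(mesh, sphere_material, sphere_material, FAST)
        finals.append(res.final_diop)
    assert abs(finals[1] / finals[0] - 1) < 0.01
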