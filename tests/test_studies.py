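"""Parametric studies: sweeps, sensitivity, cross-rate correlation, calibration."""

import numpy as np
import pandas as pd
import pytest

from iopsim import (
    FAST,
    INTERMEDIATE,
    SLOW,
    FEEngine,
    OracleEngine,
    calibrate_parameters,
    correlate_rates,
    population_from_sweep,
    run_rate_study,
    sensitivity_scan,
    sweep_parameter,
)
from iopsim.studies import BASELINE_PARAMS, PARAMETER_SPECS, ParameterSpec
from conftest import nearly_elastic


def _span(values):
    return (values.max() - values.min()) / values.min()


def test_parameter_specs_match_reference_table():
    s = PARAMETER_SPECS
    assert (s["instantaneous_modulus"].cornea_baseline,
            s["instantaneous_modulus"].cornea_min,
            s["instantaneous_modulus"].cornea_max) == (1.1, 0.62, 1.6)
    assert (s["equilibrium_modulus"].cornea_baseline,
            s["equilibrium_modulus"].cornea_min,
            s["equilibrium_modulus"].cornea_max) == (0.265, 0.065, 0.465)
    assert (s["short_time_constant"].cornea_baseline,
            s["short_time_constant"].cornea_min,
            s["short_time_constant"].cornea_max) == (0.35, 0.05, 0.65)
    assert (s["long_time_constant"].cornea_baseline,
            s["long_time_constant"].cornea_min,
            s["long_time_constant"].cornea_max) == (68.0, 18.0, 128.0)
    with pytest.raises(ValueError):
        ParameterSpec("bad", 2.0, 1.0, 1.5, "MPa")


def test_rate_study_ordering_and_linearity(oracle_engine):
    curves = run_rate_study(oracle_engine)
    ends = {name: df["dIOP_mmHg"].iloc[-1] for name, df in curves.items()}
    assert ends["fast"] > ends["intermediate"] > ends["slow"]
    for df in curves.values():
        assert len(df) >= 11
        assert df["volume_uL"].iloc[0] == 0.0 and df["volume_uL"].iloc[-1] == 15.0
        d = df["dIOP_mmHg"].to_numpy()
        chord = d[-1] * df["volume_uL"].to_numpy() / 15.0
        assert np.abs(d - chord).max() < 0.15 * d[-1]


def test_rate_study_elastic_limit_is_rate_independent():
    class ElasticEngine(OracleEngine):
        def _spec(self, params):
            from iopsim import SphericalShellSpec

            return SphericalShellSpec(self.radius, self.thickness, nearly_elastic(1.325))

    curves = run_rate_study(ElasticEngine())
    ref = curves["fast"]["dIOP_mmHg"].to_numpy()
    for name in ("intermediate", "slow"):
        np.testing.assert_allclose(curves[name]["dIOP_mmHg"], ref, rtol=1e-12)


def test_instantaneous_modulus_sweep(oracle_engine):
    sw = sweep_parameter(PARAMETER_SPECS["instantaneous_modulus"], oracle_engine)
    for rate in ("fast", "intermediate", "slow"):
        d = sw.end_diop(rate)
        assert np.all(np.diff(d) > 0)  # strictly increasing in stiffness
    fits = sw.fits.set_index("rate")
    assert (fits["r_squared"] >= 0.98).all()
    # the sweep slope is largest at the fastest rate
    assert fits.loc["fast", "slope"] > fits.loc["intermediate", "slope"] > fits.loc["slow", "slope"]


def test_time_constant_selectivity(oracle_engine):
    """tau_s shapes the fast response and barely touches the slow one;
    tau_l acts on intermediate/slow and barely on fast."""
    sw_s = sweep_parameter(PARAMETER_SPECS["short_time_constant"], oracle_engine)
    assert np.all(np.diff(sw_s.end_diop("fast")) > 0)
    assert _span(sw_s.end_diop("slow")) < 0.01
    # the fast-rate effect dominates the residual intermediate-rate effect
    assert _span(sw_s.end_diop("fast")) > 5 * _span(sw_s.end_diop("intermediate"))

    sw_l = sweep_parameter(PARAMETER_SPECS["long_time_constant"], oracle_engine)
    assert np.all(np.diff(sw_l.end_diop("intermediate")) > 0)
    assert np.all(np.diff(sw_l.end_diop("slow")) > 0)
    assert _span(sw_l.end_diop("fast")) < 0.02


def test_sweep_rejects_unphysical_grid(oracle_engine):
    bad = ParameterSpec("equilibrium_modulus", 0.9, 0.5, 1.4, "MPa")  # crosses E_inst = 1.1
    with pytest.raises(ValueError, match="unphysical"):
        sweep_parameter(bad, oracle_engine)
    with pytest.raises(ValueError):
        sweep_parameter(PARAMETER_SPECS["equilibrium_modulus"], oracle_engine, n_grid=2)


def test_sensitivity_rankings(oracle_engine):
    sens = sensitivity_scan(oracle_engine)
    assert sens.ranking("fast")[0] == "instantaneous_modulus"
    assert sens.ranking("intermediate")[0] == "instantaneous_modulus"
    assert sens.ranking("slow")[0] == "equilibrium_modulus"
    # baseline is not the range midpoint for every parameter; both recorded
    assert sens.baseline_coordinates["equilibrium_modulus"] == pytest.approx(0.0)
    assert sens.baseline_coordinates["instantaneous_modulus"] != 0.0


def test_sensitivity_zero_width_range_has_zero_influence(oracle_engine):
    eps = 1e-9
    narrow = {
        "short_time_constant": ParameterSpec(
            "short_time_constant", 0.35, 0.35 - eps, 0.35 + eps, "s"
        )
    }
    sens = sensitivity_scan(oracle_engine, specs=narrow)
    assert (sens.influence["influence_mmHg"] < 1e-6).all()


def test_cross_rate_correlation_instantaneous_population(oracle_engine):
    pop = population_from_sweep(PARAMETER_SPECS["instantaneous_modulus"], oracle_engine, n_eyes=5)
    assert pop.correlation.loc["fast", "intermediate"] >= 0.999
    assert pop.correlation.loc["fast", "slow"] >= 0.999
    np.testing.assert_allclose(np.diag(pop.correlation), 1.0)
    pd.testing.assert_frame_equal(pop.correlation, pop.correlation.T)


def test_two_eye_population_perfect_correlation():
    end = pd.DataFrame({"fast": [1.0, 2.0], "intermediate": [0.5, 0.9]})
    pop = correlate_rates(end)
    assert abs(pop.correlation.loc["fast", "intermediate"]) == pytest.approx(1.0)


def test_degenerate_population_flagged():
    end = pd.DataFrame({"fast": [1.0, 1.0, 1.0], "intermediate": [0.5, 0.5, 0.5]})
    pop = correlate_rates(end)
    assert pop.degenerate
    assert np.isnan(pop.fits["r"]).all()
    with pytest.raises(ValueError):
        correlate_rates(end.iloc[:1])


def test_nonlinearity_detection_on_time_constant_population(oracle_engine):
    """A long-time-constant-varied population produces a genuinely curved
    fast-vs-slow relationship that the quadratic diagnostic flags."""
    pop = population_from_sweep(PARAMETER_SPECS["long_time_constant"], oracle_engine, n_eyes=5)
    gain = pop.fits.set_index(["x", "y"]).loc[("fast", "slow"), "quadratic_ss_reduction"]
    assert gain > 0.10


def test_engine_interchangeability_orderings(eye_section):
    """A coarse FE sweep on the eye reproduces the oracle's orderings."""
    fe = FEEngine(element_size=0.45)
    oracle = OracleEngine()
    spec = PARAMETER_SPECS["instantaneous_modulus"]
    for engine in (fe, oracle):
        sw = sweep_parameter(spec, engine, n_grid=3, protocols=(FAST, SLOW))
        assert np.all(np.diff(sw.end_diop("fast")) > 0)
        assert np.all(np.diff(sw.end_diop("slow")) > 0)
        ends = {p: engine.end_diop({}, p) for p in (FAST, SLOW)}
        assert ends[FAST] > ends[SLOW]


def _observed_baseline_curves(engine):
    vols = np.linspace(0.0, 15.0, 11)
    return {
        p.name: engine.curve_at_volumes({}, p, vols)[["volume_uL", "dIOP_mmHg"]]
        for p in (FAST, INTERMEDIATE, SLOW)
    }


def test_calibration_recovers_noise_free_parameters(oracle_engine):
    cal = calibrate_parameters(_observed_baseline_curves(oracle_engine), oracle_engine)
    assert cal.parameters["instantaneous_modulus"] == pytest.approx(1.1, rel=0.02)
    assert cal.parameters["equilibrium_modulus"] == pytest.approx(0.265, rel=0.02)
    assert cal.parameters["short_time_constant"] == pytest.approx(0.35, rel=0.10)
    assert cal.parameters["long_time_constant"] == pytest.approx(68.0, rel=0.10)
    assert cal.weakly_identifiable == []
    assert cal.at_bounds == []


def test_calibration_noisy_recovery_medians(oracle_engine):
    """20 replicates at 3% multiplicative noise; medians frozen from the
    first recovery study (E_inst is robust, E_equ and the time constants
    carry the collinearity burden)."""
    base = BASELINE_PARAMS
    errs = {k: [] for k in base}
    vols = np.linspace(0.0, 15.0, 11)
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        obs = {}
        for p in (FAST, INTERMEDIATE, SLOW):
            df = oracle_engine.curve_at_volumes({}, p, vols).copy()
            df["dIOP_mmHg"] *= 1 + rng.normal(0, 0.03, len(df))
            obs[p.name] = df
        cal = calibrate_parameters(obs, oracle_engine)
        for k, v in cal.parameters.items():
            errs[k].append(abs(v - base[k]) / base[k])
    med = {k: np.median(v) for k, v in errs.items()}
    assert med["instantaneous_modulus"] <= 0.10
    assert med["equilibrium_modulus"] <= 0.25
    assert med["short_time_constant"] <= 0.30
    assert med["long_time_constant"] <= 0.30


@pytest.mark.parametrize("rate_name", ["fast", "intermediate", "slow"])
def test_single_rate_input_flags_time_constants(oracle_engine, rate_name):
    obs = _observed_baseline_curves(oracle_engine)
    cal = calibrate_parameters({rate_name: obs[rate_name]}, oracle_engine)
    assert "short_time_constant" in cal.weakly_identifiable
    assert "long_time_constant" in cal.weakly_identifiable


def test_calibration_input_validation(oracle_engine):
    with pytest.raises(ValueError):
        calibrate_parameters({}, oracle_engine)
    with pytest.raises(ValueError, match="unknown protocol"):
        calibrate_parameters({"warp": pd.DataFrame()}, oracle_engine)


def test_sweep_determinism(oracle_engine):
    a = sweep_parameter(PARAMETER_SPECS["instantaneous_modulus"], oracle_engine)
    b = sweep_parameter(PARAMETER_SPECS["instantaneous_modulus"], oracle_engine)
    assert a.table.to_csv() == b.table.to_csv()
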