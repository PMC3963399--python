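"""Parametric studies: rate study, one-at-a-time sweeps, sensitivity scan,
cross-rate correlation over simulated eye populations, and calibration.

Every study varies the four corneal viscoelastic parameters
(instantaneous modulus, equilibrium modulus, short and long time constant)
with the scleral moduli tied to the corneal ones 5:1 and the time constants
shared, runs the chosen engine (closed-form sphere oracle or the
finite-element eye model) for one or more infusion protocols, and reports
the end-of-infusion pressure elevation dIOP(15 uL) -- the scalar summary
used throughout.

Engines
-------
``OracleEngine`` evaluates the closed-form membrane solution on an
equivalent uniform sphere (default R = 12 mm, h = 0.8 mm, carrying the
scleral material, i.e. 5x the corneal parameters, since the shell is
predominantly sclera).  ``FEEngine`` runs the axisymmetric finite-element
model on the two-material eye geometry; its discretisation and
unit-modulus stiffness operators are cached so a parameter sweep only
refactorises and time-steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import fem
from .geometry import BASELINE_GEOMETRY, EyeGeometry, build_geometry, generate_mesh
from .materials import ViscoelasticMaterial, make_material, scleral_from_corneal
from .oracle import SphericalShellSpec, oracle_pressure
from .protocols import FAST, INTERMEDIATE, PROTOCOLS, SLOW, InfusionProtocol

__all__ = [
    "ParameterSpec",
    "PARAMETER_SPECS",
    "SweepResult",
    "SensitivityResult",
    "PopulationResult",
    "CalibrationResult",
    "OracleEngine",
    "FEEngine",
    "corneal_material_from_params",
    "run_rate_study",
    "sweep_parameter",
    "sensitivity_scan",
    "correlate_rates",
    "calibrate_parameters",
]

#: Scleral-to-corneal baseline modulus ratio.
SCLERA_CORNEA_RATIO = 5.0

DEFAULT_PROTOCOLS = (FAST, INTERMEDIATE, SLOW)


@dataclass(frozen=True)
class ParameterSpec:
    """One viscoelastic parameter: corneal baseline and plausible range.

    For the two moduli the scleral value is tied to the corneal one by the
    5:1 ratio; the time constants are shared between cornea and sclera.
    """

    name: str
    cornea_baseline: float
    cornea_min: float
    cornea_max: float
    units: str

    def __post_init__(self) -> None:
        if not self.cornea_min < self.cornea_baseline < self.cornea_max:
            raise ValueError(f"{self.name}: require min < baseline < max")

    def grid(self, n: int) -> np.ndarray:
        return np.linspace(self.cornea_min, self.cornea_max, n)

    @property
    def baseline_scaled_coordinate(self) -> float:
        """Baseline position on the [-1, +1] min-to-max scale (not always 0)."""
        return -1.0 + 2.0 * (self.cornea_baseline - self.cornea_min) / (
            self.cornea_max - self.cornea_min
        )


PARAMETER_SPECS = {
    "instantaneous_modulus": ParameterSpec("instantaneous_modulus", 1.1, 0.62, 1.6, "MPa"),
    "equilibrium_modulus": ParameterSpec("equilibrium_modulus", 0.265, 0.065, 0.465, "MPa"),
    "short_time_constant": ParameterSpec("short_time_constant", 0.35, 0.05, 0.65, "s"),
    "long_time_constant": ParameterSpec("long_time_constant", 68.0, 18.0, 128.0, "s"),
}

BASELINE_PARAMS = {name: spec.cornea_baseline for name, spec in PARAMETER_SPECS.items()}


def corneal_material_from_params(params: dict, poisson_ratio: float = 0.49) -> ViscoelasticMaterial:
    """Corneal material from a {parameter name: value} dict (baselines filled in)."""
    p = dict(BASELINE_PARAMS)
    p.update(params)
    if p["equilibrium_modulus"] >= p["instantaneous_modulus"]:
        raise ValueError(
            f"invalid parameter point: equilibrium modulus {p['equilibrium_modulus']} >= "
            f"instantaneous modulus {p['instantaneous_modulus']}"
        )
    return make_material(
        p["instantaneous_modulus"],
        p["equilibrium_modulus"],
        p["short_time_constant"],
        p["long_time_constant"],
        poisson_ratio,
    )


class OracleEngine:
    """Closed-form engine: uniform sphere carrying the tied scleral material."""

    def __init__(self, radius: float = 12.0, thickness: float = 0.8, use_sclera: bool = True):
        self.radius = radius
        self.thickness = thickness
        self.use_sclera = use_sclera

    def _spec(self, params: dict) -> SphericalShellSpec:
        mat = corneal_material_from_params(params)
        if self.use_sclera:
            mat = scleral_from_corneal(mat, SCLERA_CORNEA_RATIO)
        return SphericalShellSpec(self.radius, self.thickness, mat)

    def curve(self, params: dict, protocol: InfusionProtocol, n_points: int = 11) -> pd.DataFrame:
        volumes = np.linspace(0.0, protocol.total_volume, n_points)
        return self.curve_at_volumes(params, protocol, volumes)

    def curve_at_volumes(self, params, protocol, volumes) -> pd.DataFrame:
        volumes = np.asarray(volumes, dtype=float)
        times = volumes / protocol.rate
        diop = oracle_pressure(self._spec(params), protocol, times)
        return pd.DataFrame({"time_s": times, "volume_uL": volumes, "dIOP_mmHg": diop})

    def end_diop(self, params: dict, protocol: InfusionProtocol) -> float:
        return float(
            oracle_pressure(self._spec(params), protocol, protocol.duration)
        )


class FEEngine:
    """Finite-element engine on the two-material eye geometry.

    Mesh, strain operators and unit-modulus stiffness matrices are built
    once; each parameter point costs one factorisation plus time stepping.
    """

    def __init__(
        self,
        geometry: EyeGeometry = BASELINE_GEOMETRY,
        element_size: float = 0.25,
        dt: float | None = None,
    ):
        self.geometry = geometry
        self.element_size = element_size
        self.dt = dt
        self.mesh = generate_mesh(build_geometry(geometry), element_size)
        self.disc = fem.precompute_discretization(self.mesh)
        self._bundle_cache: dict = {}

    def _bundle(self, params: dict) -> fem.OperatorBundle:
        cornea = corneal_material_from_params(params)
        key = (cornea.equilibrium_modulus, cornea.branch_moduli, cornea.time_constants)
        if key not in self._bundle_cache:
            sclera = scleral_from_corneal(cornea, SCLERA_CORNEA_RATIO)
            if len(self._bundle_cache) == 0:
                bundle = fem.assemble_system(self.mesh, cornea, sclera, disc=self.disc)
                self._template = bundle
            else:
                # unit stiffness matrices depend only on nu; reuse them
                t = self._template
                bundle = fem.OperatorBundle(
                    mesh=t.mesh,
                    cornea=cornea,
                    sclera=sclera,
                    disc=t.disc,
                    k_cornea_unit=t.k_cornea_unit,
                    k_sclera_unit=t.k_sclera_unit,
                    d_cornea_w=t.d_cornea_w,
                    d_sclera_w=t.d_sclera_w,
                    g=t.g,
                    reference_volume=t.reference_volume,
                    free=t.free,
                    fixed_axial_node=t.fixed_axial_node,
                )
            if len(self._bundle_cache) > 32:
                self._bundle_cache.clear()
            self._bundle_cache[key] = bundle
        return self._bundle_cache[key]

    def simulate(self, params: dict, protocol: InfusionProtocol) -> fem.SimulationResult:
        bundle = self._bundle(params)
        return fem.simulate_infusion(
            self.mesh, bundle.cornea, bundle.sclera, protocol, dt=self.dt, bundle=bundle
        )

    def curve(self, params: dict, protocol: InfusionProtocol, n_points: int = 11) -> pd.DataFrame:
        res = self.simulate(params, protocol)
        volumes = np.linspace(0.0, protocol.total_volume, n_points)
        diop = np.interp(volumes, res.injected_volume, res.diop_mmhg)
        return pd.DataFrame(
            {"time_s": volumes / protocol.rate, "volume_uL": volumes, "dIOP_mmHg": diop}
        )

    def curve_at_volumes(self, params, protocol, volumes) -> pd.DataFrame:
        res = self.simulate(params, protocol)
        volumes = np.asarray(volumes, dtype=float)
        diop = np.interp(volumes, res.injected_volume, res.diop_mmhg)
        return pd.DataFrame(
            {"time_s": volumes / protocol.rate, "volume_uL": volumes, "dIOP_mmHg": diop}
        )

    def end_diop(self, params: dict, protocol: InfusionProtocol) -> float:
        return self.simulate(params, protocol).final_diop


# --------------------------------------------------------------------------
# studies


def run_rate_study(engine, params: dict | None = None, n_points: int = 11) -> dict:
    """dIOP-vs-volume curves for the fast/intermediate/slow protocols."""
    if n_points < 11:
        raise ValueError("rate-study curves are sampled at >= 11 volume levels")
    params = params or {}
    return {p.name: engine.curve(params, p, n_points) for p in DEFAULT_PROTOCOLS}


@dataclass
class SweepResult:
    """One-at-a-time sweep of a single parameter across its plausible range."""

    parameter: str
    values: np.ndarray
    table: pd.DataFrame  # columns: value, rate, dIOP_mmHg
    fits: pd.DataFrame  # per-rate linear fit: slope, intercept, r_squared

    def end_diop(self, rate_name: str) -> np.ndarray:
        sub = self.table[self.table["rate"] == rate_name]
        return sub.sort_values("value")["dIOP_mmHg"].to_numpy()


def sweep_parameter(
    spec: ParameterSpec,
    engine,
    n_grid: int = 5,
    protocols=DEFAULT_PROTOCOLS,
) -> SweepResult:
    """Sweep one parameter over its range, all else at baseline.

    The two moduli move cornea and sclera together (5:1); the time constants
    are shared.  Attaches a per-rate linear fit (slope, R^2) of end dIOP
    against the parameter value.
    """
    if n_grid < 3:
        raise ValueError("n_grid must be at least 3")
    values = spec.grid(n_grid)
    rows = []
    for v in values:
        params = {spec.name: float(v)}
        try:
            corneal_material_from_params(params)
        except ValueError as exc:
            raise ValueError(f"sweep point {spec.name} = {v} is unphysical: {exc}") from exc
        for protocol in protocols:
            rows.append(
                {
                    "parameter": spec.name,
                    "value": float(v),
                    "rate": protocol.name,
                    "dIOP_mmHg": engine.end_diop(params, protocol),
                }
            )
    table = pd.DataFrame(rows)
    fits = []
    for protocol in protocols:
        sub = table[table["rate"] == protocol.name]
        fit = stats.linregress(sub["value"], sub["dIOP_mmHg"])
        fits.append(
            {
                "rate": protocol.name,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
            }
        )
    return SweepResult(
        parameter=spec.name, values=values, table=table, fits=pd.DataFrame(fits)
    )


@dataclass
class SensitivityResult:
    """Normalised one-at-a-time scan of all four parameters.

    Each parameter is mapped linearly from its minimum (-1) to its maximum
    (+1); the influence score per rate is the dIOP span over the scan.  The
    baseline does not generally sit at coordinate 0; its scaled position is
    recorded per parameter.
    """

    table: pd.DataFrame  # parameter, s, value, rate, dIOP_mmHg
    influence: pd.DataFrame  # parameter, rate, influence_mmHg
    baseline_coordinates: dict

    def ranking(self, rate_name: str) -> list[str]:
        sub = self.influence[self.influence["rate"] == rate_name]
        return list(sub.sort_values("influence_mmHg", ascending=False)["parameter"])


def sensitivity_scan(
    engine,
    n_grid: int = 5,
    protocols=DEFAULT_PROTOCOLS,
    specs: dict | None = None,
) -> SensitivityResult:
    """Scan each parameter across [-1, +1] (min to max), others at baseline."""
    specs = specs or PARAMETER_SPECS
    rows = []
    for name, spec in specs.items():
        values = spec.grid(n_grid)
        s_coords = np.linspace(-1.0, 1.0, n_grid)
        for s, v in zip(s_coords, values):
            for protocol in protocols:
                rows.append(
                    {
                        "parameter": name,
                        "s": float(s),
                        "value": float(v),
                        "rate": protocol.name,
                        "dIOP_mmHg": engine.end_diop({name: float(v)}, protocol),
                    }
                )
    table = pd.DataFrame(rows)
    influence = (
        table.groupby(["parameter", "rate"])["dIOP_mmHg"]
        .agg(lambda x: x.max() - x.min())
        .rename("influence_mmHg")
        .reset_index()
    )
    baselines = {name: spec.baseline_scaled_coordinate for name, spec in specs.items()}
    return SensitivityResult(table=table, influence=influence, baseline_coordinates=baselines)


@dataclass
class PopulationResult:
    """Cross-rate relationships of end dIOP over a population of eyes."""

    end_diop: pd.DataFrame  # one row per eye, one column per rate
    correlation: pd.DataFrame  # Pearson matrix, unit diagonal
    fits: pd.DataFrame  # per rate pair: slope, intercept, r, p, quadratic SS gain
    degenerate: bool = False


def correlate_rates(end_diop: pd.DataFrame) -> PopulationResult:
    """Pearson correlations and linear fits between per-rate end dIOP columns.

    ``end_diop`` has one row per simulated eye and one column per rate name.
    For each rate pair a quadratic fit is also performed and the fractional
    reduction of the residual sum of squares relative to the linear fit is
    reported (a nonlinearity diagnostic).  A population with fewer than two
    distinct values in some column is flagged degenerate and the
    correlation left undefined.
    """
    if len(end_diop) < 2:
        raise ValueError("need at least two eyes")
    cols = list(end_diop.columns)
    degenerate = any(end_diop[c].nunique() < 2 for c in cols)
    corr = end_diop.corr(method="pearson")
    fits = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x = end_diop[a].to_numpy()
            y = end_diop[b].to_numpy()
            if degenerate:
                fits.append(
                    {"x": a, "y": b, "slope": np.nan, "intercept": np.nan, "r": np.nan,
                     "p_value": np.nan, "quadratic_ss_reduction": np.nan}
                )
                continue
            fit = stats.linregress(x, y)
            resid_lin = y - (fit.intercept + fit.slope * x)
            ss_lin = float(resid_lin @ resid_lin)
            if len(x) >= 4:
                coef = np.polyfit(x, y, 2)
                resid_quad = y - np.polyval(coef, x)
                ss_quad = float(resid_quad @ resid_quad)
                gain = (ss_lin - ss_quad) / ss_lin if ss_lin > 0 else 0.0
            else:
                gain = np.nan
            fits.append(
                {
                    "x": a,
                    "y": b,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r": fit.rvalue,
                    "p_value": fit.pvalue,
                    "quadratic_ss_reduction": gain,
                }
            )
    return PopulationResult(
        end_diop=end_diop, correlation=corr, fits=pd.DataFrame(fits), degenerate=degenerate
    )


def population_from_sweep(
    spec: ParameterSpec,
    engine,
    n_eyes: int = 5,
    protocols=DEFAULT_PROTOCOLS,
) -> PopulationResult:
    """Treat each sweep grid point as an individual eye and correlate rates."""
    if n_eyes < 2:
        raise ValueError("need at least two eyes")
    sweep = sweep_parameter(spec, engine, n_grid=max(n_eyes, 3), protocols=protocols)
    wide = sweep.table.pivot(index="value", columns="rate", values="dIOP_mmHg")
    wide = wide[[p.name for p in protocols]]
    wide.columns.name = None
    return correlate_rates(wide.reset_index(drop=True))


# --------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    """Bounded least-squares fit of the four viscoelastic parameters."""

    parameters: dict
    residual_norm: float
    covariance: np.ndarray | None
    relative_uncertainty: dict
    weakly_identifiable: list
    at_bounds: list
    n_observations: int

    @property
    def material(self) -> ViscoelasticMaterial:
        return corneal_material_from_params(self.parameters)


_CAL_ORDER = (
    "instantaneous_modulus",
    "equilibrium_modulus",
    "short_time_constant",
    "long_time_constant",
)


def calibrate_parameters(
    observed: dict,
    engine,
    bounds: dict | None = None,
    x0: dict | None = None,
) -> CalibrationResult:
    """Fit (E_inst, E_equ, tau_s, tau_l) to observed dIOP--volume curves.

    ``observed`` maps a protocol name (fast / intermediate / slow) to a
    DataFrame with columns volume_uL and dIOP_mmHg.  All rates are fitted
    simultaneously by bounded least squares (loss: squared dIOP error on
    the observed volume grids).  The covariance is estimated from the
    Gauss-Newton approximation at the optimum; parameters whose relative
    standard deviation exceeds 50% are flagged weakly identifiable --
    expect the time constants to be flagged when only one rate is supplied.
    """
    if not observed:
        raise ValueError("no observed curves supplied")
    unknown = set(observed) - set(PROTOCOLS)
    if unknown:
        raise ValueError(f"unknown protocol names: {sorted(unknown)}")
    bounds = bounds or {
        name: (spec.cornea_min, spec.cornea_max) for name, spec in PARAMETER_SPECS.items()
    }
    lower = np.array([bounds[k][0] for k in _CAL_ORDER])
    upper = np.array([bounds[k][1] for k in _CAL_ORDER])
    start = np.array(
        [
            (x0 or {}).get(k, np.sqrt(bounds[k][0] * bounds[k][1]))
            for k in _CAL_ORDER
        ]
    )

    items = [
        (PROTOCOLS[name], df["volume_uL"].to_numpy(), df["dIOP_mmHg"].to_numpy())
        for name, df in observed.items()
    ]
    n_obs = sum(len(v) for _, v, _ in items)

    def residuals(x):
        params = dict(zip(_CAL_ORDER, x))
        res = []
        for protocol, volumes, diop in items:
            pred = engine.curve_at_volumes(params, protocol, volumes)["dIOP_mmHg"].to_numpy()
            res.append(pred - diop)
        return np.concatenate(res)

    sol = optimize.least_squares(
        residuals, start, bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"calibration optimizer failed: {sol.message}")
    params = dict(zip(_CAL_ORDER, (float(v) for v in sol.x)))

    # local identifiability: Gauss-Newton covariance in the *relative*
    # parametrisation (columns of J scaled by the parameter values), with the
    # noise scale floored at 1% of the observed dIOP rms so a perfect
    # (noise-free) fit still yields a meaningful uncertainty per plausible
    # measurement noise rather than a vacuous zero
    data_rms = float(np.sqrt(np.mean(np.concatenate([d for _, _, d in items]) ** 2)))
    resid_rms = float(np.sqrt(2.0 * sol.cost / max(n_obs, 1)))
    noise = max(resid_rms, 0.01 * data_rms)
    jac_rel = sol.jac * sol.x[None, :]
    try:
        cov_rel = np.linalg.pinv(jac_rel.T @ jac_rel)
        cov = (noise**2) * cov_rel * np.outer(sol.x, sol.x)
        rel = {
            k: float(noise * np.sqrt(max(cov_rel[i, i], 0.0)))
            for i, k in enumerate(_CAL_ORDER)
        }
    except np.linalg.LinAlgError:  # pragma: no cover
        cov, rel = None, {k: np.inf for k in _CAL_ORDER}
    weak = [k for k in _CAL_ORDER if rel[k] > 0.3]
    at_bounds = [
        k
        for i, k in enumerate(_CAL_ORDER)
        if np.isclose(sol.x[i], lower[i], rtol=1e-6) or np.isclose(sol.x[i], upper[i], rtol=1e-6)
    ]
    return CalibrationResult(
        parameters=params,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        covariance=cov,
        relative_uncertainty=rel,
        weakly_identifiable=weak,
        at_bounds=at_bounds,
        n_observations=n_obs,
    )
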