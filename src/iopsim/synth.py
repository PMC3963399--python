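"""Synthetic "experimental" infusion datasets for a population of eyes.

No measured porcine infusion data are distributed, so the calibration,
correlation and figure-reproduction stages are exercised on synthetic
datasets with the statistical structure the analysis assumes: a population
of eyes whose viscoelastic parameters scatter around the baseline
(multiplicative log-normal, by default a 20% coefficient of variation on
the instantaneous modulus only, since variance in that parameter best
explains linearly correlated cross-rate elevations), measured as noisy
dIOP--volume curves at the three infusion rates (additive Gaussian noise,
0.5 mmHg by default, plus an optional multiplicative component).

The log-normal inter-eye distribution and the noise magnitudes are
synthetic-data assumptions of this package, not measured quantities; see
docs/methods.md.  Datasets are byte-reproducible under a fixed spec + seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .studies import BASELINE_PARAMS, DEFAULT_PROTOCOLS, OracleEngine

__all__ = ["PopulationSpec", "SyntheticDataset", "generate_population", "emulate_average_eye_dataset"]


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of a synthetic eye population.

    ``coefficient_of_variation`` maps parameter names to multiplicative
    log-normal CVs (unlisted parameters do not vary); draws violating
    E_equ < E_inst are rejected and resampled.  ``noise_sd_mmHg`` is the
    additive Gaussian measurement noise on each dIOP reading and
    ``noise_relative`` an optional multiplicative component (e.g. 0.02).
    """

    n_eyes: int = 11
    coefficient_of_variation: dict = field(
        default_factory=lambda: {"instantaneous_modulus": 0.2}
    )
    noise_sd_mmhg: float = 0.5
    noise_relative: float = 0.0
    volume_levels: tuple = tuple(np.linspace(0.0, 15.0, 11))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be at least 1")
        if any(cv < 0 for cv in self.coefficient_of_variation.values()):
            raise ValueError("coefficients of variation must be non-negative")
        if self.noise_sd_mmhg < 0 or self.noise_relative < 0:
            raise ValueError("noise levels must be non-negative")
        unknown = set(self.coefficient_of_variation) - set(BASELINE_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """Noisy per-eye dIOP--volume tables plus the hidden true parameters."""

    spec: PopulationSpec
    measurements: pd.DataFrame  # eye_id, rate_uL_per_s, volume_uL, dIOP_mmHg
    true_parameters: pd.DataFrame  # one row per eye

    def eye_curves(self, eye_id: int) -> dict:
        """Observed curves of one eye keyed by protocol name (for calibration)."""
        rate_to_name = {p.rate: p.name for p in DEFAULT_PROTOCOLS}
        sub = self.measurements[self.measurements["eye_id"] == eye_id]
        out = {}
        for rate, grp in sub.groupby("rate_uL_per_s"):
            out[rate_to_name[float(rate)]] = grp[["volume_uL", "dIOP_mmHg"]].reset_index(
                drop=True
            )
        return out

    def save(self, directory) -> None:
        """CSV of measurements plus a JSON sidecar with spec and true parameters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(directory / "measurements.csv", index=False)
        sidecar = {
            "spec": asdict(self.spec),
            "true_parameters": self.true_parameters.to_dict(orient="records"),
        }
        (directory / "population.json").write_text(json.dumps(sidecar, indent=2, default=float))


def _draw_parameters(spec: PopulationSpec, rng: np.random.Generator) -> dict:
    for _ in range(100):
        params = dict(BASELINE_PARAMS)
        for name, cv in spec.coefficient_of_variation.items():
            if cv == 0:
                continue
            sigma = np.sqrt(np.log1p(cv**2))
            # mean-one multiplicative log-normal scatter
            params[name] *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        if params["equilibrium_modulus"] < params["instantaneous_modulus"]:
            return params
    raise RuntimeError("failed to draw physical parameters after 100 attempts")


def generate_population(spec: PopulationSpec, engine=None) -> SyntheticDataset:
    """Simulate a population of eyes and their noisy measured curves.

    Noise-free curves come from the engine (closed-form sphere oracle by
    default) at each eye's true parameters; Gaussian noise is then added per
    the spec.  True parameters are returned alongside for recovery tests.
    """
    engine = engine or OracleEngine()
    rng = np.random.default_rng(spec.seed)
    volumes = np.asarray(spec.volume_levels, dtype=float)
    rows = []
    truths = []
    for eye in range(spec.n_eyes):
        params = _draw_parameters(spec, rng)
        truths.append({"eye_id": eye, **params})
        for protocol in DEFAULT_PROTOCOLS:
            clean = engine.curve_at_volumes(params, protocol, volumes)["dIOP_mmHg"].to_numpy()
            noisy = clean + rng.normal(0.0, spec.noise_sd_mmhg, size=clean.shape)
            if spec.noise_relative > 0:
                noisy = noisy + clean * rng.normal(0.0, spec.noise_relative, size=clean.shape)
            for v, d in zip(volumes, noisy):
                rows.append(
                    {
                        "eye_id": eye,
                        "rate_uL_per_s": protocol.rate,
                        "volume_uL": float(v),
                        "dIOP_mmHg": float(d),
                    }
                )
    return SyntheticDataset(
        spec=spec,
        measurements=pd.DataFrame(rows),
        true_parameters=pd.DataFrame(truths),
    )


def emulate_average_eye_dataset(seed: int = 0, engine=None) -> pd.DataFrame:
    """Noise-free baseline "average eye" curves at the three rates.

    Eleven volume levels evenly distributed over [0, 15] uL per rate
    (3 x 11 rows); the fixture for rate-study agreement and closed-loop
    calibration tests.  The seed is accepted for interface uniformity; the
    output is deterministic.
    """
    del seed
    engine = engine or OracleEngine()
    volumes = np.linspace(0.0, 15.0, 11)
    frames = []
    for protocol in DEFAULT_PROTOCOLS:
        df = engine.curve_at_volumes({}, protocol, volumes).copy()
        df.insert(0, "rate_uL_per_s", protocol.rate)
        frames.append(df[["rate_uL_per_s", "volume_uL", "dIOP_mmHg"]])
    return pd.concat(frames, ignore_index=True)
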