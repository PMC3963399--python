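"""Closed-form pressure--volume response of a thin viscoelastic spherical shell.

Independent reduced-order solution used to verify the finite-element solver
and as a fast engine for parameter studies and synthetic data.

Derivation (documented here because it is the package's verification
anchor).  For a thin spherical shell of mid-surface radius R and wall
thickness h under internal pressure p, membrane equilibrium gives the
equibiaxial wall stress sigma = p R / (2 h).  An equibiaxial membrane
strain eps changes the enclosed volume by dV = 3 eps V0 with
V0 = (4/3) pi R^3, so eps = dV / (3 V0).  For a linear isotropic material
the equibiaxial stress-strain relation is sigma = E eps / (1 - nu).
Combining, and replacing the modulus by the hereditary integral of the
Prony relaxation function E(t), the pressure elevation under a prescribed
volume history V(t) is

    dp(t) = 2 h / (3 (1 - nu) R V0) * int_0^t E(t - s) dV/ds ds.

For piecewise-constant infusion rates the integral has the closed form of
the constant-strain-rate stress solution, evaluated segment by segment and
superposed.  Pressures are returned in mmHg, volumes in uL, time in s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fem import MMHG_IN_MPA
from .materials import ViscoelasticMaterial
from .protocols import InfusionProtocol

__all__ = ["SphericalShellSpec", "oracle_pressure", "oracle_curve"]


@dataclass(frozen=True)
class SphericalShellSpec:
    """Thin uniform spherical shell: mid-surface radius and wall thickness (mm)."""

    radius: float
    thickness: float
    material: ViscoelasticMaterial

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("radius and thickness must be positive")
        if self.thickness / self.radius > 0.15:
            warnings.warn(
                f"h/R = {self.thickness / self.radius:.3f} exceeds the membrane regime (0.15); "
                "the closed form degrades",
                stacklevel=2,
            )

    @property
    def enclosed_volume(self) -> float:
        """Mid-surface enclosed volume V0 = (4/3) pi R^3 (uL)."""
        return 4.0 / 3.0 * np.pi * self.radius**3


def _segment_stress(material: ViscoelasticMaterial, rate: float, t0: float, t1: float, t):
    """Uniaxial-form hereditary stress of a constant strain-rate segment.

    The segment runs over [t0, t1] with strain rate ``rate``; evaluated at
    times ``t`` (array), zero before t0.
    """
    t = np.asarray(t, dtype=float)
    tau_a = np.clip(t - t0, 0.0, None)  # time since segment start
    tau_b = np.clip(t - t1, 0.0, None)  # time since segment end
    active = np.minimum(t, t1) - np.minimum(t, t0)  # elapsed loading time
    out = material.equilibrium_modulus * rate * active
    for e_i, tau_i in zip(material.branch_moduli, material.time_constants):
        out = out + e_i * rate * tau_i * (np.exp(-tau_b / tau_i) - np.exp(-tau_a / tau_i)) * (
            t >= t0
        )
    return out


def oracle_pressure(spec: SphericalShellSpec, protocol: InfusionProtocol, t):
    """Pressure elevation dIOP (mmHg) at time(s) t under the infusion protocol.

    Supports t beyond the infusion end, where the pressure relaxes toward
    the equilibrium-modulus plateau with the material's time constants.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    m = spec.material
    strain_rate = protocol.rate / (3.0 * spec.enclosed_volume)
    sigma = _segment_stress(m, strain_rate, 0.0, protocol.duration, t_arr)
    factor = 2.0 * spec.thickness / ((1.0 - m.poisson_ratio) * spec.radius)
    dp = factor * sigma / MMHG_IN_MPA
    return dp if dp.ndim else float(dp)


def oracle_curve(spec: SphericalShellSpec, protocol: InfusionProtocol, n_points: int = 11):
    """dIOP-vs-injected-volume curve, evenly spaced in volume.

    Returns a DataFrame with columns time_s, volume_uL, dIOP_mmHg; the curve
    is non-decreasing and near-linear in volume for baseline-like materials.
    """
    import pandas as pd

    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    volumes = np.linspace(0.0, protocol.total_volume, n_points)
    times = volumes / protocol.rate
    diop = oracle_pressure(spec, protocol, times)
    return pd.DataFrame({"time_s": times, "volume_uL": volumes, "dIOP_mmHg": diop})
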