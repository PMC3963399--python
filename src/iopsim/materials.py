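"""Generalized Maxwell (Prony-series) viscoelasticity for corneoscleral tissue.

The cornea and sclera are modelled as nearly incompressible linear
viscoelastic solids: an equilibrium spring in parallel with ``m`` Maxwell
(spring--dashpot) branches.  The relaxation modulus is the Prony series

    E(t) = E_equ + sum_i E_i * exp(-t / tau_i),

so that ``E(0) = E_inst = E_equ + sum_i E_i`` and ``E(inf) = E_equ``.  The
default two-branch model carries a short time constant ``tau_s`` (sub-second
relaxation) and a long one ``tau_l`` (tens of seconds), with the branch
moduli set equal, ``E_1 = E_2 = (E_inst - E_equ) / 2``.

Units are MPa for moduli and seconds for time constants throughout.

For arbitrary strain histories the hereditary integral

    sigma(t) = E_equ eps(t) + sum_i int_0^t E_i exp(-(t-s)/tau_i) deps/ds ds

is advanced with the exact exponential recurrence per branch (exact for
strain varying linearly within a step), which stays stable for steps far
larger than the shortest time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ViscoelasticMaterial",
    "ViscoelasticState",
    "make_material",
    "scleral_from_corneal",
    "relaxation_modulus",
    "constant_rate_stress",
    "initial_state",
    "step_state",
    "CORNEA_BASELINE",
    "SCLERA_BASELINE",
]


class MaterialError(ValueError):
    """Invalid viscoelastic parameter set."""


@dataclass(frozen=True)
class ViscoelasticMaterial:
    """Prony-series material: equilibrium spring plus Maxwell branches.

    Parameters
    ----------
    equilibrium_modulus:
        Long-time (fully relaxed) modulus ``E_equ`` in MPa.
    branch_moduli:
        Moduli ``E_i`` of the Maxwell branches in MPa.
    time_constants:
        Relaxation time constants ``tau_i`` in seconds, sorted ascending
        (the first is the short-term constant, the last the long-term one).
    poisson_ratio:
        Poisson's ratio, held constant in time; 0.49 by default to express
        near-incompressibility.  The full stiffness relaxes proportionally,
        i.e. bulk and shear share the Prony spectrum.
    """

    equilibrium_modulus: float
    branch_moduli: tuple[float, ...]
    time_constants: tuple[float, ...]
    poisson_ratio: float = 0.49

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch_moduli", tuple(float(e) for e in self.branch_moduli))
        object.__setattr__(self, "time_constants", tuple(float(t) for t in self.time_constants))
        if self.equilibrium_modulus <= 0:
            raise MaterialError("equilibrium modulus must be positive")
        if len(self.branch_moduli) != len(self.time_constants):
            raise MaterialError("branch_moduli and time_constants must pair up")
        if any(e <= 0 for e in self.branch_moduli):
            raise MaterialError("branch moduli must be positive")
        if any(t <= 0 for t in self.time_constants):
            raise MaterialError("time constants must be positive")
        if list(self.time_constants) != sorted(self.time_constants):
            raise MaterialError("time constants must be sorted ascending")
        if len(set(self.time_constants)) != len(self.time_constants):
            raise MaterialError("time constants must be distinct")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise MaterialError("poisson_ratio must lie in (0, 0.5)")

    @property
    def instantaneous_modulus(self) -> float:
        """``E_inst = E_equ + sum_i E_i`` (MPa)."""
        return self.equilibrium_modulus + sum(self.branch_moduli)

    @property
    def branch_count(self) -> int:
        return len(self.branch_moduli)

    @property
    def short_time_constant(self) -> float:
        return self.time_constants[0]

    @property
    def long_time_constant(self) -> float:
        return self.time_constants[-1]

    def scaled(self, factor: float) -> "ViscoelasticMaterial":
        """Material with all moduli multiplied by ``factor`` (spectrum kept)."""
        if factor <= 0:
            raise MaterialError("scale factor must be positive")
        return ViscoelasticMaterial(
            equilibrium_modulus=factor * self.equilibrium_modulus,
            branch_moduli=tuple(factor * e for e in self.branch_moduli),
            time_constants=self.time_constants,
            poisson_ratio=self.poisson_ratio,
        )


def make_material(
    instantaneous_modulus: float,
    equilibrium_modulus: float,
    short_time_constant: float,
    long_time_constant: float,
    poisson_ratio: float = 0.49,
) -> ViscoelasticMaterial:
    """Two-branch material with the equal-branch rule E_1 = E_2 = (E_inst - E_equ)/2."""
    if instantaneous_modulus <= equilibrium_modulus:
        raise MaterialError(
            "no relaxation headroom: instantaneous modulus must exceed the equilibrium modulus"
        )
    if equilibrium_modulus <= 0:
        raise MaterialError("equilibrium modulus must be positive")
    if not 0 < short_time_constant < long_time_constant:
        raise MaterialError("require 0 < tau_s < tau_l")
    e_branch = 0.5 * (instantaneous_modulus - equilibrium_modulus)
    return ViscoelasticMaterial(
        equilibrium_modulus=equilibrium_modulus,
        branch_moduli=(e_branch, e_branch),
        time_constants=(short_time_constant, long_time_constant),
        poisson_ratio=poisson_ratio,
    )


def scleral_from_corneal(cornea: ViscoelasticMaterial, ratio: float = 5.0) -> ViscoelasticMaterial:
    """Scleral material tied to the corneal one by a stiffness ratio (default 5:1).

    Both moduli scale by the ratio; the relaxation time constants and
    Poisson's ratio are shared between the two tissues.
    """
    return cornea.scaled(ratio)


#: Baseline corneal material: E_inst 1.1 MPa, E_equ 0.265 MPa, tau 0.35 / 68 s.
CORNEA_BASELINE = make_material(1.1, 0.265, 0.35, 68.0)

#: Baseline scleral material, 5x the corneal moduli with the same spectrum.
SCLERA_BASELINE = scleral_from_corneal(CORNEA_BASELINE)


def relaxation_modulus(material: ViscoelasticMaterial, t):
    """Relaxation modulus E(t) in MPa; ``t`` may be a scalar or array (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation modulus requires t >= 0")
    out = np.full_like(t, material.equilibrium_modulus, dtype=float)
    for e_i, tau_i in zip(material.branch_moduli, material.time_constants):
        out = out + e_i * np.exp(-t / tau_i)
    return out if out.ndim else float(out)


def constant_rate_stress(material: ViscoelasticMaterial, strain_rate: float, t):
    """Uniaxial stress under constant strain rate, closed form (MPa).

    sigma(t) = E_equ * eps_dot * t + sum_i E_i * eps_dot * tau_i * (1 - exp(-t/tau_i)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("constant_rate_stress requires t >= 0")
    out = material.equilibrium_modulus * strain_rate * t
    for e_i, tau_i in zip(material.branch_moduli, material.time_constants):
        out = out + e_i * strain_rate * tau_i * (-np.expm1(-t / tau_i))
    return out if out.ndim else float(out)


@dataclass
class ViscoelasticState:
    """Internal-variable memory of the hereditary integral at one material point.

    ``strain`` holds the current total strain (any array shape; a scalar array
    for uniaxial use, a tensor for multiaxial), ``branch_stresses`` one internal
    stress per Maxwell branch with the same shape, and ``time`` the current
    simulation time in seconds.
    """

    strain: np.ndarray
    branch_stresses: np.ndarray  # (m, *strain.shape)
    time: float = 0.0

    def stress(self, material: ViscoelasticMaterial) -> np.ndarray:
        """Current total stress: equilibrium part plus branch memory (MPa)."""
        return material.equilibrium_modulus * self.strain + self.branch_stresses.sum(axis=0)


def initial_state(material: ViscoelasticMaterial, shape: tuple[int, ...] = ()) -> ViscoelasticState:
    """Virgin state: zero strain history, all branch stresses zero."""
    return ViscoelasticState(
        strain=np.zeros(shape),
        branch_stresses=np.zeros((material.branch_count, *shape)),
        time=0.0,
    )


def branch_step_coefficients(material: ViscoelasticMaterial, dt: float):
    """Per-branch decay ``exp(-dt/tau_i)`` and increment weight.

    For strain varying linearly over the step the branch update

        q_i(t+dt) = exp(-dt/tau_i) q_i(t) + E_i * (tau_i/dt) * (1 - exp(-dt/tau_i)) * deps

    is the exact solution of the branch evolution equation, hence
    unconditionally stable and second-order accurate for smooth histories.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    tau = np.asarray(material.time_constants)
    decay = np.exp(-dt / tau)
    weight = np.asarray(material.branch_moduli) * (tau / dt) * (-np.expm1(-dt / tau))
    return decay, weight


def step_state(
    material: ViscoelasticMaterial,
    state: ViscoelasticState,
    strain_increment,
    dt: float,
) -> tuple[ViscoelasticState, np.ndarray]:
    """Advance the internal variables one step; return (new state, stress).

    The recurrence is exact for piecewise-linear strain within the step.
    """
    decay, weight = branch_step_coefficients(material, dt)
    d_eps = np.asarray(strain_increment, dtype=float)
    new_strain = state.strain + d_eps
    new_q = decay.reshape((-1,) + (1,) * d_eps.ndim) * state.branch_stresses + (
        weight.reshape((-1,) + (1,) * d_eps.ndim) * d_eps
    )
    new_state = ViscoelasticState(strain=new_strain, branch_stresses=new_q, time=state.time + dt)
    return new_state, new_state.stress(material)
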