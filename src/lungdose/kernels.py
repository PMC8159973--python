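"""Particle physical properties and per-airway deposition efficiencies.

Three mechanisms remove particles from the airborne bolus: gravitational
sedimentation (Stokes settling in an inclined tube), inertial impaction at
bifurcations (Yeh–Schum efficiency) and Brownian diffusion to the tube wall
(Ingham laminar series).  Each kernel returns a per-airway-transit
deposition probability; the transport solver converts probabilities to
first-order loss rates via the local residence time.  Kernels are pluggable
through a registry so alternative published efficiencies can be swapped in
without touching the solver.

Also houses the nondimensional numbers used for extrathoracic reporting:
the tracheal Reynolds number Re = 4 ρ Q_mean / (π µ D) and the Stokes
number Stk = ρ_p Cc d_p² w / (18 µ d_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class PhysicalConstants:
    """Air and environment properties (SI, body temperature)."""

    rho_air: float = 1.2          # kg/m³
    mu: float = 1.8e-5            # Pa·s
    g: float = 9.81               # m/s²
    mfp_um: float = 0.066         # air mean free path, µm
    k_B: float = 1.380649e-23     # J/K
    T: float = 310.0              # K

    def __post_init__(self) -> None:
        for name in ("rho_air", "mu", "g", "mfp_um", "k_B", "T"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"PhysicalConstants.{name} must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()


def slip_correction(d_p_um: float, mfp_um: float = DEFAULT_CONSTANTS.mfp_um) -> float:
    """Cunningham slip correction factor for a particle of diameter ``d_p_um`` µm."""
    if d_p_um <= 0:
        raise ValidationError("particle diameter must be positive")
    kn2 = 2.0 * mfp_um / d_p_um  # 2·Knudsen number
    return 1.0 + kn2 * (1.257 + 0.4 * math.exp(-0.55 * d_p_um / mfp_um))


@dataclass(frozen=True)
class ParticleSpec:
    """An aerosol particle: diameter (µm), density (g/mL) and derived transport properties."""

    d_p: float                     # µm
    rho_p: float = 1.0             # g/mL
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    Cc: float = field(init=False)
    v_s: float = field(init=False)   # settling velocity, m/s
    D_B: float = field(init=False)   # Brownian diffusivity, m²/s

    def __post_init__(self) -> None:
        if self.d_p <= 0 or self.rho_p <= 0:
            raise ValidationError("particle diameter and density must be positive")
        object.__setattr__(self, "Cc", slip_correction(self.d_p, self.constants.mfp_um))
        object.__setattr__(self, "v_s", settling_velocity(self, self.constants))
        object.__setattr__(self, "D_B", brownian_diffusivity(self, self.constants))


def settling_velocity(particle: "ParticleSpec", constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Stokes settling velocity v_s = ρ_p Cc d_p² g / (18 µ), m/s."""
    rho_p = particle.rho_p * 1000.0      # g/mL -> kg/m³
    d_p = particle.d_p * 1e-6            # µm -> m
    Cc = slip_correction(particle.d_p, constants.mfp_um)
    return rho_p * Cc * d_p**2 * constants.g / (18.0 * constants.mu)


def brownian_diffusivity(particle: "ParticleSpec", constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Stokes–Einstein diffusivity D_B = k_B T Cc / (3π µ d_p), m²/s."""
    d_p = particle.d_p * 1e-6
    Cc = slip_correction(particle.d_p, constants.mfp_um)
    return constants.k_B * constants.T * Cc / (3.0 * math.pi * constants.mu * d_p)


def reynolds_number(
    Q_mean_ml_s: float, D_mm: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Airway Reynolds number Re = 4 ρ Q_mean / (π µ D)."""
    if Q_mean_ml_s <= 0 or D_mm <= 0:
        raise ValidationError("flow and diameter must be positive")
    Q = Q_mean_ml_s * 1e-6  # m³/s
    D = D_mm * 1e-3
    return 4.0 * constants.rho_air * Q / (math.pi * constants.mu * D)


def mean_velocity(Q_mean_ml_s: float, d_c_mm: float) -> float:
    """Mean flow velocity w = Q / (π d_c²/4) through a circular section, m/s."""
    Q = Q_mean_ml_s * 1e-6
    d = d_c_mm * 1e-3
    return Q / (math.pi * d**2 / 4.0)


def stokes_number(
    particle: ParticleSpec,
    w_m_s: float,
    d_c_mm: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    use_slip: bool = True,
) -> float:
    """Stokes number Stk = ρ_p (Cc) d_p² w / (18 µ d_c).

    Slip correction is included by default; only then do published
    extrathoracic values for a 4.8 mm infant airway reproduce.
    """
    if w_m_s < 0 or d_c_mm <= 0:
        raise ValidationError("velocity must be non-negative and diameter positive")
    rho_p = particle.rho_p * 1000.0
    d_p = particle.d_p * 1e-6
    Cc = particle.Cc if use_slip else 1.0
    return rho_p * Cc * d_p**2 * w_m_s / (18.0 * constants.mu * d_c_mm * 1e-3)


# ---------------------------------------------------------------------------
# Deposition probability kernels (per airway transit)
# ---------------------------------------------------------------------------

def prob_sedimentation(v_s, residence_time, d, gravity_cos):
    """Sedimentation probability 1 − exp(−4 v_s cosφ t / (π d)) in a tube of diameter ``d`` m."""
    v_s = np.asarray(v_s, dtype=float)
    arg = 4.0 * v_s * np.asarray(gravity_cos) * np.asarray(residence_time) / (
        math.pi * np.asarray(d)
    )
    return np.clip(1.0 - np.exp(-arg), 0.0, 1.0)


def prob_impaction(stk, branch_angle_deg):
    """Yeh–Schum inertial impaction probability at a bifurcation.

    With x = θ·Stk (θ the branch angle in radians): P = 1 − (2/π) acos(x)
    + (1/π) sin(2 acos(x)) for x < 1, else 1.
    """
    stk = np.asarray(stk, dtype=float)
    theta = np.deg2rad(np.asarray(branch_angle_deg, dtype=float))
    x = np.clip(theta * stk, 0.0, 1.0)
    ac = np.arccos(x)
    p = 1.0 - (2.0 / math.pi) * ac + (1.0 / math.pi) * np.sin(2.0 * ac)
    p = np.where(x <= 0.0, 0.0, p)  # exact zero limit (sin(pi) roundoff)
    out = np.clip(p, 0.0, 1.0)
    return out if out.shape else float(out)


_INGHAM = ((0.819, 14.63), (0.0976, 89.22), (0.0325, 228.0))


def prob_diffusion(D_B, length, mean_speed, radius, residence_time=None):
    """Ingham laminar-tube diffusional deposition probability.

    Δ = D_B L / (4 u a²); when the mean speed is ~0 the pure-residence
    limit Δ = D_B t / (4 a²) is used instead (requires ``residence_time``).
    """
    length = np.asarray(length, dtype=float)
    u = np.asarray(mean_speed, dtype=float)
    a2 = np.asarray(radius, dtype=float) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(u > 1e-12, D_B * length / (4.0 * u * a2), np.inf)
    if residence_time is not None:
        delta = np.where(
            np.isinf(delta), D_B * np.asarray(residence_time) / (4.0 * a2), delta
        )
    delta = np.minimum(delta, 50.0)  # series saturates; avoid overflow warnings
    p = 1.0
    for coef, expo in _INGHAM:
        p = p - coef * np.exp(-expo * delta)
    p = p - 0.0509 * np.exp(-125.9 * delta ** (2.0 / 3.0))
    return np.clip(p, 0.0, 1.0)


def combine_losses(P_list, residence_time=None, max_rate: float = 1e4):
    """Combine independent per-transit probabilities into survival and loss rate.

    survival = Π(1 − P_i); if ``residence_time`` is given, also return the
    first-order loss rate −ln(survival)/t (capped at ``max_rate`` 1/s).
    """
    survival = 1.0
    for P in P_list:
        P = np.asarray(P, dtype=float)
        if np.any(P < 0.0) or np.any(P > 1.0):
            raise ValidationError("probabilities must lie in [0, 1]")
        survival = survival * (1.0 - P)
    if residence_time is None:
        return survival
    with np.errstate(divide="ignore"):
        rate = np.where(
            survival > 0.0,
            -np.log(np.maximum(survival, 1e-300)) / np.asarray(residence_time),
            max_rate,
        )
    return survival, np.minimum(rate, max_rate)


def prob_to_rate(P, residence_time, max_rate: float = 1e4):
    """First-order rate −ln(1−P)/t for one mechanism, capped at ``max_rate`` 1/s."""
    P = np.clip(np.asarray(P, dtype=float), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        rate = -np.log1p(-np.minimum(P, 1.0 - 1e-15)) / np.asarray(residence_time)
    return np.minimum(rate, max_rate)


# ---------------------------------------------------------------------------
# Kernel registry
# ---------------------------------------------------------------------------
# Each kernel maps (particle, constants, geometry/flow arrays) -> per-transit
# deposition probability per cell.  Geometry arguments are SI arrays:
# ``diameter`` (m), ``length`` (m), ``speed`` (m/s, magnitude),
# ``t_res`` (s), plus per-cell ``gravity_cos`` and ``branch_angle_deg``.

def _sedimentation_stokes(particle, constants, *, diameter, length, speed,
                          t_res, gravity_cos, branch_angle_deg,
                          settle_diameter=None):
    d = diameter if settle_diameter is None else settle_diameter
    return prob_sedimentation(particle.v_s, t_res, d, gravity_cos)


def _impaction_yeh_schum(particle, constants, *, diameter, length, speed,
                         t_res, gravity_cos, branch_angle_deg,
                         settle_diameter=None):
    rho_p = particle.rho_p * 1000.0
    stk = rho_p * particle.Cc * (particle.d_p * 1e-6) ** 2 * speed / (
        18.0 * constants.mu * diameter
    )
    return prob_impaction(stk, branch_angle_deg)


def _diffusion_ingham(particle, constants, *, diameter, length, speed,
                      t_res, gravity_cos, branch_angle_deg,
                      settle_diameter=None):
    return prob_diffusion(particle.D_B, length, speed, diameter / 2.0, t_res)


# Exposure class: "resident" rates act on all mass held in a cell
# (settling happens wherever the aerosol sits); "transit" probabilities are
# incurred once per duct/bifurcation passage, so the solver exposes only
# the through-flowing mass flux to them.
_sedimentation_stokes.exposure = "resident"
_impaction_yeh_schum.exposure = "transit"
_diffusion_ingham.exposure = "transit"

KERNEL_REGISTRY: dict[str, object] = {
    "sedimentation.stokes": _sedimentation_stokes,
    "impaction.yeh_schum": _impaction_yeh_schum,
    "diffusion.ingham": _diffusion_ingham,
}

DEFAULT_KERNELS = (
    "sedimentation.stokes",
    "impaction.yeh_schum",
    "diffusion.ingham",
)


def get_kernel(key: str):
    """Look up a registered deposition kernel by its registry key."""
    try:
        return KERNEL_REGISTRY[key]
    except KeyError:
        raise LookupError(
            f"unknown kernel {key!r}; registered: {sorted(KERNEL_REGISTRY)}"
        ) from None


def register_kernel(key: str, fn) -> None:
    """Register (or replace) a deposition kernel under ``key``."""
    KERNEL_REGISTRY[key] = fn


def mechanism_of(key: str) -> str:
    """Mechanism name of a registry key (the part before the dot)."""
    return key.split(".", 1)[0]
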