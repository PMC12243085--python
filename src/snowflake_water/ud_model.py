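"""Statistical-mechanical core of the analytical 2D water model.

Each water molecule has three equivalent interaction arms, and each arm is
in one of three pair states: hydrogen bonded (HB), Lennard-Jones contact
(LJ), or noninteracting (0).  The pair energies are

    u_HB(theta) = -eps_HB - eps_LJ + k_s * theta**2   for |theta| < pi/3
    u_LJ        = -eps_LJ
    u_0         = 0

A hexagon of six molecules carries the isothermal-isobaric partition
function

    Q1 = (D_HB + D_LJ + D_0)**6 - D_HB**6 + delta * D_s**6

where the D_i are per-arm statistical weights, the s state is the
cooperative all-bonded hexagon, and delta = exp(-beta*eps_c) is the
Boltzmann factor of the cooperative energy.  State populations are the
logarithmic derivatives f_i = (d ln Q1 / d ln D_i) / 6 and thermodynamic
response functions follow from g = -T ln(Q1) / 6 by standard relations.

The per-arm weights are constructed as

    D_j = Omega_j(T) * exp(-beta * (u_j_min + p * v_j))

with configurational factors Omega_j and cell areas v_j documented on
:class:`DefaultWeightModel`.  The weight model is pluggable: any object
with the same ``__call__`` signature can be passed to :func:`state_weights`
and everything downstream (populations, thermodynamics, snowflake growth)
picks it up unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from scipy.integrate import quad

from .params import ModelParams, StatePoint

__all__ = [
    "StateWeights",
    "Populations",
    "ThermoProperties",
    "energy_hb",
    "DefaultWeightModel",
    "state_weights",
    "hexagon_partition",
    "populations",
    "populations_from_weights",
    "thermo_properties",
]

THETA_MAX = math.pi / 3.0  # half-width of the HB angular window


@dataclass(frozen=True)
class StateWeights:
    """Per-arm isothermal-isobaric weights at one state point."""

    delta_HB: float
    delta_LJ: float
    delta_0: float
    delta_s: float
    delta_coop: float  # delta = exp(-beta * eps_c)

    def __post_init__(self) -> None:
        for name in ("delta_HB", "delta_LJ", "delta_0", "delta_s"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"StateWeights.{name} must be finite and >= 0, got {v}")
        if not (self.delta_coop > 0 and math.isfinite(self.delta_coop)):
            raise ValueError(f"delta_coop must be finite and positive, got {self.delta_coop}")


@dataclass(frozen=True)
class Populations:
    """Probabilities of the four arm states (HB, LJ, 0, s)."""

    f_HB: float
    f_LJ: float
    f_0: float
    f_s: float

    def __post_init__(self) -> None:
        total = self.f_HB + self.f_LJ + self.f_0 + self.f_s
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"populations must sum to 1, got {total!r}")
        for name in ("f_HB", "f_LJ", "f_0", "f_s"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"Populations.{name} out of [0, 1]: {v}")

    @property
    def p_HB(self) -> float:
        """Probability that a new snowflake arm forms a hydrogen bond.

        The cooperative s state is an all-bonded hexagon, so its
        population counts toward hydrogen bonding.
        """
        return self.f_HB + self.f_s

    def as_array(self) -> np.ndarray:
        return np.array([self.f_HB, self.f_LJ, self.f_0, self.f_s])


@dataclass(frozen=True)
class ThermoProperties:
    """Thermodynamic observables per molecule at one state point."""

    volume_per_molecule: float
    density: float
    enthalpy_per_molecule: float
    alpha_p: float   # thermal expansion coefficient (1/v)(dv/dT)_p
    kappa_T: float   # isothermal compressibility -(1/v)(dv/dp)_T
    c_p: float       # isobaric heat capacity (dh/dT)_p


def energy_hb(theta: float, params: ModelParams) -> float:
    """Pair energy of a hydrogen bond bent by ``theta`` radians.

    Valid only inside the angular window |theta| < pi/3; outside of it the
    arm no longer points at the neighbor and no hydrogen bond exists.
    """
    if abs(theta) >= THETA_MAX:
        raise ValueError(f"|theta| must be < pi/3 for a hydrogen bond, got {theta}")
    return -params.eps_HB - params.eps_LJ + params.k_s * theta**2


def _hb_angular_integral(beta: float, k_s: float) -> float:
    """Integral of exp(-beta k_s theta^2) over the HB window (-pi/3, pi/3)."""
    val, _ = quad(lambda t: math.exp(-beta * k_s * t * t), -THETA_MAX, THETA_MAX)
    return val


class WeightModel(Protocol):
    def __call__(self, sp: StatePoint, params: ModelParams) -> StateWeights: ...


class DefaultWeightModel:
    """Default construction of the per-arm isothermal-isobaric weights.

    Cell areas (2D "volumes"):

    * ``v_s = (3*sqrt(3)/4) * r_HB**2`` -- area per molecule of a perfect
      honeycomb with bond length r_HB (the all-bonded solid).
    * ``v_HB = x_v * v_s`` -- liquid hydrogen-bond cell, rescaled by the
      preset's volume factor.
    * ``v_LJ = (sqrt(3)/2) * sigma_LJ**2`` -- hexagonally close-packed cell
      of discs with diameter sigma_LJ.
    * ``v_0 = T / p`` -- 2D ideal-gas cell area.

    Configurational factors:

    * ``Omega_HB = Omega_s = a * I_theta(T)`` where ``I_theta`` integrates
      the Boltzmann factor of the angular spring over the HB window and
      ``a`` is the radial well width.
    * ``Omega_LJ = a * (2*pi/3)`` -- radial width ``a`` times the free
      angular range of one arm sector.
    * ``Omega_0 = v_0`` -- the noninteracting molecule roams its cell.

    The cooperative factor ``delta = exp(-beta*eps_c)`` is carried
    separately and applied to the sixth power of ``delta_s`` in the
    hexagon partition function.
    """

    def __call__(self, sp: StatePoint, params: ModelParams) -> StateWeights:
        beta = sp.beta
        v_s = (3.0 * math.sqrt(3.0) / 4.0) * params.r_HB**2
        v_HB = params.x_v * v_s
        v_LJ = (math.sqrt(3.0) / 2.0) * params.sigma_LJ**2
        v_0 = sp.T / sp.p

        i_theta = _hb_angular_integral(beta, params.k_s)
        u_bond = -params.eps_HB - params.eps_LJ

        d_HB = params.a * i_theta * math.exp(-beta * (u_bond + sp.p * v_HB))
        d_s = params.a * i_theta * math.exp(-beta * (u_bond + sp.p * v_s))
        d_LJ = params.a * (2.0 * math.pi / 3.0) * math.exp(
            -beta * (-params.eps_LJ + sp.p * v_LJ)
        )
        d_0 = v_0 * math.exp(-beta * sp.p * v_0)  # exp(-1): p*v_0 = T
        return StateWeights(
            delta_HB=d_HB,
            delta_LJ=d_LJ,
            delta_0=d_0,
            delta_s=d_s,
            delta_coop=math.exp(-beta * params.eps_c),
        )

    def cell_areas(self, sp: StatePoint, params: ModelParams) -> dict[str, float]:
        """Cell areas v_i per state, for the volume consistency check."""
        v_s = (3.0 * math.sqrt(3.0) / 4.0) * params.r_HB**2
        return {
            "HB": params.x_v * v_s,
            "LJ": (math.sqrt(3.0) / 2.0) * params.sigma_LJ**2,
            "0": sp.T / sp.p,
            "s": v_s,
        }


_default_weight_model = DefaultWeightModel()


def state_weights(
    sp: StatePoint, params: ModelParams, model: WeightModel | None = None
) -> StateWeights:
    """Per-arm statistical weights at a state point (pluggable weight model)."""
    return (model or _default_weight_model)(sp, params)


def hexagon_partition(weights: StateWeights) -> float:
    """Partition function of a six-molecule hexagon.

    Q1 = (D_HB + D_LJ + D_0)**6 - D_HB**6 + delta * D_s**6.  The all-HB
    term of the independent-arm expansion is replaced by the cooperative
    solid term.
    """
    s = weights.delta_HB + weights.delta_LJ + weights.delta_0
    q1 = s**6 - weights.delta_HB**6 + weights.delta_coop * weights.delta_s**6
    if not (q1 > 0 and math.isfinite(q1)):
        raise ArithmeticError(f"hexagon partition function is not positive: {q1}")
    return q1


def populations_from_weights(weights: StateWeights, numerical: bool = False) -> Populations:
    """State populations f_i = (d ln Q1 / d ln D_i) / 6 for given weights.

    The analytic expressions follow from differentiating Q1; with
    S = D_HB + D_LJ + D_0:

        f_HB = D_HB * (S**5 - D_HB**5) / Q1
        f_LJ = D_LJ * S**5 / Q1
        f_0  = D_0  * S**5 / Q1
        f_s  = delta * D_s**6 / Q1

    ``numerical=True`` instead uses a centered finite difference of
    ln Q1 in ln D_i (step 1e-6), which is the independent cross-check.
    """
    if numerical:
        return _populations_numerical(weights)
    q1 = hexagon_partition(weights)
    s = weights.delta_HB + weights.delta_LJ + weights.delta_0
    f_hb = weights.delta_HB * (s**5 - weights.delta_HB**5) / q1
    f_lj = weights.delta_LJ * s**5 / q1
    f_0 = weights.delta_0 * s**5 / q1
    f_s = weights.delta_coop * weights.delta_s**6 / q1
    # guard rounding of the Euler identity before the dataclass validates
    total = f_hb + f_lj + f_0 + f_s
    return Populations(f_HB=f_hb / total, f_LJ=f_lj / total, f_0=f_0 / total, f_s=f_s / total)


def _populations_numerical(weights: StateWeights, rel_step: float = 1e-6) -> Populations:
    base = [weights.delta_HB, weights.delta_LJ, weights.delta_0, weights.delta_s]

    def log_q1(d: list[float]) -> float:
        s = d[0] + d[1] + d[2]
        return math.log(s**6 - d[0] ** 6 + weights.delta_coop * d[3] ** 6)

    f = []
    for i in range(4):
        if base[i] == 0.0:
            f.append(0.0)
            continue
        up = list(base)
        dn = list(base)
        up[i] = base[i] * math.exp(rel_step)
        dn[i] = base[i] * math.exp(-rel_step)
        f.append((log_q1(up) - log_q1(dn)) / (2.0 * rel_step) / 6.0)
    total = sum(f)
    return Populations(*(x / total for x in f))


def populations(
    sp: StatePoint, params: ModelParams, model: WeightModel | None = None
) -> Populations:
    """State populations at a thermodynamic state point."""
    return populations_from_weights(state_weights(sp, params, model))


def _gibbs_per_molecule(
    T: float, p: float, params: ModelParams, model: WeightModel | None
) -> float:
    w = state_weights(StatePoint(T=T, p=p), params, model)
    return -T * math.log(hexagon_partition(w)) / 6.0


def thermo_properties(
    sp: StatePoint,
    params: ModelParams,
    model: WeightModel | None = None,
    rel_step: float = 1e-4,
) -> ThermoProperties:
    """Thermodynamic response functions by centered finite differences.

    From g = -T ln(Q1)/6: v = (dg/dp)_T, h = (d(g/T)/d(1/T))_p, and the
    responses alpha_p, kappa_T, c_p are second differences.  The relative
    step (default 1e-4) applies to the differentiated variable.  Near the
    melting region the weights switch sharply and finite differences
    become step-sensitive; values there are reported as computed, not
    smoothed.
    """
    g: Callable[[float, float], float] = lambda T, p: _gibbs_per_molecule(T, p, params, model)

    def volume(T: float, p: float) -> float:
        hp = p * rel_step
        return (g(T, p + hp) - g(T, p - hp)) / (2.0 * hp)

    def enthalpy(T: float, p: float) -> float:
        # h = d(beta*g)/d(beta) at constant p
        beta = 1.0 / T
        hb = beta * rel_step
        bg = lambda b: g(1.0 / b, p) * b
        return (bg(beta + hb) - bg(beta - hb)) / (2.0 * hb)

    v = volume(sp.T, sp.p)
    if v <= 0:
        raise ArithmeticError(
            f"computed volume per molecule is not positive at (T={sp.T}, p={sp.p}): {v}"
        )
    ht = sp.T * rel_step
    hp = sp.p * rel_step
    dv_dT = (volume(sp.T + ht, sp.p) - volume(sp.T - ht, sp.p)) / (2.0 * ht)
    dv_dp = (volume(sp.T, sp.p + hp) - volume(sp.T, sp.p - hp)) / (2.0 * hp)
    dh_dT = (enthalpy(sp.T + ht, sp.p) - enthalpy(sp.T - ht, sp.p)) / (2.0 * ht)
    return ThermoProperties(
        volume_per_molecule=v,
        density=1.0 / v,
        enthalpy_per_molecule=enthalpy(sp.T, sp.p),
        alpha_p=dv_dT / v,
        kappa_T=-dv_dp / v,
        c_p=dh_dT,
    )
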