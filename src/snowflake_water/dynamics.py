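"""Random-walk model of diffusion built on the cell-theory populations.

Molecular transport is approximated as a 2D random walk whose step length
and step frequency depend on the interaction state of the molecule.  The
total diffusion coefficient is the population-weighted sum

    D = T * sum_i f_i * lambda_i**2 * nu_i,      nu_i = C * exp(beta * <u_i>)

over the four states HB, LJ, 0, and s.  Step lengths: the bonded states
move by one hydrogen-bond length, the LJ state by the contact diameter,
and the noninteracting state by the mean inter-molecule distance
sqrt(v_0) = sqrt(T/p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.integrate import quad

from .params import ModelParams, StatePoint
from .ud_model import THETA_MAX, Populations, populations

__all__ = [
    "STATES",
    "StateKinetics",
    "step_lengths",
    "mean_theta_sq",
    "mean_state_energy",
    "state_kinetics",
    "diffusion_coefficient",
]

STATES = ("HB", "LJ", "0", "s")


@dataclass(frozen=True)
class StateKinetics:
    """Per-state random-walk ingredients at one state point."""

    lambda_: dict
    nu: dict
    D: dict
    u_mean: dict


def step_lengths(sp: StatePoint, params: ModelParams) -> dict[str, float]:
    """Step length of each interaction state (reduced length)."""
    return {
        "HB": params.r_HB,
        "s": params.r_HB,
        "LJ": params.sigma_LJ,
        "0": math.sqrt(sp.T / sp.p),
    }


def mean_theta_sq(sp: StatePoint, params: ModelParams) -> float:
    """Boltzmann average of theta^2 under exp(-beta k_s theta^2) on (-pi/3, pi/3).

    Computed by adaptive quadrature on the truncated window, not from the
    untruncated Gaussian moment T/(2 k_s); the two agree only when
    beta*k_s is large.
    """
    bk = sp.beta * params.k_s
    num, _ = quad(lambda t: t * t * math.exp(-bk * t * t), -THETA_MAX, THETA_MAX)
    den, _ = quad(lambda t: math.exp(-bk * t * t), -THETA_MAX, THETA_MAX)
    return num / den


def mean_state_energy(state: str, sp: StatePoint, params: ModelParams) -> float:
    """Mean pair energy <u_i> of one interaction state.

    The s state is a cooperative hydrogen bond, so its mean energy adds
    the cooperative term eps_c to the HB mean energy.
    """
    if state == "0":
        return 0.0
    if state == "LJ":
        return -params.eps_LJ
    if state == "HB":
        return -params.eps_HB - params.eps_LJ + params.k_s * mean_theta_sq(sp, params)
    if state == "s":
        return mean_state_energy("HB", sp, params) + params.eps_c
    raise ValueError(f"unknown interaction state {state!r}; expected one of {STATES}")


def state_kinetics(sp: StatePoint, params: ModelParams) -> StateKinetics:
    """Step lengths, Boltzmann step frequencies, and per-state D_i."""
    lam = step_lengths(sp, params)
    nu = {
        s: params.C * math.exp(sp.beta * mean_state_energy(s, sp, params)) for s in STATES
    }
    d = {s: lam[s] ** 2 * nu[s] for s in STATES}
    u = {s: mean_state_energy(s, sp, params) for s in STATES}
    return StateKinetics(lambda_=lam, nu=nu, D=d, u_mean=u)


def diffusion_coefficient(
    sp: StatePoint, params: ModelParams, pops: Populations | None = None
) -> float:
    """Total diffusion coefficient D = T * sum_i f_i * D_i (reduced units)."""
    if pops is None:
        pops = populations(sp, params)
    kin = state_kinetics(sp, params)
    f = {"HB": pops.f_HB, "LJ": pops.f_LJ, "0": pops.f_0, "s": pops.f_s}
    return sp.T * sum(f[s] * kin.D[s] for s in STATES)
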