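"""Model parameters, thermodynamic state points, and named presets.

The model lives entirely in reduced units: the hydrogen-bond energy
``eps_HB`` sets the energy unit and the hydrogen-bond length ``r_HB`` the
length unit, so temperature is ``k_B T / |eps_HB|`` and the 2D pressure is
``p r_HB^2 / |eps_HB|``.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "ModelParams",
    "StatePoint",
    "load_preset",
    "available_presets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter record for one parametrization of the analytical model.

    Attributes
    ----------
    eps_HB : float
        Hydrogen-bond energy constant; defines the reduced energy unit (= 1).
    eps_LJ : float
        Lennard-Jones contact energy.
    k_s : float
        Angular spring constant of the hydrogen bond (energy / rad^2).
    eps_c : float
        Cooperative hydrogen-bond energy; negative values favor the
        all-bonded solid state through delta = exp(-beta * eps_c).
    r_HB : float
        Hydrogen-bond length; defines the reduced length unit (= 1).
    x_v : float
        Scale factor applied to the honeycomb cell area to obtain the
        liquid hydrogen-bond state cell area.
    sigma_LJ : float
        Lennard-Jones diameter.
    a : float
        Well-width parameter entering the configurational weight factors.
    C : float
        Frequency unit constant of the random-walk diffusion model.
    m_1, m_3 : float
        Molecular mass and moment of inertia.  The moment of inertia is
        that of three arms of mass 0.1 at distance 0.35 from the center,
        m_3 = 3 * 0.1 * 0.35**2 = 0.03675.
    q : float
        Angle between the interaction arms, 2*pi/3 (120 degrees).
    A : float
        Empirical thermal-noise scale of the structural (snowflake) model.
    k_HB : float
        Radial and angular harmonic constant of hydrogen-bond placement
        noise; equals 2*k_s because the structural part writes the
        harmonic potential with a 1/2 prefactor.
    k_LJ : float
        Harmonic constant fitted to the Lennard-Jones well.
    k_0 : float
        Harmonic constant of the noninteracting state (small, so that
        noninteracting neighbors are scattered broadly).
    """

    eps_HB: float = 1.0
    eps_LJ: float = 0.1
    k_s: float = 16.0
    eps_c: float = -0.05
    r_HB: float = 1.0
    x_v: float = 1.0
    sigma_LJ: float = 0.7
    a: float = 0.06
    C: float = 0.5
    m_1: float = 1.0
    m_3: float = 0.03675
    q: float = 2.0 * math.pi / 3.0
    A: float = 0.65
    k_HB: float = 32.0
    k_LJ: float = 10.0
    k_0: float = 0.001

    def __post_init__(self) -> None:
        for name in ("eps_HB", "k_s", "sigma_LJ", "r_HB", "A", "k_HB", "k_LJ", "k_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ModelParams.{name} must be positive, got {getattr(self, name)}")

    def with_overrides(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StatePoint:
    """A reduced thermodynamic state point (T, p)."""

    T: float
    p: float
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.p <= 0:
            raise ValueError(f"pressure must be positive, got {self.p}")
        object.__setattr__(self, "beta", 1.0 / self.T)


def _read_preset_table() -> dict:
    text = resources.files("snowflake_water").joinpath("presets.toml").read_text()
    return tomllib.loads(text)


def available_presets() -> list[str]:
    """Names of the shipped parameter presets."""
    return sorted(_read_preset_table())


def load_preset(name: str | Path, **overrides: float) -> ModelParams:
    """Load a named preset (``"MB-rose"`` or ``"real-rose"``) or a TOML file.

    A path argument must point to a TOML file with the same field names as
    :class:`ModelParams`.  Keyword overrides replace individual fields.
    """
    name_str = str(name)
    if name_str in _read_preset_table():
        record = _read_preset_table()[name_str]
        log.info("preset %s: q and eps_c follow the corrected text values", name_str)
    else:
        path = Path(name)
        if not path.is_file():
            raise KeyError(
                f"unknown preset {name_str!r}; available presets: {available_presets()}"
            )
        record = tomllib.loads(path.read_text())
    params = ModelParams(**record)
    if overrides:
        params = params.with_overrides(**overrides)
    return params
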