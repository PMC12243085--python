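"""Stochastic growth of snowflake-like hydrogen-bond clusters.

Clusters are grown shell by shell from a central molecule at the origin.
Each frontier molecule offers its free arms (all three for the central
molecule, two for everyone else, since arm 0 points back to the parent);
for every arm an interaction type is sampled from the cell-theory state
populations (HB with probability f_HB + f_s, LJ with f_LJ, noninteracting
with f_0) and a new molecule is proposed at

    x_child = x + cos(theta + k*q + Z_theta) * (r_j + Z_r)
    y_child = y + sin(theta + k*q + Z_theta) * (r_j + Z_r)
    theta_child = theta + k*q + Z_theta + pi

with thermal placement noise Z_r, Z_theta.  A candidate is rejected if it
comes closer than sigma_LJ - 0.05 to any existing molecule; the one
exception is a candidate of shell >= 2 that falls within r_LJ of the
*central* molecule, which is accepted with probability
exp(-k_LJ (r - r_LJ)^2 / T) to keep the radial distribution function
continuous at small distances.  Placement is retried with fresh noise up
to ``max_attempts`` times; on failure that branch of the snowflake is
terminated.  Growth stops at ``max_shells`` or when every branch has
terminated.

Two engines produce ensembles: a readable pure-Python reference
(:func:`grow_snowflake`, built from the operation functions below) and a
numba kernel used by :func:`generate_ensemble` for 10^4--10^5 replica
runs.  Both implement the same algorithm; their random streams differ, so
reproducibility is per engine and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numba import njit

from .params import ModelParams, StatePoint
from .ud_model import Populations, populations

__all__ = [
    "BOND_HB",
    "BOND_LJ",
    "BOND_NONE",
    "BOND_NAMES",
    "Molecule",
    "GrowthConfig",
    "Snowflake",
    "interaction_lengths",
    "noise_sigmas",
    "sample_interaction",
    "sample_noise",
    "propose_child",
    "accept_placement",
    "grow_snowflake",
    "generate_ensemble",
]

# integer codes for the interaction that created a molecule
BOND_HB, BOND_LJ, BOND_NONE = 0, 1, 2
BOND_NAMES = {BOND_HB: "HB", BOND_LJ: "LJ", BOND_NONE: "0"}
_BOND_CODES = {v: k for k, v in BOND_NAMES.items()}


@dataclass(frozen=True)
class Molecule:
    """One molecule in a snowflake (reduced coordinates, lab = body frame)."""

    x: float
    y: float
    theta: float
    shell: int
    parent: int = -1          # index of the source molecule; -1 for the center
    bond_type: int = -1       # BOND_* code of the creating interaction; -1 for the center


@dataclass(frozen=True)
class GrowthConfig:
    """Run configuration of the snowflake generator.

    Defaults follow the published calculations: at most 9 shells, 100,000
    replicas, 10 placement attempts per branch, and a hard-core distance
    of sigma_LJ minus an overlap margin of 0.05.
    """

    max_shells: int = 9
    n_replicas: int = 100_000
    max_attempts: int = 10
    overlap_margin: float = 0.05
    seed: int | None = None
    populations_override: Populations | None = None
    zero_noise: bool = False

    def __post_init__(self) -> None:
        if self.max_shells < 0:
            raise ValueError("max_shells must be >= 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")


@dataclass
class Snowflake:
    """A grown cluster stored as parallel arrays (index 0 is the center)."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    shell: np.ndarray
    parent: np.ndarray
    bond_type: np.ndarray
    terminated: bool = True   # True when no branch reached max_shells

    @property
    def n_molecules(self) -> int:
        return len(self.x)

    def molecules(self) -> list[Molecule]:
        return [
            Molecule(
                x=float(self.x[i]),
                y=float(self.y[i]),
                theta=float(self.theta[i]),
                shell=int(self.shell[i]),
                parent=int(self.parent[i]),
                bond_type=int(self.bond_type[i]),
            )
            for i in range(self.n_molecules)
        ]


def interaction_lengths(sp: StatePoint, params: ModelParams) -> dict[str, float]:
    """Bond length of each interaction type.

    r_HB is the hydrogen-bond length, r_LJ = sigma_LJ * 2**(1/6) is the
    Lennard-Jones minimum distance, and the noninteracting neighbor sits
    one mean free distance sqrt(T/p) beyond the LJ contact.
    """
    r_lj = params.sigma_LJ * 2.0 ** (1.0 / 6.0)
    return {
        "HB": params.r_HB,
        "LJ": r_lj,
        "0": math.sqrt(sp.T / sp.p) + r_lj,
    }


def noise_sigmas(sp: StatePoint, params: ModelParams) -> dict[str, float]:
    """Standard deviations of the thermal placement noise.

    Each interaction is approximated by a harmonic well; equipartition
    gives a positional spread sqrt(T/k_j), scaled by the empirical factor
    A and the mass (radial) or moment of inertia (angular):

        sigma_r(j)   = A * sqrt(T / (m_1 * k_j))      j in {HB, LJ, 0}
        sigma_th(HB) = A * sqrt(T / (m_3 * k_HB))

    The LJ and noninteracting angular noise is uniform on (-pi/3, pi/3)
    rather than Gaussian: those contacts have no angular spring.
    """
    t = sp.T
    return {
        "r_HB": params.A * math.sqrt(t / (params.m_1 * params.k_HB)),
        "r_LJ": params.A * math.sqrt(t / (params.m_1 * params.k_LJ)),
        "r_0": params.A * math.sqrt(t / (params.m_1 * params.k_0)),
        "theta_HB": params.A * math.sqrt(t / (params.m_3 * params.k_HB)),
    }


def sample_interaction(pop: Populations, rng: np.random.Generator) -> int:
    """Draw the interaction type of a new arm from the state populations."""
    u = rng.random()
    if u < pop.p_HB:
        return BOND_HB
    if u < pop.p_HB + pop.f_LJ:
        return BOND_LJ
    return BOND_NONE


def sample_noise(
    j: int,
    sp: StatePoint,
    params: ModelParams,
    rng: np.random.Generator,
    zero_noise: bool = False,
) -> tuple[float, float]:
    """Sample the radial and angular placement noise for bond type ``j``."""
    if zero_noise:
        return 0.0, 0.0
    sig = noise_sigmas(sp, params)
    if j == BOND_HB:
        return rng.normal(0.0, sig["r_HB"]), rng.normal(0.0, sig["theta_HB"])
    if j == BOND_LJ:
        return rng.normal(0.0, sig["r_LJ"]), rng.uniform(-math.pi / 3, math.pi / 3)
    if j == BOND_NONE:
        return rng.normal(0.0, sig["r_0"]), rng.uniform(-math.pi / 3, math.pi / 3)
    raise ValueError(f"unknown bond type code {j}")


def propose_child(
    parent: Molecule,
    parent_index: int,
    k: int,
    j: int,
    sp: StatePoint,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    zero_noise: bool = False,
    noise: tuple[float, float] | None = None,
) -> Molecule:
    """Propose a new molecule on arm ``k`` of ``parent`` via interaction ``j``.

    The central molecule grows on arms {0, 1, 2}; every later molecule
    only on {1, 2}, because its arm 0 points back to its own parent.
    Placement noise is drawn from ``rng`` unless ``noise=(z_r, z_theta)``
    is supplied explicitly.
    """
    allowed = (0, 1, 2) if parent.shell == 0 else (1, 2)
    if k not in allowed:
        raise ValueError(f"arm index {k} invalid for a shell-{parent.shell} molecule")
    r_j = interaction_lengths(sp, params)[BOND_NAMES[j]]
    if noise is None:
        if rng is None:
            raise ValueError("either rng or explicit noise must be given")
        noise = sample_noise(j, sp, params, rng, zero_noise)
    z_r, z_theta = noise
    ang = parent.theta + k * params.q + z_theta
    length = r_j + z_r
    return Molecule(
        x=parent.x + math.cos(ang) * length,
        y=parent.y + math.sin(ang) * length,
        theta=ang + math.pi,
        shell=parent.shell + 1,
        parent=parent_index,
        bond_type=j,
    )


def accept_placement(
    cand: Molecule,
    existing_xy: np.ndarray,
    sp: StatePoint,
    params: ModelParams,
    rng: np.random.Generator,
    overlap_margin: float = 0.05,
) -> bool:
    """Hard-core acceptance test of a candidate against the current cluster.

    ``existing_xy`` is the (n, 2) array of already-placed positions with
    the central molecule in row 0.  The candidate is rejected when it
    comes within sigma_LJ - overlap_margin of any molecule, except that a
    shell >= 2 candidate closer than r_LJ to the central molecule is
    instead accepted with probability exp(-k_LJ (r - r_LJ)^2 / T).
    """
    cut = params.sigma_LJ - overlap_margin
    r_lj = params.sigma_LJ * 2.0 ** (1.0 / 6.0)
    d_central = math.hypot(cand.x, cand.y)
    if cand.shell >= 2 and d_central < r_lj:
        p_acc = math.exp(-params.k_LJ * (d_central - r_lj) ** 2 / sp.T)
        if rng.random() >= p_acc:
            return False
    elif d_central < cut:
        return False
    if len(existing_xy) > 1:
        others = existing_xy[1:]
        d2 = (others[:, 0] - cand.x) ** 2 + (others[:, 1] - cand.y) ** 2
        if np.any(d2 < cut * cut):
            return False
    return True


def _capacity(max_shells: int) -> int:
    return 1 + 3 * ((1 << max_shells) - 1) if max_shells >= 1 else 1


def grow_snowflake(
    sp: StatePoint,
    params: ModelParams,
    pop: Populations,
    cfg: GrowthConfig,
    rng: np.random.Generator,
) -> Snowflake:
    """Grow one snowflake (pure-Python reference engine)."""
    mols: list[Molecule] = [Molecule(0.0, 0.0, 0.0, shell=0)]
    xy = np.zeros((_capacity(cfg.max_shells), 2))
    lengths = interaction_lengths(sp, params)
    i = 0
    while i < len(mols):
        parent = mols[i]
        if parent.shell >= cfg.max_shells:
            i += 1
            continue
        arms = (0, 1, 2) if parent.shell == 0 else (1, 2)
        for k in arms:
            j = sample_interaction(pop, rng)
            for _ in range(cfg.max_attempts):
                z = sample_noise(j, sp, params, rng, cfg.zero_noise)
                if lengths[BOND_NAMES[j]] + z[0] <= 0.0:
                    continue  # negative proposed bond length: failed attempt
                cand = propose_child(parent, i, k, j, sp, params, noise=z)
                if accept_placement(
                    cand, xy[: len(mols)], sp, params, rng, cfg.overlap_margin
                ):
                    xy[len(mols)] = (cand.x, cand.y)
                    mols.append(cand)
                    break
        i += 1
    shells = np.array([m.shell for m in mols], dtype=np.int32)
    return Snowflake(
        x=np.array([m.x for m in mols]),
        y=np.array([m.y for m in mols]),
        theta=np.array([m.theta for m in mols]),
        shell=shells,
        parent=np.array([m.parent for m in mols], dtype=np.int32),
        bond_type=np.array([m.bond_type for m in mols], dtype=np.int8),
        terminated=bool(cfg.max_shells not in shells),
    )


@njit(cache=True)
def _grow_kernel(
    seed,
    max_shells,
    max_attempts,
    p_hb,
    p_lj,
    r_bond,      # (3,) bond lengths for HB, LJ, 0
    sigma_r,     # (3,) radial noise sigmas
    sigma_th_hb,
    q,
    cut,
    r_lj,
    k_lj,
    T,
    zero_noise,
):  # pragma: no cover - exercised through generate_ensemble
    np.random.seed(seed)
    cap = 1 + 3 * ((1 << max_shells) - 1) if max_shells >= 1 else 1
    x = np.zeros(cap)
    y = np.zeros(cap)
    th = np.zeros(cap)
    shell = np.zeros(cap, np.int32)
    parent = np.full(cap, -1, np.int32)
    btype = np.full(cap, -1, np.int8)
    n = 1
    third_pi = np.pi / 3.0
    i = 0
    while i < n:
        s = shell[i]
        if s >= max_shells:
            i += 1
            continue
        k_start = 0 if s == 0 else 1
        for k in range(k_start, 3):
            u = np.random.random()
            if u < p_hb:
                j = 0
            elif u < p_hb + p_lj:
                j = 1
            else:
                j = 2
            for _attempt in range(max_attempts):
                if zero_noise:
                    zr = 0.0
                    zth = 0.0
                else:
                    zr = np.random.normal(0.0, sigma_r[j])
                    if j == 0:
                        zth = np.random.normal(0.0, sigma_th_hb)
                    else:
                        zth = np.random.uniform(-third_pi, third_pi)
                length = r_bond[j] + zr
                if length <= 0.0:
                    continue
                ang = th[i] + k * q + zth
                cx = x[i] + np.cos(ang) * length
                cy = y[i] + np.sin(ang) * length
                cshell = s + 1
                ok = True
                d0 = np.sqrt(cx * cx + cy * cy)
                if cshell >= 2 and d0 < r_lj:
                    p_acc = np.exp(-k_lj * (d0 - r_lj) ** 2 / T)
                    if np.random.random() >= p_acc:
                        ok = False
                elif d0 < cut:
                    ok = False
                if ok:
                    for m in range(1, n):
                        dx = cx - x[m]
                        dy = cy - y[m]
                        if dx * dx + dy * dy < cut * cut:
                            ok = False
                            break
                if ok:
                    x[n] = cx
                    y[n] = cy
                    th[n] = ang + np.pi
                    shell[n] = cshell
                    parent[n] = i
                    btype[n] = j
                    n += 1
                    break
        i += 1
    reached = False
    for m in range(n):
        if shell[m] == max_shells:
            reached = True
            break
    return (
        x[:n].copy(),
        y[:n].copy(),
        th[:n].copy(),
        shell[:n].copy(),
        parent[:n].copy(),
        btype[:n].copy(),
        not reached,
    )


def _grow_fast(
    sp: StatePoint,
    params: ModelParams,
    pop: Populations,
    cfg: GrowthConfig,
    seed: int,
) -> Snowflake:
    lengths = interaction_lengths(sp, params)
    sig = noise_sigmas(sp, params)
    x, y, th, shell, parent, btype, terminated = _grow_kernel(
        seed,
        cfg.max_shells,
        cfg.max_attempts,
        pop.p_HB,
        pop.f_LJ,
        np.array([lengths["HB"], lengths["LJ"], lengths["0"]]),
        np.array([sig["r_HB"], sig["r_LJ"], sig["r_0"]]),
        sig["theta_HB"],
        params.q,
        params.sigma_LJ - cfg.overlap_margin,
        params.sigma_LJ * 2.0 ** (1.0 / 6.0),
        params.k_LJ,
        sp.T,
        cfg.zero_noise,
    )
    return Snowflake(x, y, th, shell, parent, btype, terminated=bool(terminated))


def generate_ensemble(
    sp: StatePoint,
    params: ModelParams,
    cfg: GrowthConfig,
    rng: np.random.Generator | None = None,
    engine: str = "fast",
) -> Iterator[Snowflake]:
    """Yield ``cfg.n_replicas`` independent snowflakes.

    Populations come from the cell theory at (T, p) unless overridden in
    the config.  Reproducibility: a fixed ``cfg.seed`` gives an identical
    ensemble for a given engine ("fast" = numba kernel, "reference" =
    pure Python).
    """
    pop = cfg.populations_override or populations(sp, params)
    if engine not in ("fast", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    ss = np.random.SeedSequence(cfg.seed)
    if engine == "reference":
        for child_ss in ss.spawn(cfg.n_replicas):
            yield grow_snowflake(sp, params, pop, cfg, np.random.default_rng(child_ss))
    else:
        seeds = ss.generate_state(cfg.n_replicas, dtype=np.uint32) >> np.uint32(1)
        for s in seeds:
            yield _grow_fast(sp, params, pop, cfg, int(s))


def ensemble_list(
    sp: StatePoint,
    params: ModelParams,
    cfg: GrowthConfig,
    engine: str = "fast",
) -> list[Snowflake]:
    """Materialize :func:`generate_ensemble` as a list."""
    return list(generate_ensemble(sp, params, cfg, engine=engine))
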