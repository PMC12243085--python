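"""Structural observables of snowflake ensembles.

All distributions are referenced to the central molecule: every snowflake
is grown in the body frame of its center (arm 0 along 0 degrees), so the
radial distribution function (RDF), angular distribution functions (ADF)
at fixed radial shells, and the 2D spatial distribution function (SDF)
are histograms of neighbor positions about the origin, pooled over
replicas and normalized the way pair distributions are normalized in
standard simulations.

The model has exact C3 (120-degree rotation) and mirror symmetry about
the arm directions; :func:`angular_distribution` can optionally fold the
angles into the fundamental [0, 60] degree sector, which sharpens the
statistics by a factor of six.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .params import ModelParams, StatePoint
from .snowflake import Snowflake
from .ud_model import thermo_properties

__all__ = [
    "RadialDistribution",
    "AngularDistribution",
    "SpatialDistribution",
    "radial_distribution",
    "angular_distribution",
    "spatial_distribution",
    "find_peaks",
]


@dataclass
class RadialDistribution:
    """Central-molecule RDF with uniform radial bins."""

    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    n_replicas: int
    rho_ref: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class AngularDistribution:
    """ADF at a fixed radial shell, normalized to unit circular mean."""

    distance: float
    half_width: float
    bin_edges: np.ndarray  # degrees
    density: np.ndarray
    counts: np.ndarray
    n_replicas: int
    folded: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class SpatialDistribution:
    """2D body-frame density on a square grid centered on the molecule."""

    extent: float
    bin_edges: np.ndarray  # shared by x and y
    density: np.ndarray    # (n_grid, n_grid), rows = x bins
    counts: np.ndarray
    n_replicas: int
    rho_ref: float


def _pooled_xy(ensemble: Sequence[Snowflake]) -> tuple[np.ndarray, np.ndarray]:
    """Positions of all non-central molecules pooled over replicas."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    xs = np.concatenate([f.x[1:] for f in ensemble])
    ys = np.concatenate([f.y[1:] for f in ensemble])
    return xs, ys


def _reference_density(
    sp: StatePoint | None, params: ModelParams | None, rho_ref: float | None
) -> float:
    if rho_ref is not None:
        return rho_ref
    if sp is None or params is None:
        return 1.0
    return thermo_properties(sp, params).density


def radial_distribution(
    ensemble: Sequence[Snowflake],
    sp: StatePoint | None = None,
    params: ModelParams | None = None,
    bin_width: float = 0.02,
    r_max: float = 4.0,
    rho_ref: float | None = None,
    plateau_rescale: bool = False,
) -> RadialDistribution:
    """Central-molecule radial distribution function.

    Distances from the center are pooled over replicas, histogrammed with
    uniform bins, and divided by n_replicas * rho_ref * annulus area.  By
    default rho_ref is the cell-theory density at (T, p); beyond roughly
    4 hydrogen-bond lengths a 9-shell cluster no longer surrounds the
    center and the normalization becomes geometrically biased, hence the
    default r_max.  ``plateau_rescale`` rescales g so the mean over the
    outermost 10% of bins is 1.
    """
    xs, ys = _pooled_xy(ensemble)
    r = np.hypot(xs, ys)
    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    rho = _reference_density(sp, params, rho_ref)
    annulus = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = counts / (len(ensemble) * rho * annulus)
    if plateau_rescale:
        tail = g[-max(1, n_bins // 10):]
        scale = tail.mean()
        if scale > 0:
            g = g / scale
    return RadialDistribution(
        bin_edges=edges, g=g, counts=counts, n_replicas=len(ensemble), rho_ref=rho
    )


def fold_angles_deg(angles_deg: np.ndarray) -> np.ndarray:
    """Fold angles into the fundamental C3 + mirror sector [0, 60] degrees."""
    a = np.abs(angles_deg) % 120.0
    return np.where(a > 60.0, 120.0 - a, a)


def angular_distribution(
    ensemble: Sequence[Snowflake],
    distance: float,
    half_width: float = 0.05,
    n_bins: int = 180,
    fold: bool = False,
) -> AngularDistribution:
    """ADF of molecules in the shell ``distance +- half_width``.

    Angles are atan2(y, x) in the body frame of the central molecule
    (arm 0 at 0 degrees), histogrammed over (-180, 180] degrees -- or
    over [0, 60] when ``fold=True`` exploits the C3 + mirror symmetry --
    and normalized to unit circular mean.
    """
    if distance <= 0 or half_width <= 0:
        raise ValueError("distance and half_width must be positive")
    xs, ys = _pooled_xy(ensemble)
    r = np.hypot(xs, ys)
    mask = np.abs(r - distance) <= half_width
    if not np.any(mask):
        raise ValueError(
            f"no molecules found in the radial window {distance} +- {half_width}"
        )
    ang = np.degrees(np.arctan2(ys[mask], xs[mask]))
    if fold:
        ang = fold_angles_deg(ang)
        edges = np.linspace(0.0, 60.0, n_bins + 1)
    else:
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(ang, bins=edges)
    density = counts / counts.mean()
    return AngularDistribution(
        distance=distance,
        half_width=half_width,
        bin_edges=edges,
        density=density,
        counts=counts,
        n_replicas=len(ensemble),
        folded=fold,
    )


def spatial_distribution(
    ensemble: Sequence[Snowflake],
    extent: float = 3.0,
    n_grid: int = 200,
    sp: StatePoint | None = None,
    params: ModelParams | None = None,
    rho_ref: float | None = None,
) -> SpatialDistribution:
    """2D spatial distribution function on a square body-frame grid.

    A statistically averaged snapshot: the 2D histogram of neighbor
    positions over [-extent, extent]^2, normalized by replica count, cell
    area, and the reference density.
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    if n_grid < 16:
        raise ValueError("n_grid must be >= 16")
    xs, ys = _pooled_xy(ensemble)
    edges = np.linspace(-extent, extent, n_grid + 1)
    counts, _, _ = np.histogram2d(xs, ys, bins=[edges, edges])
    rho = _reference_density(sp, params, rho_ref)
    cell_area = (2.0 * extent / n_grid) ** 2
    density = counts / (len(ensemble) * cell_area * rho)
    return SpatialDistribution(
        extent=extent,
        bin_edges=edges,
        density=density,
        counts=counts,
        n_replicas=len(ensemble),
        rho_ref=rho,
    )


def find_peaks(
    dist: RadialDistribution | AngularDistribution,
    min_prominence: float = 0.0,
) -> list[tuple[float, float]]:
    """Local maxima of a binned distribution above a prominence threshold.

    Returns (location, height) pairs at bin centers, in order of
    ascending location (so equal-height ties resolve toward the smaller
    location).  A flat distribution has no local maxima; maxima in the
    outermost bins are not reported.
    """
    values = dist.g if isinstance(dist, RadialDistribution) else dist.density
    if len(values) == 0:
        raise ValueError("distribution is empty")
    idx, _ = signal.find_peaks(values, prominence=min_prominence or None)
    centers = dist.bin_centers
    return [(float(centers[i]), float(values[i])) for i in idx]
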