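"""Ensemble text format, TSV helpers, and reduced-to-SI unit conversion.

Ensembles are stored in an extended-XYZ-style plain-text format, one
block per snowflake::

    <molecule count>
    # replica=<i> terminated=<0|1> [free-form metadata]
    x y theta shell parent bond
    ...

Coordinates are written with 9 significant digits; ``bond`` is one of
``HB``, ``LJ``, ``0``, or ``-`` for the central molecule.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.constants import N_A

from .snowflake import BOND_NAMES, Snowflake

__all__ = ["ParseError", "write_ensemble", "read_ensemble", "pressure_to_si"]

_BOND_TOKENS = dict(BOND_NAMES)
_BOND_TOKENS[-1] = "-"
_TOKEN_BONDS = {v: k for k, v in _BOND_TOKENS.items()}


class ParseError(ValueError):
    """Malformed ensemble file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_ensemble(
    path: str | Path,
    flakes: Sequence[Snowflake] | Iterable[Snowflake],
    comment: str = "",
) -> None:
    """Write an ensemble to ``path`` (one text block per snowflake)."""
    with open(path, "w") as fh:
        _write_stream(fh, flakes, comment)


def _write_stream(fh: TextIO, flakes: Iterable[Snowflake], comment: str) -> None:
    extra = f" {comment}" if comment else ""
    for i, flake in enumerate(flakes):
        fh.write(f"{flake.n_molecules}\n")
        fh.write(f"# replica={i} terminated={int(flake.terminated)}{extra}\n")
        for m in range(flake.n_molecules):
            fh.write(
                "%.9g %.9g %.9g %d %d %s\n"
                % (
                    flake.x[m],
                    flake.y[m],
                    flake.theta[m],
                    flake.shell[m],
                    flake.parent[m],
                    _BOND_TOKENS[int(flake.bond_type[m])],
                )
            )


def read_ensemble(path: str | Path) -> list[Snowflake]:
    """Read an ensemble written by :func:`write_ensemble`."""
    flakes: list[Snowflake] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    ln = 0
    n_lines = len(lines)
    while ln < n_lines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            count = int(lines[ln].strip())
        except ValueError:
            raise ParseError(f"expected a molecule count, got {lines[ln]!r}", ln + 1)
        if count < 1:
            raise ParseError(f"molecule count must be >= 1, got {count}", ln + 1)
        if ln + 1 >= n_lines or not lines[ln + 1].lstrip().startswith("#"):
            raise ParseError("expected a '#' comment line after the count", ln + 2)
        terminated = "terminated=1" in lines[ln + 1]
        start = ln + 2
        if start + count > n_lines:
            raise ParseError(
                f"truncated block: expected {count} molecule rows", ln + 1
            )
        x = np.empty(count)
        y = np.empty(count)
        theta = np.empty(count)
        shell = np.empty(count, np.int32)
        parent = np.empty(count, np.int32)
        bond = np.empty(count, np.int8)
        for m in range(count):
            row = lines[start + m].split()
            if len(row) != 6:
                raise ParseError(
                    f"expected 6 columns, got {len(row)}", start + m + 1
                )
            try:
                x[m], y[m], theta[m] = float(row[0]), float(row[1]), float(row[2])
                shell[m], parent[m] = int(row[3]), int(row[4])
                bond[m] = _TOKEN_BONDS[row[5]]
            except (ValueError, KeyError) as exc:
                raise ParseError(f"bad molecule row ({exc})", start + m + 1)
        flakes.append(
            Snowflake(x, y, theta, shell, parent, bond, terminated=terminated)
        )
        ln = start + count
    return flakes


def pressure_to_si(p_reduced: float, eps_HB_SI: float, r_HB_SI: float) -> float:
    """Convert a reduced 2D pressure to SI force-per-length units (N/m).

    The reduced pressure is p* = p r_HB^2 / |eps_HB|, so the physical 2D
    pressure is p* (eps_HB / N_A) / r_HB^2 with eps_HB in J/mol and r_HB
    in meters.  With eps_HB = 120 kJ/mol and r_HB = 0.25 nm, p* = 0.19
    corresponds to about 0.6 N/m.
    """
    if p_reduced < 0:
        raise ValueError("reduced pressure must be >= 0")
    if eps_HB_SI <= 0 or r_HB_SI <= 0:
        raise ValueError("eps_HB_SI and r_HB_SI must be positive")
    return p_reduced * (eps_HB_SI / N_A) / r_HB_SI**2
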