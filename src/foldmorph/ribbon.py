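"""A folded-ribbon toy model for building intuition about K, S and I.

The shape is a closed ribbon whose midline is a sinusoid wrapped around a
circle, r(theta) = R0 + a*sin(n_folds*theta): a 2D cartoon of a folded
cortex.  Each parameter maps onto one morphometric —

* the base circle radius R0 dictates the exposed-perimeter analog
  2*pi*R0 (standing in for Ae),
* the fold amplitude ``a`` dictates the folded midline arc length
  (standing in for At),
* the ribbon thickness T is used directly (entering the log point as T^2).

Feeding these analogs through the component projections shows how the
tension, shape and size terms respond to thickness, fold amplitude and
overall radius.  This is a schematic, not a mechanical model of folding:
only the *signs* of the responses are meaningful, and those are what
:func:`gradient_signs` extracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import integrate

from .components import Basis, DEFAULT_BASIS, Components, compute_components, to_log_point
from .errors import ConfigurationError, DomainError

__all__ = [
    "RibbonSpec",
    "RibbonMeasures",
    "ribbon_arc_length",
    "ribbon_measures",
    "ribbon_components",
    "ribbon_grid",
    "gradient_signs",
    "DEFAULT_GRID_RANGES",
]

#: Default parameter ranges for grid scans; chosen so every grid point
#: keeps the inner ribbon face at a positive radius (no self-intersection).
DEFAULT_GRID_RANGES = {"R0": (8.0, 16.0), "a": (0.0, 2.0), "T": (0.2, 1.0)}


@dataclass(frozen=True)
class RibbonSpec:
    """Geometry of one circular sinusoidal ribbon.

    R0 is the midline base radius, ``a`` the sinusoid amplitude, T the
    ribbon thickness and n_folds the number of oscillations around the
    circle (default 8).  The inner face must stay at positive radius:
    R0 - a - T/2 > 0.
    """

    R0: float
    a: float
    T: float
    n_folds: int = 8

    def __post_init__(self):
        if not (self.R0 > 0 and self.T > 0 and self.a >= 0):
            raise DomainError("require R0 > 0, T > 0, a >= 0")
        if self.n_folds < 1:
            raise DomainError("n_folds must be a positive integer")
        if not self.R0 - self.a - self.T / 2 > 0:
            raise DomainError(
                f"inner face radius R0 - a - T/2 = {self.R0 - self.a - self.T / 2:g} "
                "must be positive"
            )


class RibbonMeasures(NamedTuple):
    """Morphometric analogs of one ribbon: (At_analog, Ae_analog, T)."""

    At_analog: float
    Ae_analog: float
    T: float


def ribbon_arc_length(spec: RibbonSpec, tol: float = 1e-9) -> float:
    """Arc length of the folded midline r(theta) = R0 + a sin(n theta).

    Adaptive quadrature of sqrt(r^2 + r'^2) over one period, times the
    number of folds (the integrand has period 2*pi/n_folds); relative
    tolerance ``tol``.  At a = 0 this reduces exactly to the circle
    perimeter 2*pi*R0.
    """
    R0, a, n = spec.R0, spec.a, spec.n_folds
    if a == 0:
        return 2.0 * np.pi * R0

    def speed(theta):
        r = R0 + a * np.sin(n * theta)
        dr = a * n * np.cos(n * theta)
        return np.sqrt(r * r + dr * dr)

    period = 2.0 * np.pi / n
    val, _ = integrate.quad(speed, 0.0, period, epsrel=tol, epsabs=0.0, limit=200)
    return float(n * val)


def ribbon_measures(
    spec: RibbonSpec,
    envelope: str = "base",
    envelope_includes_thickness: bool = False,
    both_faces: bool = False,
    tol: float = 1e-9,
) -> RibbonMeasures:
    """Map a ribbon to its (At, Ae, T) analogs.

    By default the exposed-perimeter analog is the base circle (radius R0)
    and the folded-length analog is the midline arc length, so each ribbon
    parameter drives exactly one morphometric analog (radius -> Ae,
    amplitude -> At, thickness -> T).  ``envelope="peak"`` uses instead the
    circle encapsulating the fold crests (radius R0 + a); with that choice
    a growing amplitude initially widens the envelope faster than it
    lengthens the midline, so the tension term's amplitude response loses
    its clean sign.  ``envelope_includes_thickness`` grows the envelope by
    the outer half-thickness; ``both_faces`` sums the two ribbon faces
    instead of the midline (roughly doubling At_analog).  These two options
    change no gradient sign over the default ranges.
    """
    if envelope not in ("base", "peak"):
        raise ConfigurationError(f"unknown envelope {envelope!r}; use 'base' or 'peak'")
    arc = ribbon_arc_length(spec, tol)
    if both_faces:
        arc = 2.0 * arc
    radius = spec.R0 + (spec.a if envelope == "peak" else 0.0)
    if envelope_includes_thickness:
        radius += spec.T / 2.0
    return RibbonMeasures(arc, 2.0 * np.pi * radius, spec.T)


def ribbon_components(
    spec: RibbonSpec, basis: Basis = DEFAULT_BASIS, **measure_kwargs
) -> Components:
    """Components (K, I, S) of a ribbon's morphometric analogs."""
    m = ribbon_measures(spec, **measure_kwargs)
    return compute_components(to_log_point(m.At_analog, m.Ae_analog, m.T), basis)


def ribbon_grid(
    r0_range=DEFAULT_GRID_RANGES["R0"],
    a_range=DEFAULT_GRID_RANGES["a"],
    t_range=DEFAULT_GRID_RANGES["T"],
    n_folds: int = 8,
    shape=(10, 10, 10),
    basis: Basis = DEFAULT_BASIS,
) -> pd.DataFrame:
    """Scan (R0, a, T) on a regular grid and tabulate K, S, I.

    Grid points violating the no-self-intersection invariant are dropped
    (count recorded in ``df.attrs['n_dropped']``); an entirely invalid
    grid raises :class:`~foldmorph.errors.ConfigurationError`.
    """
    r0s = np.linspace(*r0_range, shape[0])
    amps = np.linspace(*a_range, shape[1])
    ts = np.linspace(*t_range, shape[2])
    rows, dropped = [], 0
    for R0 in r0s:
        for a in amps:
            for T in ts:
                try:
                    spec = RibbonSpec(R0, a, T, n_folds)
                except DomainError:
                    dropped += 1
                    continue
                c = ribbon_components(spec, basis)
                rows.append((R0, a, T, float(c.K), float(c.S), float(c.I)))
    if not rows:
        raise ConfigurationError("no grid point satisfies R0 - a - T/2 > 0")
    df = pd.DataFrame(rows, columns=["R0", "a", "T", "K", "S", "I"])
    df.attrs["n_dropped"] = dropped
    df.attrs["n_folds"] = n_folds
    return df


def gradient_signs(grid: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Dominant sign of each component's response to each ribbon parameter.

    Central finite differences of K, S, I along the R0, a and T axes of a
    full-factorial grid; per (component, parameter) the result is "+" if
    every defined difference is positive, "-" if all negative, "mixed"
    otherwise, and "undefined" for a degenerate (single-valued) axis.
    """
    axes = {p: np.sort(grid[p].unique()) for p in ("R0", "a", "T")}
    shape = tuple(len(v) for v in axes.values())
    index = {
        p: {v: i for i, v in enumerate(vals)} for p, vals in axes.items()
    }
    signs: dict[str, dict[str, str]] = {}
    for comp in ("K", "S", "I"):
        cube = np.full(shape, np.nan)
        for _, row in grid.iterrows():
            cube[index["R0"][row["R0"]], index["a"][row["a"]], index["T"][row["T"]]] = row[comp]
        signs[comp] = {}
        for ax, p in enumerate(("R0", "a", "T")):
            if shape[ax] < 2:
                signs[comp][p] = "undefined"
                continue
            diff = np.gradient(cube, axes[p], axis=ax)
            finite = diff[np.isfinite(diff)]
            if finite.size == 0:
                signs[comp][p] = "undefined"
            elif np.all(finite > 0):
                signs[comp][p] = "+"
            elif np.all(finite < 0):
                signs[comp][p] = "-"
            else:
                signs[comp][p] = "mixed"
    return signs
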