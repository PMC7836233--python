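"""Independent components of cortical morphology.

A cortex with total pial surface area ``At`` (mm^2), exposed surface area
``Ae`` (mm^2) and mean thickness ``T`` (mm) is represented as a point

    p = (log10 At, log10 Ae, log10 T^2)

in a 3D log space in which every axis carries units of (log) area.  The
cortical folding scaling law ``At * sqrt(T) = k * Ae^(5/4)`` is a plane in
this space, and its normal, together with the isometric direction and their
cross product, forms an orthogonal basis:

    kappa = (1, -5/4,  1/4)   tension direction  (K = p . kappa)
    iota  = (1,  1,    1)     isometric/size direction (I = p . iota)
    sigma = (3/2, 3/4, -9/4)  shape direction    (S = p . sigma)

``K`` and ``S`` are dimensionless (their coefficients sum to zero, so a
common rescaling of all areas cancels), while ``I`` captures size only.
Projections use the *unnormalized* basis by default; because downstream
group statistics z-score every measure against a reference cohort, the
basis lengths drop out of all effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "KAPPA_EXACT",
    "IOTA_EXACT",
    "SIGMA_EXACT",
    "Basis",
    "Components",
    "to_log_point",
    "from_log_point",
    "compute_components",
    "invert_components",
    "components_table",
    "angle_to_kappa",
    "pca_directions",
]

#: Exact rational coordinates of the basis, for identity checks.
KAPPA_EXACT = (Fraction(1), Fraction(-5, 4), Fraction(1, 4))
IOTA_EXACT = (Fraction(1), Fraction(1), Fraction(1))
SIGMA_EXACT = (Fraction(3, 2), Fraction(3, 4), Fraction(-9, 4))


@dataclass(frozen=True)
class Basis:
    """The orthogonal (kappa, iota, sigma) basis of log-morphology space.

    Parameters
    ----------
    normalized
        If True, each direction is scaled to unit Euclidean length.  The
        default keeps the conventional coefficients (|kappa|^2 = 21/8,
        |iota|^2 = 3, |sigma|^2 = 63/8); component values then differ from
        the normalized ones only by these constant factors.

    Note the sign of sigma: the right-handed cross product kappa x iota is
    ``-sigma``; the orientation used here keeps S increasing with folding
    amplitude, which matches how the shape term is usually discussed.
    """

    normalized: bool = False
    kappa: np.ndarray = field(init=False, repr=False)
    iota: np.ndarray = field(init=False, repr=False)
    sigma: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        k = np.array([1.0, -1.25, 0.25])
        i = np.array([1.0, 1.0, 1.0])
        s = np.array([1.5, 0.75, -2.25])
        if self.normalized:
            k = k / np.linalg.norm(k)
            i = i / np.linalg.norm(i)
            s = s / np.linalg.norm(s)
        object.__setattr__(self, "kappa", k)
        object.__setattr__(self, "iota", i)
        object.__setattr__(self, "sigma", s)

    @property
    def matrix(self) -> np.ndarray:
        """Rows kappa, iota, sigma — maps log points to (K, I, S)."""
        return np.vstack([self.kappa, self.iota, self.sigma])


DEFAULT_BASIS = Basis()


class Components(NamedTuple):
    """Projections (K, I, S) of one or many log points."""

    K: np.ndarray
    I: np.ndarray
    S: np.ndarray


def to_log_point(At, Ae, T) -> np.ndarray:
    """Map raw morphometrics to the log-area point (log10 At, log10 Ae, log10 T^2).

    Accepts scalars or equal-length arrays; returns an array of shape
    ``(..., 3)``.  All inputs must be strictly positive.
    """
    At = np.asarray(At, dtype=float)
    Ae = np.asarray(Ae, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(At <= 0) or np.any(Ae <= 0) or np.any(T <= 0):
        raise DomainError("At, Ae and T must be strictly positive")
    return np.stack([np.log10(At), np.log10(Ae), 2.0 * np.log10(T)], axis=-1)


def from_log_point(p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert :func:`to_log_point`: return (At, Ae, T)."""
    p = np.asarray(p, dtype=float)
    return 10.0 ** p[..., 0], 10.0 ** p[..., 1], 10.0 ** (p[..., 2] / 2.0)


def compute_components(p, basis: Basis = DEFAULT_BASIS) -> Components:
    """Project log points onto the basis: K = p.kappa, I = p.iota, S = p.sigma."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise DomainError("log point coordinates must be finite")
    return Components(K=p @ basis.kappa, I=p @ basis.iota, S=p @ basis.sigma)


def invert_components(c, basis: Basis = DEFAULT_BASIS) -> np.ndarray:
    """Reconstruct the unique log point with the given (K, I, S).

    Because the basis is orthogonal (not orthonormal) the inverse divides
    each direction by its squared length:
    ``p = K kappa/|kappa|^2 + I iota/|iota|^2 + S sigma/|sigma|^2``.
    """
    K, I, S = (np.asarray(v, dtype=float) for v in c)
    b = basis
    return (
        np.multiply.outer(K / (b.kappa @ b.kappa), b.kappa)
        + np.multiply.outer(I / (b.iota @ b.iota), b.iota)
        + np.multiply.outer(S / (b.sigma @ b.sigma), b.sigma)
    )


def components_table(
    table, basis: Basis = DEFAULT_BASIS, log_columns: bool = False
) -> pd.DataFrame:
    """Append K, I, S columns (and optionally logAt/logAe/logT2) to a table.

    ``table`` is a :class:`~foldmorph.io.SubjectTable` or a DataFrame with
    At_mm2, Ae_mm2, T_mm columns.  Row order is preserved.
    """
    df = getattr(table, "data", table).copy()
    p = to_log_point(df["At_mm2"].to_numpy(), df["Ae_mm2"].to_numpy(), df["T_mm"].to_numpy())
    c = compute_components(p, basis)
    if log_columns:
        df["logAt"], df["logAe"], df["logT2"] = p[:, 0], p[:, 1], p[:, 2]
    df["K"], df["I"], df["S"] = c.K, c.I, c.S
    return df


def angle_to_kappa(direction, basis: Basis = DEFAULT_BASIS) -> float:
    """Angle in degrees between the *line* of ``direction`` and the kappa line.

    Sign-invariant (a direction and its negative give the same angle), so
    the result lies in [0, 90].
    """
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0 or not np.all(np.isfinite(d)):
        raise DomainError("direction must be a finite non-zero vector")
    cosang = abs(d @ basis.kappa) / (nd * np.linalg.norm(basis.kappa))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def pca_directions(points, standardize: bool = False):
    """Principal directions of a cloud of log points.

    Eigendecomposition of the 3x3 covariance (of the optionally z-scored
    coordinates).  Directions are unit length, sorted by descending
    eigenvalue, with a deterministic sign convention: the largest-magnitude
    entry of each direction is positive.

    Returns
    -------
    directions : (3, 3) array, one principal direction per row
    explained_variance : (3,) array of eigenvalues (descending)
    """
    import warnings

    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise DomainError("need at least 3 points in 3 dimensions")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - X.mean(axis=0)) / sd
    cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order].T
    tol = max(evals.max(), 1.0) * 1e-12
    if np.any(evals < tol):
        warnings.warn(
            "covariance is rank deficient; zero-variance components present",
            stacklevel=2,
        )
    evals = np.clip(evals, 0.0, None)
    for row in evecs:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return evecs, evals
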