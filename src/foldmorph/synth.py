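"""Synthetic cohort generation.

Real per-hemisphere tables come from an MRI pipeline; for testing and
demonstration this module produces tables with the statistical structure
the analysis assumes: points scattered tightly around the scaling-law
plane (near-constant tension term K), with independent Gaussian variation
in the size and shape terms, optional linear age trends and sex offsets
per component, and group offsets in (K, I, S) for building comparison
cohorts with known effects.

Noise is drawn in component space — the analysis operates on the log
variables, and independent K/I/S noise there is exactly the independence
the decomposition is built to expose — and mapped back to raw (At, Ae, T)
through the inverse projection.  The defaults describe a plausible adult
hemisphere: At0 = 100000 mm^2, Ae0 = 40000 mm^2, T0 = 2.5 mm, with K
varying five times less than I and S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .components import (
    Basis,
    DEFAULT_BASIS,
    Components,
    compute_components,
    from_log_point,
    invert_components,
    to_log_point,
)
from .errors import ConfigurationError, DomainError
from .io import SubjectTable

__all__ = ["CohortSpec", "generate_cohort", "generate_on_plane"]


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    Component means derive from the baseline (At0, Ae0, T0) triple; age
    slopes are per year of age centered at the age-range midpoint, sex
    offsets are added for sex == 1, and group offsets shift the whole
    cohort.  ``offsets_in_sd`` interprets the group offsets in units of
    the corresponding component SD instead of raw log10 units.
    """

    n_subjects: int = 100
    hemispheres: int = 2
    age_range: tuple[float, float] = (20.0, 70.0)
    sex_ratio: float = 0.5
    baseline: tuple[float, float, float] = (100_000.0, 40_000.0, 2.5)
    sd_K: float = 0.01
    sd_I: float = 0.05
    sd_S: float = 0.05
    age_slopes: tuple[float, float, float] = (0.0, 0.0, 0.0)  # dK/yr, dI/yr, dS/yr
    sex_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    group_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    offsets_in_sd: bool = False
    group: str = "reference"
    seed: int | None = None

    def __post_init__(self):
        if min(self.sd_K, self.sd_I, self.sd_S) < 0:
            raise ConfigurationError("component SDs must be non-negative")
        if min(self.baseline) <= 0:
            raise ConfigurationError("baseline (At0, Ae0, T0) must be positive")
        if self.hemispheres not in (1, 2):
            raise ConfigurationError("hemispheres per subject must be 1 or 2")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return spec

    def describe(self) -> dict:
        return asdict(self)


def generate_cohort(spec: CohortSpec, basis: Basis = DEFAULT_BASIS) -> SubjectTable:
    """Draw a cohort per ``spec``; reproducible under a fixed seed.

    Per hemisphere: (K, I, S) = baseline components + age/sex terms +
    group offsets + independent Gaussian noise, inverted to raw
    (At, Ae, T).  Both hemispheres of a subject share age and sex but draw
    independent noise (they enter the analysis as separate datapoints).
    """
    rng = np.random.default_rng(spec.seed)
    n_rows = spec.n_subjects * spec.hemispheres

    base = compute_components(to_log_point(*spec.baseline), basis)
    sds = np.array([spec.sd_K, spec.sd_I, spec.sd_S])
    offsets = np.asarray(spec.group_offsets, dtype=float)
    if spec.offsets_in_sd:
        offsets = offsets * sds

    age = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sex = (rng.random(spec.n_subjects) < spec.sex_ratio).astype(float)
    age = np.repeat(age, spec.hemispheres)
    sex = np.repeat(sex, spec.hemispheres)
    age_c = age - np.mean(spec.age_range)

    slopes = np.asarray(spec.age_slopes, dtype=float)
    sexoff = np.asarray(spec.sex_offsets, dtype=float)
    mean = np.array([base.K, base.I, base.S])
    kis = (
        mean
        + offsets
        + np.outer(age_c, slopes)
        + np.outer(sex, sexoff)
        + rng.standard_normal((n_rows, 3)) * sds
    )
    p = invert_components(Components(kis[:, 0], kis[:, 1], kis[:, 2]), basis)
    At, Ae, T = from_log_point(p)
    bad = ~(np.isfinite(At) & np.isfinite(Ae) & np.isfinite(T) & (At > 0) & (Ae > 0) & (T > 0))
    if bad.any():
        raise DomainError(
            f"generated non-positive/overflowed morphometrics at draw(s) "
            f"{list(np.flatnonzero(bad)[:10])}; spec is pathological"
        )

    hemis = ["left", "right"][: spec.hemispheres] * spec.n_subjects
    subj = np.repeat([f"S{i:04d}" for i in range(spec.n_subjects)], spec.hemispheres)
    df = pd.DataFrame(
        {
            "subject_id": subj,
            "hemisphere": hemis,
            "group": spec.group,
            "age": age,
            "sex": sex,
            "At_mm2": At,
            "Ae_mm2": Ae,
            "T_mm": T,
        }
    )
    prov = [f"synthetic cohort: {spec.describe()}"]
    return SubjectTable(df, prov)


def generate_on_plane(
    n: int,
    log_k: float = 0.0,
    spread: float = 0.05,
    seed=None,
    basis: Basis = DEFAULT_BASIS,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Sample log points lying *exactly* on the scaling-law plane K = log_k.

    Points vary only in the isometric and shape directions (Gaussian with
    SD ``spread`` around ``center``, which defaults to the components of
    the standard baseline hemisphere), so any plane fit must recover the
    theoretical slope 5/4 and intercept log_k up to rounding.
    """
    if n < 3:
        raise DomainError("need n >= 3 points")
    if not spread > 0:
        raise DomainError("spread must be positive")
    rng = np.random.default_rng(seed)
    if center is None:
        c0 = compute_components(to_log_point(100_000.0, 40_000.0, 2.5), basis)
        center = (float(c0.I), float(c0.S))
    I = center[0] + spread * rng.standard_normal(n)
    S = center[1] + spread * rng.standard_normal(n)
    K = np.full(n, float(log_k))
    return invert_components(Components(K, I, S), basis)
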