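"""Group statistics: z-scoring, bootstrap of means, effect sizes, trajectories.

Every measure (a raw log variable or one of K, I, S) is first converted to
z-scores relative to the mean and standard deviation of the reference
cohort, so effect sizes are in reference-SD units and are invariant to the
log base and to basis normalization.  The group effect ``d`` is the
difference of the averages of bootstrapped mean z-scores (comparison minus
reference, 100 resamples by default); the p-value is a two-sided Wilcoxon
rank-sum on the raw z-scores, not the bootstrapped means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .components import Basis, DEFAULT_BASIS, components_table
from .errors import ConfigurationError, DegenerateFitError, DomainError

__all__ = [
    "MEASURES",
    "GroupEffect",
    "TrajectoryPoint",
    "zscore_to_reference",
    "bootstrap_means",
    "effect_size_d",
    "ranksum_p",
    "compare_cohorts",
    "trajectory_points",
]

#: Measures compare_cohorts understands, derivable from At_mm2/Ae_mm2/T_mm.
MEASURES = ("logAt", "logAe", "logT2", "K", "I", "S")

#: Total sample size up to which the rank-sum p-value is computed by exact
#: enumeration (when there are no ties).
EXACT_RANKSUM_MAX_N = 12


@dataclass
class GroupEffect:
    """Effect of a comparison cohort on one measure, relative to reference."""

    measure: str
    d: float
    p: float
    boot_ref: np.ndarray = field(repr=False)
    boot_cmp: np.ndarray = field(repr=False)
    n_ref: int = 0
    n_cmp: int = 0

    @property
    def significant(self) -> bool:
        """Nominal significance at p < 0.05 (no multiplicity correction)."""
        return self.p < 0.05


@dataclass(frozen=True)
class TrajectoryPoint:
    """One condition's displacement from its reference in (K, S, I) effect space."""

    condition: str
    d_K: float
    d_S: float
    d_I: float

    @property
    def coordinates(self) -> tuple[float, float, float]:
        return (self.d_K, self.d_S, self.d_I)


def zscore_to_reference(values, reference) -> np.ndarray:
    """z = (v - mean_ref) / sd_ref with the n-1 SD of the reference cohort."""
    reference = np.asarray(reference, dtype=float)
    if reference.size < 2:
        raise DegenerateFitError("reference needs at least 2 values")
    sd = reference.std(ddof=1)
    if sd == 0:
        raise DegenerateFitError("reference has zero spread; z-scores undefined")
    return (np.asarray(values, dtype=float) - reference.mean()) / sd


def bootstrap_means(values, n_boot: int = 100, seed=None) -> np.ndarray:
    """Means of ``n_boot`` with-replacement resamples of the full sample."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise DomainError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    return values[idx].mean(axis=1)


def effect_size_d(boot_ref, boot_cmp) -> float:
    """Difference of average bootstrapped means: comparison minus reference."""
    boot_ref = np.asarray(boot_ref, dtype=float)
    boot_cmp = np.asarray(boot_cmp, dtype=float)
    if boot_ref.size == 0 or boot_cmp.size == 0:
        raise DomainError("bootstrap distributions must be non-empty")
    return float(boot_cmp.mean() - boot_ref.mean())


def ranksum_p(raw_ref, raw_cmp) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled sample is small (<= 12) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(raw_ref, dtype=float)
    b = np.asarray(raw_cmp, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= EXACT_RANKSUM_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def _measure_frame(table, basis: Basis) -> pd.DataFrame:
    df = getattr(table, "data", table)
    have_all = all(m in df.columns for m in MEASURES)
    if have_all:
        return df
    return components_table(df, basis, log_columns=True)


def compare_cohorts(
    reference,
    comparison,
    measures=("K", "I", "S"),
    n_boot: int = 100,
    seed=None,
    basis: Basis = DEFAULT_BASIS,
) -> list[GroupEffect]:
    """Full per-measure pipeline: z-score -> bootstrap both cohorts -> d, p.

    ``reference`` and ``comparison`` are SubjectTables or DataFrames with
    raw morphometrics (measure columns are derived if absent).  Returns one
    :class:`GroupEffect` per requested measure; derived child seeds keep
    the measures' bootstraps independent but jointly reproducible.
    """
    for m in measures:
        if m not in MEASURES:
            raise ConfigurationError(f"unknown measure {m!r}; choose from {MEASURES}")
    ref = _measure_frame(reference, basis)
    cmp_ = _measure_frame(comparison, basis)
    seeds = np.random.SeedSequence(seed).spawn(len(measures))
    effects = []
    for m, ss in zip(measures, seeds):
        v_ref = ref[m].to_numpy(dtype=float)
        v_cmp = cmp_[m].to_numpy(dtype=float)
        z_ref = zscore_to_reference(v_ref, v_ref)
        z_cmp = zscore_to_reference(v_cmp, v_ref)
        rng = np.random.default_rng(ss)
        boot_ref = bootstrap_means(z_ref, n_boot, rng)
        boot_cmp = bootstrap_means(z_cmp, n_boot, rng)
        effects.append(
            GroupEffect(
                measure=m,
                d=effect_size_d(boot_ref, boot_cmp),
                p=ranksum_p(z_ref, z_cmp),
                boot_ref=boot_ref,
                boot_cmp=boot_cmp,
                n_ref=v_ref.size,
                n_cmp=v_cmp.size,
            )
        )
    return effects


def effects_frame(effects: list[GroupEffect], condition: str | None = None) -> pd.DataFrame:
    """Tabulate effects as condition, measure, d, p, n_ref, n_cmp, significant."""
    rows = [
        {
            "condition": condition,
            "measure": e.measure,
            "d": e.d,
            "p": e.p,
            "n_ref": e.n_ref,
            "n_cmp": e.n_cmp,
            "significant": e.significant,
        }
        for e in effects
    ]
    df = pd.DataFrame(rows)
    if condition is None:
        df = df.drop(columns=["condition"])
    return df


def trajectory_points(
    effects_by_condition: dict[str, list[GroupEffect]],
    reference_label: str = "reference",
) -> list[TrajectoryPoint]:
    """One point per condition in (d_K, d_S, d_I) effect space.

    The reference sits at the origin; each condition's coordinates are its
    effect sizes in the three independent components.
    """
    points = [TrajectoryPoint(reference_label, 0.0, 0.0, 0.0)]
    for condition, effects in effects_by_condition.items():
        by_measure = {e.measure: e for e in effects}
        missing = [m for m in ("K", "S", "I") if m not in by_measure]
        if missing:
            raise ConfigurationError(
                f"condition {condition!r} lacks effects for {missing}"
            )
        points.append(
            TrajectoryPoint(
                condition,
                d_K=by_measure["K"].d,
                d_S=by_measure["S"].d,
                d_I=by_measure["I"].d,
            )
        )
    return points
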