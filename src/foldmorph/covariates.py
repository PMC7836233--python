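"""Covariate correction of the log morphometrics.

Two strategies, mirroring how cohort studies handle demographics:

* :func:`fit_linear_correction` / :func:`apply_correction` — regress age
  and sex (no interaction) out of each of the three log variables, with
  coefficients estimated on the *reference* cohort and applied to every
  cohort.  Correction is full residualization (the intercept is removed
  too), so a reference cohort corrected by its own model has mean zero in
  all three log variables and hence mean K = I = S = 0: the corrected
  controls sit exactly on the plane log k = K = 0.
* :func:`sex_mean_center` — for narrow age bands where an age term is not
  wanted: center each log variable within each sex independently.

Corrected raw values (At, Ae, T) are recovered by exponentiation purely
for display; all analysis happens on the logs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .components import to_log_point
from .errors import ConfigurationError, DegenerateFitError
from .io import SubjectTable

__all__ = ["CorrectionModel", "fit_linear_correction", "apply_correction", "sex_mean_center"]

LOG_VARS = ("logAt", "logAe", "logT2")


@dataclass
class CorrectionModel:
    """Per-log-variable linear coefficients (intercept, beta_age, beta_sex).

    ``coefficients`` maps each of logAt, logAe, logT2 to a dict with keys
    intercept, beta_age (per year) and beta_sex (0/1 indicator contrast).
    """

    coefficients: dict[str, dict[str, float]]
    reference_group: str | None = None
    n: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients,
                "reference_group": self.reference_group,
                "n": self.n,
                "notes": self.notes,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionModel":
        d = json.loads(text)
        return cls(d["coefficients"], d.get("reference_group"), d.get("n", 0), d.get("notes", []))


def _log_matrix(df: pd.DataFrame) -> np.ndarray:
    return to_log_point(
        df["At_mm2"].to_numpy(), df["Ae_mm2"].to_numpy(), df["T_mm"].to_numpy()
    )


def fit_linear_correction(reference: SubjectTable) -> CorrectionModel:
    """Fit intercept + beta_age * age + beta_sex * sex to each log variable.

    Requires age and sex on every reference row and n >= 4.  A covariate
    with zero variance in the reference (single sex, identical ages) makes
    that coefficient unidentifiable; it is set to 0 with a warning and the
    model degrades gracefully toward intercept-only.
    """
    df = reference.data
    for col in ("age", "sex"):
        if col not in df.columns or df[col].isna().any():
            raise ConfigurationError(f"correction requires column {col!r} on every row")
    if len(df) < 4:
        raise DegenerateFitError("need at least 4 reference rows to fit the correction")

    age = df["age"].to_numpy(dtype=float)
    sex = df["sex"].to_numpy(dtype=float)
    logs = _log_matrix(df)

    notes: list[str] = []
    cols, names = [np.ones(len(df))], ["intercept"]
    for vals, nm in ((age, "beta_age"), (sex, "beta_sex")):
        if np.ptp(vals) == 0:
            warnings.warn(f"{nm} unidentifiable (constant covariate); set to 0", stacklevel=2)
            notes.append(f"{nm} set to 0: covariate constant in reference")
        else:
            cols.append(vals)
            names.append(nm)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError("collinear covariate design (age and sex confounded)")

    coefficients = {}
    for j, var in enumerate(LOG_VARS):
        params = sm.OLS(logs[:, j], X).fit().params
        coef = {"intercept": 0.0, "beta_age": 0.0, "beta_sex": 0.0}
        for nm, val in zip(names, params):
            coef[nm] = float(val)
        coefficients[var] = coef

    group = None
    if "group" in df.columns and df["group"].nunique() == 1:
        group = str(df["group"].iloc[0])
    return CorrectionModel(coefficients, group, len(df), notes)


def apply_correction(model: CorrectionModel, table: SubjectTable) -> SubjectTable:
    """Replace each log variable by its residual under ``model``.

    Full residualization: v <- v - (intercept + beta_age*age + beta_sex*sex).
    Raw columns are rewritten from the corrected logs (At = 10**logAt etc.),
    and the operation is recorded in provenance.
    """
    df = table.data.copy()
    need_age = any(c["beta_age"] != 0 for c in model.coefficients.values())
    need_sex = any(c["beta_sex"] != 0 for c in model.coefficients.values())
    for col, needed in (("age", need_age), ("sex", need_sex)):
        if (col not in df.columns or df[col].isna().any()) and needed:
            bad = "all rows" if col not in df.columns else str(list(df.index[df[col].isna()][:10]))
            raise ConfigurationError(f"correction needs {col!r}; missing on {bad}")
    age = df["age"].to_numpy(dtype=float) if "age" in df.columns else np.zeros(len(df))
    sex = df["sex"].to_numpy(dtype=float) if "sex" in df.columns else np.zeros(len(df))

    logs = _log_matrix(df)
    for j, var in enumerate(LOG_VARS):
        c = model.coefficients[var]
        logs[:, j] -= c["intercept"] + c["beta_age"] * age + c["beta_sex"] * sex
    df["At_mm2"] = 10.0 ** logs[:, 0]
    df["Ae_mm2"] = 10.0 ** logs[:, 1]
    df["T_mm"] = 10.0 ** (logs[:, 2] / 2.0)

    out = SubjectTable(df, list(table.provenance), table.rejected)
    out.provenance.append(
        f"applied age+sex correction (reference={model.reference_group}, n={model.n})"
    )
    return out


def sex_mean_center(table: SubjectTable) -> SubjectTable:
    """Center each log variable to mean zero within each sex stratum."""
    df = table.data.copy()
    if "sex" not in df.columns or df["sex"].isna().any():
        raise ConfigurationError("sex mean-centering requires a complete sex column")
    logs = _log_matrix(df)
    sex = df["sex"].to_numpy()
    for level in np.unique(sex):
        mask = sex == level
        if mask.sum() == 1:
            warnings.warn(
                f"sex stratum {level!r} has a single row; it centers to exactly 0",
                stacklevel=2,
            )
        logs[mask] -= logs[mask].mean(axis=0)
    df["At_mm2"] = 10.0 ** logs[:, 0]
    df["Ae_mm2"] = 10.0 ** logs[:, 1]
    df["T_mm"] = 10.0 ** (logs[:, 2] / 2.0)
    out = SubjectTable(df, list(table.provenance), table.rejected)
    out.provenance.append("sex mean-centering applied to log variables")
    return out
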