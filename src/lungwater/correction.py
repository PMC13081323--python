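"""ECBF correction of thermodilution EVLWI.

Thermodilution overestimates lung water on VV ECMO in proportion to the
extracorporeal blood flow (ECBF).  An ordinary-least-squares regression of
EVLWI_TPTD on {1, EVLWI_CT, ECBF}, with the CT estimate as reference, yields
an ECBF coefficient (ml/kg per l/min); the bedside correction subtracts
``factor * ecbf`` from the raw thermodilution value.  Only the ECBF
coefficient is applied at the bedside; intercept and CT slope are reported
for diagnostics but not used in the correction.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import IdentifiabilityError, ValidationError

__all__ = [
    "CorrectionModel",
    "REQUIRED_FIT_COLUMNS",
    "fit_correction_model",
    "apply_correction",
    "correct_cohort",
    "save_model",
    "load_model",
]

REQUIRED_FIT_COLUMNS = ("evlwi_ct", "evlwi_tptd", "ecbf")


@dataclass(frozen=True)
class CorrectionModel:
    """OLS fit of evlwi_tptd ~ 1 + evlwi_ct + ecbf.

    ``correction_factor`` is the ECBF coefficient (ml/kg per l/min);
    ``residual_sd`` uses n - 3 degrees of freedom.
    """

    intercept: float
    slope_ct: float
    correction_factor: float
    residual_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError(f"model requires n >= 3, got n={self.n}")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")


def _validated_fit_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_FIT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort is missing required column(s): {missing}")
    sub = cohort.loc[:, list(REQUIRED_FIT_COLUMNS)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValidationError(f"cohort has missing values in {bad}; rows are not imputed")
    return sub.astype(float)


def fit_correction_model(cohort: pd.DataFrame) -> CorrectionModel:
    """Fit the correction regression by plain OLS.

    Raises :class:`IdentifiabilityError` when the design is rank deficient
    (ECBF or EVLWI_CT constant across rows).
    """
    sub = _validated_fit_frame(cohort)
    n = len(sub)
    if n < 3:
        raise ValidationError(f"need at least 3 complete rows to fit, got {n}")
    X = sm.add_constant(sub[["evlwi_ct", "ecbf"]].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < 3:
        for col in ("evlwi_ct", "ecbf"):
            if np.ptp(sub[col].to_numpy()) == 0:
                raise IdentifiabilityError(
                    f"{col} is constant across rows; its coefficient is unidentifiable"
                )
        raise IdentifiabilityError("regression design is rank deficient")
    fit = sm.OLS(sub["evlwi_tptd"].to_numpy(), X).fit()
    resid_sd = float(np.sqrt(fit.ssr / (n - 3))) if n > 3 else 0.0
    return CorrectionModel(
        intercept=float(fit.params[0]),
        slope_ct=float(fit.params[1]),
        correction_factor=float(fit.params[2]),
        residual_sd=resid_sd,
        n=n,
    )


def apply_correction(evlwi_tptd, ecbf, correction_factor: float):
    """Corrected bedside estimate: evlwi_tptd - correction_factor * ecbf.

    Accepts scalars or arrays; exactly linear in both ecbf and the factor.
    """
    tptd = np.asarray(evlwi_tptd, dtype=float)
    flow = np.asarray(ecbf, dtype=float)
    if np.any(flow < 0):
        raise ValidationError("ecbf must be >= 0 l/min")
    out = tptd - correction_factor * flow
    return float(out) if out.ndim == 0 else out


def correct_cohort(cohort: pd.DataFrame, model: CorrectionModel) -> pd.DataFrame:
    """Return a copy of the cohort with an ``evlwi_tptd_corr`` column added."""
    out = cohort.copy()
    if len(out) == 0:
        out["evlwi_tptd_corr"] = pd.Series(dtype=float)
        return out
    for col in ("evlwi_tptd", "ecbf"):
        if col not in out.columns:
            raise ValidationError(f"cohort is missing required column(s): ['{col}']")
        if out[col].isna().any():
            raise ValidationError(f"cohort has missing values in ['{col}']")
    out["evlwi_tptd_corr"] = apply_correction(
        out["evlwi_tptd"].to_numpy(), out["ecbf"].to_numpy(), model.correction_factor
    )
    return out


def save_model(model: CorrectionModel, path: str | Path) -> None:
    """Persist as flat key=value text; floats via repr() for bit-exact round-trip."""
    lines = [
        f"intercept={model.intercept!r}",
        f"slope_ct={model.slope_ct!r}",
        f"correction_factor={model.correction_factor!r}",
        f"residual_sd={model.residual_sd!r}",
        f"n={model.n}",
        f"fit_date={_dt.date.today().isoformat()}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> CorrectionModel:
    text = Path(path).read_text(encoding="utf-8")
    kv: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}: line {lineno} is not key=value: {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    try:
        return CorrectionModel(
            intercept=float(kv["intercept"]),
            slope_ct=float(kv["slope_ct"]),
            correction_factor=float(kv["correction_factor"]),
            residual_sd=float(kv["residual_sd"]),
            n=int(kv["n"]),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing model key {exc}") from None
    except ValueError as exc:
        raise ValidationError(f"{path}: bad model value: {exc}") from None
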