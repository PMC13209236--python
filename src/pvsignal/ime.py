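"""Important medical events (IME) and logistic models of their occurrence.

An IME is any report whose outcome codes intersect {death, life-threatening,
hospitalization, disability, congenital anomaly}.  Gender (reference female),
age and weight — continuous and banded — are modelled as predictors of IME
occurrence with maximum-likelihood logistic regression: univariate models fit
each focal variable alone; multivariate models adjust the focal variable for
the other two entered as continuous covariates.  Complete-case analysis, Wald
inference, no imputation.  Non-convergence or (quasi-)separation is reported
as a not-available row, never as a numeric odds ratio.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .faers import CaseReport, age_band, weight_band

IME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA"})

#: an estimated |log-odds| beyond this is treated as separation, not signal
MAX_ABS_COEF = 15.0

Z95 = 1.959963984540054


def flag_ime(report: CaseReport) -> bool:
    """True iff the report carries at least one IME outcome code."""
    return bool(report.outcomes & IME_CODES)


def ime_records(store: Sequence[CaseReport]) -> pd.DataFrame:
    """Model-ready frame: ime flag, gender, age, weight and their bands."""
    rows = []
    for r in store:
        rows.append({
            "ime": flag_ime(r),
            "gender": r.gender if r.gender in ("M", "F") else None,
            "age": r.age_years,
            "weight": r.weight_kg,
            "age_band": None if r.age_years is None else age_band(r.age_years),
            "weight_band": None if r.weight_kg is None else weight_band(r.weight_kg),
        })
    return pd.DataFrame(rows, columns=["ime", "gender", "age", "weight",
                                       "age_band", "weight_band"])


@dataclass
class LogitResult:
    variable: str
    contrast: str
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p_value: float
    model: str          # univariate / multivariate
    converged: bool
    n: int

    def to_row(self) -> dict:
        return {"variable": self.variable, "contrast": self.contrast,
                "odds_ratio": self.odds_ratio, "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi, "p_value": self.p_value,
                "model": self.model, "converged": self.converged, "n": self.n}


def _design_columns(df: pd.DataFrame, variable: str) -> tuple[pd.DataFrame, list]:
    """Design matrix columns for one variable plus (column, contrast-label) list."""
    if variable == "gender":
        X = pd.DataFrame({"male": (df["gender"] == "M").astype(float)})
        labels = [("male", "Male vs Female")]
    elif variable == "age":
        X = pd.DataFrame({"age": df["age"].astype(float)})
        labels = [("age", "per year")]
    elif variable == "age_band":
        X = pd.DataFrame({
            "age_18_64": (df["age_band"] == "18-64 years").astype(float),
            "age_gt64": (df["age_band"] == ">64 years").astype(float)})
        labels = [("age_18_64", "18-64 vs <18 years"),
                  ("age_gt64", ">64 vs <18 years")]
    elif variable == "weight":
        X = pd.DataFrame({"weight": df["weight"].astype(float)})
        labels = [("weight", "per kg")]
    elif variable == "weight_band":
        X = pd.DataFrame({
            "wt_80_100": (df["weight_band"] == "80-100 kg").astype(float),
            "wt_gt100": (df["weight_band"] == ">100 kg").astype(float)})
        labels = [("wt_80_100", "80-100 vs <80 kg"),
                  ("wt_gt100", ">100 vs <80 kg")]
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return X, labels


_RAW_COLS = {"gender": ["gender"], "age": ["age"], "age_band": ["age_band"],
             "weight": ["weight"], "weight_band": ["weight_band"]}

_COVARIATES = {"gender": ["age", "weight"], "age": ["gender", "weight"],
               "age_band": ["gender", "weight"], "weight": ["gender", "age"],
               "weight_band": ["gender", "age"]}

FOCAL_VARIABLES = ("gender", "age", "age_band", "weight", "weight_band")


def _na_rows(variable: str, labels, model: str, n: int) -> list:
    nan = float("nan")
    return [LogitResult(variable=variable, contrast=lab, odds_ratio=nan,
                        ci_lo=nan, ci_hi=nan, p_value=nan, model=model,
                        converged=False, n=n)
            for _, lab in labels]


def _fit_one(df: pd.DataFrame, variable: str, model: str) -> list:
    """Fit one logistic model and return the focal-variable contrast rows."""
    covars = _COVARIATES[variable] if model == "multivariate" else []
    needed = _RAW_COLS[variable] + covars
    sub = df.dropna(subset=["ime"] + needed)
    # gender enters every design as the male indicator, which needs M/F only
    if "gender" in needed:
        sub = sub[sub["gender"].notna()]
    X, labels = _design_columns(sub, variable)
    for cv in covars:
        Xc, _ = _design_columns(sub, cv)
        X = pd.concat([X, Xc], axis=1)
    y = sub["ime"].astype(float)
    n = len(sub)

    if n == 0 or y.nunique() < 2:
        return _na_rows(variable, labels, model, n)
    # zero-variance columns make the fit unidentifiable for that contrast
    if any(X[col].nunique() < 2 for col in X.columns):
        return _na_rows(variable, labels, model, n)

    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(), exog).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", False))
        params = np.asarray(fit.params)
        bse = np.asarray(fit.bse)
    except Exception:
        return _na_rows(variable, labels, model, n)

    rows = []
    for idx, (col, lab) in enumerate(labels, start=1):
        coef, se = params[idx], bse[idx]
        # se > 100 on the logit scale marks collinearity or quasi-separation
        bad = (not converged or not np.isfinite(coef) or not np.isfinite(se)
               or abs(coef) > MAX_ABS_COEF or se <= 0 or se > 100)
        if bad:
            rows.extend(_na_rows(variable, [(col, lab)], model, n))
            continue
        z = coef / se
        rows.append(LogitResult(
            variable=variable, contrast=lab, odds_ratio=math.exp(coef),
            ci_lo=float(np.exp(coef - Z95 * se)),
            ci_hi=float(np.exp(coef + Z95 * se)),
            p_value=2.0 * (1.0 - _norm_cdf(abs(z))),
            model=model, converged=True, n=n))
    return rows


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


class IMELogit:
    """Logistic models of IME occurrence on gender, age and weight.

    ``IMELogit(records).fit(scheme)`` returns a results table; ``records`` is
    either a frame from :func:`ime_records` or a list of reports.
    """

    def __init__(self, records, drug: str = ""):
        if isinstance(records, pd.DataFrame):
            self.records = records
        else:
            self.records = ime_records(records)
        self.drug = drug

    def fit(self, scheme: str = "both") -> pd.DataFrame:
        if scheme not in ("univariate", "multivariate", "both"):
            raise ValueError(f"unknown scheme {scheme!r}")
        schemes = (["univariate", "multivariate"] if scheme == "both"
                   else [scheme])
        rows = []
        for mdl in schemes:
            for variable in FOCAL_VARIABLES:
                rows.extend(r.to_row() for r in
                            _fit_one(self.records, variable, mdl))
        out = pd.DataFrame(rows)
        if self.drug:
            out.insert(0, "drug", self.drug)
        return out


def fit_models(records, scheme: str = "both", drug: str = "") -> pd.DataFrame:
    """Functional wrapper around :class:`IMELogit`."""
    return IMELogit(records, drug=drug).fit(scheme)
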