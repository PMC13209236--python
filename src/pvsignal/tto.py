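"""Time-to-onset (TTO) analysis with two-parameter Weibull modelling.

TTO is the duration from therapy start to the event, in days, with a +1
offset so that same-day onset is representable (day 1) — consistent with
observed minima of 1 day in spontaneous-report data.  Only reports with
complete day-resolution start and event dates enter the sample.

The Weibull shape parameter alpha diagnoses the hazard trend of reporting:
alpha < 1 with its whole 95% CI below 1 is an *early failure* curve
(declining risk), alpha > 1 with CI above 1 is *wear-out* (increasing risk),
and a CI straddling 1 is *random* (roughly constant risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, SampleSizeError
from .faers import CaseReport, normalize_drug_name

MIN_FIT_N = 10
Z95 = 1.959963984540054


@dataclass
class TTOSample:
    """Onset durations (days, >= 1) for one drug, with exclusion tallies."""

    drug: str
    days: list[int]
    exclusions: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.days)


def extract_tto(store: Sequence[CaseReport], drug: str | Iterable[str],
                offset_days: int = 1) -> TTOSample:
    """Extract onset days = (event - start) + offset for one drug's reports.

    The therapy start is the drug entry's start date (day resolution only);
    the event date is the earliest complete reaction date on the report.
    Reports with partial/missing dates or event-before-start are excluded and
    counted in ``exclusions``.
    """
    if isinstance(drug, str):
        names = {normalize_drug_name(drug)}
        label = drug
    else:
        names = {normalize_drug_name(d) for d in drug}
        label = "+".join(sorted(names))
    days: list[int] = []
    excl = {"missing_start": 0, "missing_event": 0, "event_before_start": 0}
    for r in store:
        if not r.has_primary_suspect(names):
            continue
        starts = [d.start_dt.date for d in r.drugs
                  if d.role == "PS" and d.name in names
                  and d.start_dt is not None and d.start_dt.complete]
        if not starts:
            excl["missing_start"] += 1
            continue
        events = [e.event_dt.date for e in r.reactions
                  if e.event_dt is not None and e.event_dt.complete]
        if not events:
            excl["missing_event"] += 1
            continue
        delta = (min(events) - min(starts)).days
        if delta < 0:
            excl["event_before_start"] += 1
            continue
        days.append(delta + offset_days)
    return TTOSample(drug=label, days=days, exclusions=excl)


def summarize_tto(sample: TTOSample | Sequence[float]) -> dict:
    """Median, quartiles (type-7 linear interpolation), min and max."""
    days = np.asarray(sample.days if isinstance(sample, TTOSample) else sample,
                      dtype=float)
    if days.size == 0:
        raise ValueError("cannot summarize an empty TTO sample")
    q1, med, q3 = np.quantile(days, [0.25, 0.5, 0.75])  # numpy default = type 7
    return {"n": int(days.size), "median": float(med), "q1": float(q1),
            "q3": float(q3), "min": float(days.min()), "max": float(days.max())}


def _weibull_loglike(log_shape: float, log_scale: float, x: np.ndarray) -> float:
    k = math.exp(log_shape)
    lam = math.exp(log_scale)
    z = x / lam
    return (x.size * (math.log(k) - k * math.log(lam))
            + (k - 1) * float(np.log(x).sum()) - float((z ** k).sum()))


def _hessian(f, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function of two variables."""
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            H[i, j] = (f(theta + ei + ej) - f(theta + ei - ej)
                       - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h * h)
    return (H + H.T) / 2


@dataclass
class WeibullTTOResults:
    """MLE fit of the two-parameter Weibull to a TTO sample."""

    drug: str
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float
    shape: float
    shape_ci: tuple[float, float]
    scale: float
    scale_ci: tuple[float, float]
    loglike: float
    cov_log: np.ndarray  # covariance of (log shape, log scale)

    @property
    def failure_type(self) -> str:
        return classify_failure(self.shape_ci)

    def summary(self) -> str:
        lines = [
            f"Weibull TTO fit: {self.drug}",
            f"  n                 {self.n}",
            f"  median (IQR)      {self.median:.1f} ({self.q1:.1f}-{self.q3:.1f})",
            f"  min-max           {self.min:.0f}-{self.max:.0f}",
            f"  scale (beta)      {self.scale:.2f} "
            f"(95% CI {self.scale_ci[0]:.2f}-{self.scale_ci[1]:.2f})",
            f"  shape (alpha)     {self.shape:.3f} "
            f"(95% CI {self.shape_ci[0]:.3f}-{self.shape_ci[1]:.3f})",
            f"  failure type      {self.failure_type}",
            f"  log-likelihood    {self.loglike:.2f}",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {"drug": self.drug, "n": self.n, "median": self.median,
                "q1": self.q1, "q3": self.q3, "min": self.min, "max": self.max,
                "scale": self.scale, "scale_lo": self.scale_ci[0],
                "scale_hi": self.scale_ci[1], "shape": self.shape,
                "shape_lo": self.shape_ci[0], "shape_hi": self.shape_ci[1],
                "failure_type": self.failure_type}


class WeibullTTO:
    """Two-parameter Weibull model of onset times for one drug.

    Maximum likelihood on the continuous Weibull density (days treated as
    continuous); 95% CIs are Wald intervals on the log-parameter scale from
    the observed information at the MLE, back-transformed.
    """

    def __init__(self, sample: TTOSample | Sequence[float], drug: str | None = None):
        if isinstance(sample, TTOSample):
            self.days = np.asarray(sample.days, dtype=float)
            self.drug = drug or sample.drug
        else:
            self.days = np.asarray(list(sample), dtype=float)
            self.drug = drug or ""
        if np.any(self.days <= 0):
            raise ValueError("onset durations must be positive")

    def fit(self) -> WeibullTTOResults:
        x = self.days
        if x.size < MIN_FIT_N:
            raise SampleSizeError(
                f"Weibull fit needs at least {MIN_FIT_N} onset times, got {x.size}")
        if float(x.max()) == float(x.min()):
            raise FitError("degenerate TTO sample: all onset times are equal")

        # scipy MLE as starting point, then polish on the log scale
        c0, _, scale0 = stats.weibull_min.fit(x, floc=0)
        nll = lambda th: -_weibull_loglike(th[0], th[1], x)
        res = optimize.minimize(nll, x0=np.log([c0, scale0]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        theta = res.x
        H = _hessian(lambda th: _weibull_loglike(th[0], th[1], x), theta)
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular observed information: {exc}") from exc
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            raise FitError("observed information is not positive definite at the MLE")

        shape, scale = float(np.exp(theta[0])), float(np.exp(theta[1]))
        se_ls, se_lsc = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        summ = summarize_tto(x)
        return WeibullTTOResults(
            drug=self.drug, n=summ["n"], median=summ["median"], q1=summ["q1"],
            q3=summ["q3"], min=summ["min"], max=summ["max"],
            shape=shape,
            shape_ci=(shape * math.exp(-Z95 * se_ls), shape * math.exp(Z95 * se_ls)),
            scale=scale,
            scale_ci=(scale * math.exp(-Z95 * se_lsc), scale * math.exp(Z95 * se_lsc)),
            loglike=float(-res.fun), cov_log=cov)


def fit_weibull(sample: TTOSample | Sequence[float],
                drug: str | None = None) -> WeibullTTOResults:
    """Functional wrapper around :class:`WeibullTTO`."""
    return WeibullTTO(sample, drug=drug).fit()


def classify_failure(shape_ci: tuple[float, float]) -> str:
    """early / wear_out / random from the shape CI's position against 1."""
    lo, hi = shape_ci
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wear_out"
    return "random"
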