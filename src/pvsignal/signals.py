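"""Disproportionality analysis on 2x2 contingency tables.

Four algorithms run on every drug-term pair: the reporting odds ratio (ROR)
and proportional reporting ratio (PRR) with Wald confidence intervals, the
BCPNN information component (closed-form Bayesian approximation), and the
MGPS empirical Bayes geometric mean in its relative-reporting-ratio closed
form with a normal-approximation lower bound.  A pair is a *signal* only when
all four algorithms pass their thresholds simultaneously:

    ROR:   a >= 3 and 95% CI lower bound > 1
    PRR:   a >= 3, chi-square >= 4, CI lower bound > 1
    BCPNN: a >= 3 and IC025 > 0
    MGPS:  a > 0 and EBGM05 > 2

Counting rule (configurable): the analysis unit is the (report, term) pair —
a report with k distinct PTs contributes k pairs, duplicates within one
report count once — so N is constant across terms at a fixed level.  At SOC
level the table is the sum of its member-PT tables.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MeddraLookupError
from .faers import CaseReport, MeddraDict, normalize_drug_name, normalize_pt

Z95 = 1.959963984540054  # two-sided 95% normal quantile
Z90_ONE_SIDED = 1.6448536269514722

# BCPNN hyper-priors (uniform cell prior, symmetric margins)
_ALPHA1 = _BETA1 = 1.0
_ALPHA = _BETA = 2.0
_GAMMA11 = 1.0

#: metadata note carried on output tables: the EBGM05 here is a
#: normal-approximation lower bound on the closed-form EBGM, not the full
#: gamma-Poisson shrinkage posterior.
MGPS_NOTE = "EBGM05 = exp(ln EBGM - 1.64*sqrt(1/a+1/b+1/c+1/d)); not full gamma-Poisson shrinkage"


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the 2x2 drug-by-term table.

    a: target drug & target term; b: target drug, other terms;
    c: other drugs, target term; d: other drugs, other terms.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalMetrics:
    """The four algorithms' values, CIs, and threshold flags for one pair.

    Undefined quantities (a zero cell where a reciprocal or log is needed)
    are NaN and fail their flag.
    """

    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_mgps: bool
    signal: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _bcpnn_ic(a: float, ab: float, ac: float, n: float) -> tuple[float, float]:
    """Closed-form E(IC) and IC025 of the BCPNN information component."""
    gamma = _GAMMA11 * (n + _ALPHA) * (n + _BETA) / ((ab + _ALPHA1) * (ac + _BETA1))
    eic = math.log2((a + _GAMMA11) * (n + _ALPHA) * (n + _BETA)
                    / ((n + gamma) * (ab + _ALPHA1) * (ac + _BETA1)))
    vic = (1.0 / math.log(2) ** 2) * (
        (n - a + gamma - _GAMMA11) / ((a + _GAMMA11) * (1 + n + gamma))
        + (n - ab + _ALPHA - _ALPHA1) / ((ab + _ALPHA1) * (1 + n + _ALPHA))
        + (n - ac + _BETA - _BETA1) / ((ac + _BETA1) * (1 + n + _BETA)))
    return eic, eic - 2.0 * math.sqrt(vic)


def compute_metrics(t: ContingencyTable) -> SignalMetrics:
    """Evaluate all four disproportionality algorithms on one table."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    nan = float("nan")

    # --- ROR ---------------------------------------------------------------
    if min(a, b, c, d) > 0:
        ror = (a * d) / (b * c)
        half = Z95 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror_lo, ror_hi = math.exp(math.log(ror) - half), math.exp(math.log(ror) + half)
    else:
        ror = ror_lo = ror_hi = nan

    # --- PRR and chi-square ------------------------------------------------
    if a > 0 and c > 0 and (a + b) > 0 and (c + d) > 0:
        prr = (a / (a + b)) / (c / (c + d))
        rad = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
        half = Z95 * math.sqrt(max(rad, 0.0))
        prr_lo, prr_hi = math.exp(math.log(prr) - half), math.exp(math.log(prr) + half)
    else:
        prr = prr_lo = prr_hi = nan
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (a * d - b * c) ** 2 / margins if margins > 0 else nan

    # --- BCPNN --------------------------------------------------------------
    ic, ic025 = _bcpnn_ic(a, a + b, a + c, n)

    # --- MGPS ---------------------------------------------------------------
    if (a + b) > 0 and (a + c) > 0 and a > 0:
        ebgm = a * n / ((a + c) * (a + b))
        if min(b, c, d) > 0:
            ebgm05 = math.exp(math.log(ebgm)
                              - Z90_ONE_SIDED * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
        else:
            ebgm05 = nan
    else:
        ebgm = ebgm05 = nan

    flag_ror = bool(t.a >= 3 and not math.isnan(ror_lo) and ror_lo > 1)
    flag_prr = bool(t.a >= 3 and not math.isnan(chi2) and chi2 >= 4
                    and not math.isnan(prr_lo) and prr_lo > 1)
    flag_bcpnn = bool(t.a >= 3 and ic025 > 0)
    flag_mgps = bool(t.a > 0 and not math.isnan(ebgm05) and ebgm05 > 2)

    return SignalMetrics(
        ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
        prr=prr, prr_lo=prr_lo, prr_hi=prr_hi, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
        flag_ror=flag_ror, flag_prr=flag_prr,
        flag_bcpnn=flag_bcpnn, flag_mgps=flag_mgps,
        signal=flag_ror and flag_prr and flag_bcpnn and flag_mgps,
    )


def _pair_counts(store: Sequence[CaseReport], drug_names: set[str],
                 level: str, meddra: MeddraDict | None):
    """Per-term pair counts split by drug membership, plus pair totals.

    At PT level a report contributes one pair per distinct PT; at SOC level
    the pair count for a SOC is the sum over its member PTs (so the SOC-level
    a-cell is the sum of member-PT a-cells and N is level-invariant).
    """
    target = Counter()  # term -> pairs among drug reports
    other = Counter()   # term -> pairs among comparator reports
    pairs_drug = 0
    pairs_other = 0
    display: dict[str, str] = {}
    for r in store:
        pts = r.pt_set()
        is_drug = r.has_primary_suspect(drug_names)
        if level == "PT":
            # remember an original (pre-casefold) display form per PT
            for entry in r.reactions:
                k = normalize_pt(entry.pt)
                if k:
                    display.setdefault(k, str(entry.pt).strip())
        for pt in pts:
            if level == "SOC":
                if meddra is None:
                    raise ValueError("SOC-level screening needs a MedDRA dictionary")
                term = meddra.soc_of(pt)  # raises MeddraLookupError when unmapped
                key = term
                display.setdefault(key, term)
            else:
                key = pt
            if is_drug:
                target[key] += 1
                pairs_drug += 1
            else:
                other[key] += 1
                pairs_other += 1
    return target, other, pairs_drug, pairs_other, display


def build_table(store: Sequence[CaseReport], drug: str | Iterable[str], term: str,
                level: str = "PT", meddra: MeddraDict | None = None) -> ContingencyTable:
    """Build the 2x2 table for one drug-term pair at PT or SOC level."""
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    names = ({normalize_drug_name(drug)} if isinstance(drug, str)
             else {normalize_drug_name(d) for d in drug})
    target, other, pairs_drug, pairs_other, _ = _pair_counts(store, names, level, meddra)
    if level == "SOC":
        if meddra is not None and term.strip() not in meddra.socs:
            raise MeddraLookupError(f"unknown SOC: {term!r}")
        key = term.strip()
    else:
        key = normalize_pt(term)
    a = target.get(key, 0)
    c = other.get(key, 0)
    return ContingencyTable(a=a, b=pairs_drug - a, c=c, d=pairs_other - c)


_METRIC_COLS = ["ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi", "chi2",
                "ic", "ic025", "ebgm", "ebgm05",
                "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "signal"]


def screen_terms(store: Sequence[CaseReport], drug: str | Iterable[str],
                 level: str = "PT", meddra: MeddraDict | None = None,
                 min_a: int = 0) -> pd.DataFrame:
    """One row per term with a >= min_a, ranked by a desc, ROR desc, term asc."""
    if min_a < 0:
        raise ValueError("min_a must be >= 0")
    level = level.upper()
    names = ({normalize_drug_name(drug)} if isinstance(drug, str)
             else {normalize_drug_name(d) for d in drug})
    target, other, pairs_drug, pairs_other, display = _pair_counts(
        store, names, level, meddra)
    rows = []
    for key in sorted(set(target) | set(other)):
        a = target.get(key, 0)
        if a < min_a:
            continue
        c = other.get(key, 0)
        t = ContingencyTable(a=a, b=pairs_drug - a, c=c, d=pairs_other - c)
        m = compute_metrics(t)
        rows.append({"term": display[key], "level": level,
                     "a": t.a, "b": t.b, "c": t.c, "d": t.d, **m.to_dict()})
    df = pd.DataFrame(rows, columns=["term", "level", "a", "b", "c", "d"]
                      + _METRIC_COLS)
    if len(df):
        df = df.sort_values(["a", "ror", "term"],
                            ascending=[False, False, True],
                            kind="mergesort").reset_index(drop=True)
    df.attrs["mgps_note"] = MGPS_NOTE
    return df


def common_signals(per_drug: Mapping[str, pd.DataFrame]) -> list[str]:
    """Terms flagged as signals for every drug (set intersection)."""
    sets = [set(df.loc[df["signal"], "term"]) for df in per_drug.values()]
    if not sets:
        return []
    out = set.intersection(*sets)
    return sorted(out)


@dataclass
class GenderSignal:
    """Female-vs-male reporting contrast for one PT within one drug."""

    pt: str
    a: int  # females with PT
    b: int  # females, other reports
    c: int  # males with PT
    d: int  # males, other reports
    ror: float
    ror_lo: float
    ror_hi: float
    p_value: float
    direction: str | None  # "female_risk" / "male_risk" / None when undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ror)


def gender_ror(store: Sequence[CaseReport], drug: str | Iterable[str],
               pt: str) -> GenderSignal:
    """Female-vs-male ROR for one PT among a drug's reports with known gender.

    ROR > 1 marks a female-prone term, < 1 male-prone.  Pearson chi-square
    without continuity correction supplies the p-value.  A degenerate margin
    (no males or no females, or a zero cell) yields an undefined-marked
    result rather than an exception.
    """
    names = ({normalize_drug_name(drug)} if isinstance(drug, str)
             else {normalize_drug_name(d) for d in drug})
    key = normalize_pt(pt)
    a = b = c = d = 0
    for r in store:
        if not r.has_primary_suspect(names) or r.gender not in ("M", "F"):
            continue
        has = key in r.pt_set()
        if r.gender == "F":
            a += has
            b += not has
        else:
            c += has
            d += not has
    nan = float("nan")
    if min(a, b, c, d) == 0:
        return GenderSignal(pt=pt, a=a, b=b, c=c, d=d, ror=nan, ror_lo=nan,
                            ror_hi=nan, p_value=nan, direction=None)
    ror = (a * d) / (b * c)
    half = Z95 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(chi2, df=1))
    return GenderSignal(
        pt=pt, a=a, b=b, c=c, d=d, ror=ror,
        ror_lo=math.exp(math.log(ror) - half), ror_hi=math.exp(math.log(ror) + half),
        p_value=p, direction="female_risk" if ror > 1 else "male_risk")


def gender_screen(store: Sequence[CaseReport], drug: str | Iterable[str],
                  min_count: int = 3) -> pd.DataFrame:
    """Gender contrast for every PT reported at least ``min_count`` times."""
    names = ({normalize_drug_name(drug)} if isinstance(drug, str)
             else {normalize_drug_name(d) for d in drug})
    counts = Counter()
    display = {}
    for r in store:
        if r.has_primary_suspect(names) and r.gender in ("M", "F"):
            for entry in r.reactions:
                k = normalize_pt(entry.pt)
                if k:
                    display.setdefault(k, str(entry.pt).strip())
            counts.update(r.pt_set())
    rows = []
    for key in sorted(k for k, v in counts.items() if v >= min_count):
        g = gender_ror(store, names, display[key])
        rows.append({"pt": display[key], "a": g.a, "b": g.b, "c": g.c, "d": g.d,
                     "ror": g.ror, "ror_lo": g.ror_lo, "ror_hi": g.ror_hi,
                     "p_value": g.p_value, "direction": g.direction,
                     "significant": bool(g.defined and g.p_value < 0.05)})
    return pd.DataFrame(rows, columns=["pt", "a", "b", "c", "d", "ror", "ror_lo",
                                       "ror_hi", "p_value", "direction",
                                       "significant"])
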