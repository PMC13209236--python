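"""Two-sample drug-target Mendelian randomization.

cis instruments for a gene-expression exposure are selected from summary
statistics (window of +/-500 kb around the gene, per-SNP F = (beta/se)^2 with
F >= 10, greedy LD clumping at r^2 < 0.001 within a 500 kb distance window),
harmonized against outcome summary statistics (palindromic variants dropped
unconditionally, allele swaps negate the outcome beta, strand flips are
reconciled), and combined with five estimators: inverse-variance weighted
(IVW) with multiplicative overdispersion, MR-Egger, weighted median, simple
mode and weighted mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (MRInputError, NoInstrumentsAfterHarmonizationError,
                     NoSharedVariantsError)

CIS_WINDOW = 500_000
CLUMP_WINDOW = 500_000
CLUMP_R2 = 0.001
MIN_F = 10.0

GWAS_COLUMNS = ("snp", "chrom", "pos", "effect_allele", "other_allele",
                "eaf", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

METHODS = ("IVW", "Egger", "weighted_median", "simple_mode", "weighted_mode")

_MIN_SNPS = {"IVW": 1, "Egger": 3, "weighted_median": 3,
             "simple_mode": 3, "weighted_mode": 3}


def _check_gwas_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise MRInputError(f"{what} summary statistics missing columns: {missing}")
    return df


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus start > end for {self.gene}")


@dataclass
class InstrumentSet:
    """Selected cis instruments with per-SNP F statistics and a filter trail."""

    gene: str
    table: pd.DataFrame          # surviving exposure rows + f_stat column
    provenance: pd.DataFrame     # snp, status in {kept, cis_fail, f_fail, clump_drop}, detail

    @property
    def snps(self) -> list[str]:
        return list(self.table["snp"])


def f_statistic(beta: float, se: float) -> float:
    """Per-variant instrument strength F = (beta/se)^2."""
    return (beta / se) ** 2


def select_instruments(exposure: pd.DataFrame, locus: GeneLocus,
                       ld: pd.DataFrame,
                       cis_window: int = CIS_WINDOW,
                       min_f: float = MIN_F,
                       clump_r2: float = CLUMP_R2,
                       clump_window: int = CLUMP_WINDOW) -> InstrumentSet:
    """Select cis instruments around ``locus`` from exposure summary stats.

    ``ld`` is a symmetric pairwise r^2 matrix indexed by SNP id (rows and
    columns).  Greedy clumping orders candidates by ascending p-value and
    keeps a variant iff its r^2 with every already-kept variant closer than
    ``clump_window`` bp stays below ``clump_r2``.
    """
    exposure = _check_gwas_frame(exposure, "exposure").copy()
    prov_rows = []

    lo, hi = locus.start - cis_window, locus.end + cis_window
    chrom = str(locus.chrom)
    in_cis = ((exposure["chrom"].astype(str) == chrom)
              & (exposure["pos"] >= lo) & (exposure["pos"] <= hi))
    for snp in exposure.loc[~in_cis, "snp"]:
        prov_rows.append((snp, "cis_fail", f"outside {chrom}:{lo}-{hi}"))
    cand = exposure.loc[in_cis].copy()

    cand["f_stat"] = (cand["beta"] / cand["se"]) ** 2
    weak = cand["f_stat"] < min_f
    for snp, f in zip(cand.loc[weak, "snp"], cand.loc[weak, "f_stat"]):
        prov_rows.append((snp, "f_fail", f"F={f:.3g} < {min_f:g}"))
    cand = cand.loc[~weak]

    if not isinstance(ld.index, pd.Index) or ld.index.empty:
        ld_index = set()
    else:
        ld_index = set(map(str, ld.index))
    # deterministic greedy order: p-value ascending, SNP id as tie-break
    cand = cand.sort_values(["pval", "snp"], kind="mergesort")
    kept_rows = []
    for row in cand.itertuples(index=False):
        snp = str(row.snp)
        if snp not in ld_index:
            raise MRInputError(f"SNP missing from LD matrix: {snp}")
        clumped_by = None
        for kept in kept_rows:
            if abs(int(row.pos) - int(kept.pos)) > clump_window:
                continue
            r2 = float(ld.loc[snp, str(kept.snp)])
            if r2 >= clump_r2:
                clumped_by = (kept.snp, r2)
                break
        if clumped_by is None:
            kept_rows.append(row)
            prov_rows.append((snp, "kept", ""))
        else:
            prov_rows.append((snp, "clump_drop",
                              f"r2={clumped_by[1]:.3g} with {clumped_by[0]}"))

    table = pd.DataFrame(kept_rows, columns=list(cand.columns))
    table = table.sort_values("snp", kind="mergesort").reset_index(drop=True)
    provenance = pd.DataFrame(sorted(prov_rows),
                              columns=["snp", "status", "detail"])
    return InstrumentSet(gene=locus.gene, table=table, provenance=provenance)


def is_palindromic(effect: str, other: str) -> bool:
    return _COMPLEMENT.get(str(effect).upper()) == str(other).upper()


def harmonize(instruments: InstrumentSet | pd.DataFrame,
              outcome: pd.DataFrame) -> pd.DataFrame:
    """Align exposure and outcome effects onto the exposure's effect allele.

    Returns a frame with columns snp, beta_exposure, se_exposure,
    beta_outcome, se_outcome, action; ``attrs['counts']`` tallies drops.
    Raises :class:`NoSharedVariantsError` when the join is empty and
    :class:`NoInstrumentsAfterHarmonizationError` when variants were shared
    but none survived.
    """
    exp = (instruments.table if isinstance(instruments, InstrumentSet)
           else instruments)
    exp = _check_gwas_frame(exp, "exposure")
    out = _check_gwas_frame(outcome, "outcome")

    out_by_snp = {str(r.snp): r for r in out.itertuples(index=False)}
    counts = {"input": len(exp), "missing_outcome": 0, "palindromic": 0,
              "allele_mismatch": 0, "kept": 0}
    rows = []
    shared = 0
    for e in exp.itertuples(index=False):
        snp = str(e.snp)
        o = out_by_snp.get(snp)
        if o is None:
            counts["missing_outcome"] += 1
            continue
        shared += 1
        ea, oa = str(e.effect_allele).upper(), str(e.other_allele).upper()
        if is_palindromic(ea, oa):
            counts["palindromic"] += 1
            continue
        oea, ooa = str(o.effect_allele).upper(), str(o.other_allele).upper()
        if (oea, ooa) == (ea, oa):
            beta_out, action = float(o.beta), "same"
        elif (oea, ooa) == (oa, ea):
            beta_out, action = -float(o.beta), "swap"
        else:
            cea, coa = _COMPLEMENT.get(oea, "?"), _COMPLEMENT.get(ooa, "?")
            if (cea, coa) == (ea, oa):
                beta_out, action = float(o.beta), "flip"
            elif (cea, coa) == (oa, ea):
                beta_out, action = -float(o.beta), "flip_swap"
            else:
                counts["allele_mismatch"] += 1
                continue
        counts["kept"] += 1
        rows.append({"snp": snp, "beta_exposure": float(e.beta),
                     "se_exposure": float(e.se), "beta_outcome": beta_out,
                     "se_outcome": float(o.se), "action": action})

    if shared == 0:
        raise NoSharedVariantsError(
            f"no variant identifiers shared between exposure ({len(exp)} SNPs) "
            f"and outcome ({len(out)} SNPs)", counts)
    if not rows:
        raise NoInstrumentsAfterHarmonizationError(
            f"all {shared} shared variants removed during harmonization "
            f"({counts['palindromic']} palindromic, "
            f"{counts['allele_mismatch']} allele mismatches)", counts)
    df = pd.DataFrame(rows)
    df.attrs["counts"] = counts
    return df


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p_value: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"method": self.method, "beta": self.beta, "se": self.se,
               "p_value": self.p_value, "n_snp": self.n_snp}
        row.update(self.extras)
        return row


def _validated_arrays(pairs: pd.DataFrame):
    bx = np.asarray(pairs["beta_exposure"], dtype=float)
    sx = np.asarray(pairs["se_exposure"], dtype=float)
    by = np.asarray(pairs["beta_outcome"], dtype=float)
    sy = np.asarray(pairs["se_outcome"], dtype=float)
    if np.any(np.abs(bx) < 1e-12):
        bad = pairs.loc[np.abs(bx) < 1e-12, "snp"].tolist()
        raise MRInputError(f"exposure beta too close to zero for Wald ratios: {bad}")
    if np.any(sy <= 0) or np.any(sx < 0):
        raise MRInputError("standard errors must be positive")
    return bx, sx, by, sy


def _two_sided_normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _ivw(bx, sx, by, sy) -> MREstimate:
    k = bx.size
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / denom
    if k > 1:
        q = float(np.sum(w * (by - beta * bx) ** 2))
        phi = max(1.0, math.sqrt(q / (k - 1)))
    else:
        q, phi = 0.0, 1.0
    se = phi / math.sqrt(denom)
    return MREstimate(method="IVW", beta=beta, se=se,
                      p_value=_two_sided_normal_p(beta / se), n_snp=k,
                      extras={"q_statistic": q, "overdispersion": phi})


def _egger(bx, sx, by, sy) -> MREstimate:
    k = bx.size
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coefs = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coefs
    # multiplicative scale floored at 1 (no "better-than-fixed-effect" shrinkage)
    sigma2 = float(np.sum(w * resid ** 2)) / (k - 2)
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(xtx) * scale
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    t_slope = coefs[1] / se_slope
    t_int = coefs[0] / se_int
    p_slope = float(2 * stats.t.sf(abs(t_slope), df=k - 2))
    p_int = float(2 * stats.t.sf(abs(t_int), df=k - 2))
    return MREstimate(method="Egger", beta=float(coefs[1]), se=se_slope,
                      p_value=p_slope, n_snp=k,
                      extras={"egger_intercept": float(coefs[0]),
                              "egger_intercept_se": se_int,
                              "egger_intercept_p": p_int})


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5, side="right"))
    # linear interpolation between bracketing order statistics
    c0, c1 = cum[j - 1], cum[j]
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - c0) / (c1 - c0))


def _mode_point(ratios: np.ndarray, weights: np.ndarray | None,
                bandwidth_factor: float = 1.0) -> float:
    """Mode of the Gaussian-kernel-smoothed ratio distribution."""
    k = ratios.size
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    s = 1.4826 * mad
    h = bandwidth_factor * s * (4.0 / (3.0 * k)) ** 0.2
    if h <= 0:  # all ratios (essentially) identical
        return float(np.median(ratios))
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = weights / np.sum(weights)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def _bootstrap_se(point_fn, bx, sx, by, sy, seed: int, n_boot: int) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + rng.normal(0.0, sx)
        bys = by + rng.normal(0.0, sy)
        bxs = np.where(np.abs(bxs) < 1e-12, 1e-12, bxs)
        est[i] = point_fn(bxs, bys)
    return float(np.std(est, ddof=1))


def estimate(pairs: pd.DataFrame, method: str, seed: int = 0,
             n_boot: int = 1000) -> MREstimate:
    """One MR estimate from harmonized effect pairs.

    Bootstrap-based standard errors (weighted median and modes) use a seeded
    parametric bootstrap of ``n_boot`` draws.
    """
    if method not in METHODS:
        raise MRInputError(f"unknown MR method {method!r}; choose from {METHODS}")
    bx, sx, by, sy = _validated_arrays(pairs)
    k = bx.size
    if k < _MIN_SNPS[method]:
        raise MRInputError(
            f"{method} needs at least {_MIN_SNPS[method]} instruments, got {k}")

    if method == "IVW":
        return _ivw(bx, sx, by, sy)
    if method == "Egger":
        return _egger(bx, sx, by, sy)

    ratios = by / bx
    ratio_w = (bx / sy) ** 2  # inverse variance of the first-order Wald ratio

    if method == "weighted_median":
        point_fn = lambda bxs, bys: _weighted_median_point(bys / bxs, (bxs / sy) ** 2)
        beta = _weighted_median_point(ratios, ratio_w)
    elif method == "simple_mode":
        point_fn = lambda bxs, bys: _mode_point(bys / bxs, None)
        beta = _mode_point(ratios, None)
    else:  # weighted_mode
        point_fn = lambda bxs, bys: _mode_point(bys / bxs, (bxs / sy) ** 2)
        beta = _mode_point(ratios, ratio_w)

    se = _bootstrap_se(point_fn, bx, sx, by, sy, seed=seed, n_boot=n_boot)
    if se == 0.0:
        p = 0.0 if beta != 0 else 1.0
    else:
        p = _two_sided_normal_p(beta / se)
    return MREstimate(method=method, beta=beta, se=se, p_value=p, n_snp=k)


class MRModel:
    """Five-method MR analysis of one harmonized exposure-outcome pair set."""

    def __init__(self, pairs: pd.DataFrame, gene: str = "", outcome: str = ""):
        self.pairs = pairs
        self.gene = gene
        self.outcome = outcome

    def fit(self, method: str, seed: int = 0, n_boot: int = 1000) -> MREstimate:
        return estimate(self.pairs, method, seed=seed, n_boot=n_boot)

    def fit_all(self, seed: int = 0, n_boot: int = 1000) -> "MRResults":
        estimates = {}
        for i, method in enumerate(METHODS):
            try:
                estimates[method] = self.fit(method, seed=seed + i, n_boot=n_boot)
            except MRInputError as exc:
                estimates[method] = exc
        return MRResults(gene=self.gene, outcome=self.outcome,
                         estimates=estimates, n_pairs=len(self.pairs))


@dataclass
class MRResults:
    gene: str
    outcome: str
    estimates: dict
    n_pairs: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for method, est in self.estimates.items():
            if isinstance(est, MREstimate):
                row = {"gene": self.gene, "outcome": self.outcome, **est.to_row()}
            else:
                row = {"gene": self.gene, "outcome": self.outcome,
                       "method": method, "beta": float("nan"), "se": float("nan"),
                       "p_value": float("nan"), "n_snp": self.n_pairs,
                       "note": str(est)}
            rows.append(row)
        return pd.DataFrame(rows)
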