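"""Synthetic FAERS-dialect generator with a truth ledger.

Every report draws one drug (planted drugs by configured market share,
remainder split over background drugs) and one Preferred Term from a
background multinomial whose odds for planted (drug, PT) pairs are multiplied
by the configured effect — so the target reporting odds ratio of a planted
pair equals its multiplier.  Outcome codes follow a logistic model of IME
occurrence on gender, age and weight; onset days follow per-drug Weibull
laws; a configurable fraction of case ids is emitted as duplicate versions
with strictly ordered receipt dates.  The ledger records every planted
quantity so downstream results can be checked without re-reading the files.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: default MedDRA-like PT vocabulary with primary SOC assignments
_DEFAULT_PTS = {
    "Platelet count decreased": "Investigations",
    "White blood cell count decreased": "Investigations",
    "Neutrophil count decreased": "Investigations",
    "Aspartate aminotransferase increased": "Investigations",
    "Electrocardiogram qt prolonged": "Investigations",
    "Haemoglobin decreased": "Investigations",
    "Hypophosphataemia": "Metabolism and nutrition disorders",
    "Hypocalcaemia": "Metabolism and nutrition disorders",
    "Decreased appetite": "Metabolism and nutrition disorders",
    "Hypokalaemia": "Metabolism and nutrition disorders",
    "Anaemia": "Blood and lymphatic system disorders",
    "Febrile neutropenia": "Blood and lymphatic system disorders",
    "Thrombocytopenia": "Blood and lymphatic system disorders",
    "Myelosuppression": "Blood and lymphatic system disorders",
    "Nausea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Non-cardiac chest pain": "General disorders and administration site conditions",
    "Fatigue": "General disorders and administration site conditions",
    "Asthenia": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Oedema peripheral": "General disorders and administration site conditions",
    "Death": "General disorders and administration site conditions",
    "Pneumonia": "Infections and infestations",
    "Sepsis": "Infections and infestations",
    "Tumour lysis syndrome": "Metabolism and nutrition disorders",
    "Myocardial infarction": "Cardiac disorders",
    "Atrial fibrillation": "Cardiac disorders",
    "Renal impairment": "Renal and urinary disorders",
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
}

_OTHER_COUNTRIES = ("JP", "FR", "DE", "GB", "IT", "CA", "CN", "KR")

_OCCP_REVERSE = {"physician": "MD", "other_health_professional": "OT",
                 "pharmacist": "PH", "consumer": "CN", "unknown": ""}


def default_pt_dictionary() -> dict:
    """PT -> SOC mapping of the built-in background vocabulary."""
    return dict(_DEFAULT_PTS)


def sample_tto_days(shape: float, scale: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Integer onset days: ceil of Weibull(shape, scale) draws, minimum 1."""
    w = scale * rng.weibull(shape, size=n)
    return np.maximum(1, np.ceil(w)).astype(int)


@dataclass
class DrugSpec:
    """One planted drug: market share, per-PT odds multipliers, TTO law."""

    name: str
    share: float
    event_effects: dict = field(default_factory=dict)  # PT -> odds multiplier
    tto_shape: float = 0.7
    tto_scale: float = 60.0


@dataclass
class DemographicsSpec:
    male_share: float = 0.53          # among reports with known gender
    gender_missing: float = 0.12
    age_youth_share: float = 0.06     # fraction drawn uniform 1-17 years
    age_mean: float = 62.0
    age_sd: float = 13.0
    age_missing: float = 0.20
    weight_mean: float = 72.0
    weight_sd: float = 16.0
    weight_missing: float = 0.45
    reporter_probs: dict = field(default_factory=lambda: {
        "physician": 0.35, "other_health_professional": 0.25,
        "pharmacist": 0.07, "consumer": 0.20, "unknown": 0.13})
    us_share: float = 0.55


@dataclass
class ImeLogitSpec:
    """True logistic model of IME probability on gender/age/weight."""

    intercept: float = -1.5
    male: float = math.log(1.5)
    age: float = 0.01      # per year
    weight: float = 0.0    # per kg


@dataclass
class FaersSimConfig:
    n_reports: int = 50_000
    drugs: list = field(default_factory=lambda: [
        DrugSpec("vorinostat", 0.08, {"Febrile neutropenia": 10.0},
                 tto_shape=0.70, tto_scale=60.0),
        DrugSpec("romidepsin", 0.08, {"Tumour lysis syndrome": 10.0},
                 tto_shape=0.56, tto_scale=70.0),
        DrugSpec("belinostat", 0.08, {"Non-cardiac chest pain": 10.0},
                 tto_shape=0.76, tto_scale=28.0),
        DrugSpec("panobinostat", 0.08, {"Hypophosphataemia": 10.0},
                 tto_shape=0.59, tto_scale=43.0),
    ])
    duplicate_rate: float = 0.10
    demographics: DemographicsSpec = field(default_factory=DemographicsSpec)
    ime_logit: ImeLogitSpec = field(default_factory=ImeLogitSpec)
    background_pts: dict = field(default_factory=default_pt_dictionary)
    n_background_drugs: int = 20
    concomitant_rate: float = 0.25
    tto_missing_rate: float = 0.25
    start_year: int = 2015
    end_year: int = 2023
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        total_share = sum(d.share for d in self.drugs)
        if any(d.share < 0 for d in self.drugs) or total_share > 1.0 + 1e-12:
            raise ValueError("drug shares must be nonnegative and sum to <= 1")
        for d in self.drugs:
            if d.tto_shape <= 0 or d.tto_scale <= 0:
                raise ValueError(f"Weibull parameters must be positive for {d.name}")
            for pt, m in d.event_effects.items():
                if m <= 0:
                    raise ValueError(f"multiplier for ({d.name}, {pt}) must be > 0")
                if pt not in self.background_pts:
                    raise ValueError(f"planted PT {pt!r} not in background vocabulary")
        for rate in (self.duplicate_rate, self.tto_missing_rate,
                     self.concomitant_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if not self.background_pts:
            raise ValueError("background PT vocabulary must be non-empty")
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")


def _pt_weights(pts: list[str]) -> np.ndarray:
    # Zipf-like base reporting frequencies over the vocabulary
    w = 1.0 / np.arange(1, len(pts) + 1)
    return w / w.sum()


def generate_faers(config: FaersSimConfig, outdir=None, delimiter: str = "$"):
    """Generate the five tables and the truth ledger.

    Returns ``(tables, ledger)`` where ``tables`` maps demo/drug/reac/ther/
    outc to DataFrames of strings.  When ``outdir`` is given the tables are
    written as ``<NAME>.txt`` in the FAERS ASCII dialect plus
    ``truth_ledger.json``; identical seeds give byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    demo_cfg = config.demographics

    pts = sorted(config.background_pts)
    base_w = _pt_weights(pts)
    pt_index = {p: i for i, p in enumerate(pts)}

    drug_names = [d.name for d in config.drugs]
    bg_names = [f"backgrounddrug{i:02d}" for i in range(1, config.n_background_drugs + 1)]
    all_drugs = drug_names + bg_names
    bg_share = max(0.0, 1.0 - sum(d.share for d in config.drugs))
    probs = np.array([d.share for d in config.drugs]
                     + [bg_share / len(bg_names)] * len(bg_names))
    probs = probs / probs.sum()

    # per-drug PT sampling distributions (odds multipliers on the base law)
    pt_probs = {}
    for d in config.drugs:
        w = base_w.copy()
        for pt, m in d.event_effects.items():
            w[pt_index[pt]] *= m
        pt_probs[d.name] = w / w.sum()
    bg_pt_probs = base_w

    # ---- vectorized draws -------------------------------------------------
    drug_idx = rng.choice(len(all_drugs), size=n, p=probs)
    male = rng.random(n) < demo_cfg.male_share
    gender_missing = rng.random(n) < demo_cfg.gender_missing
    youth = rng.random(n) < demo_cfg.age_youth_share
    age = np.where(youth, rng.uniform(1, 17.99, n),
                   np.clip(rng.normal(demo_cfg.age_mean, demo_cfg.age_sd, n), 18, 95))
    age_missing = rng.random(n) < demo_cfg.age_missing
    weight = np.clip(rng.normal(demo_cfg.weight_mean, demo_cfg.weight_sd, n), 35, 140)
    weight_missing = rng.random(n) < demo_cfg.weight_missing

    rep_labels = list(demo_cfg.reporter_probs)
    rep_p = np.array([demo_cfg.reporter_probs[k] for k in rep_labels], dtype=float)
    rep_idx = rng.choice(len(rep_labels), size=n, p=rep_p / rep_p.sum())
    is_us = rng.random(n) < demo_cfg.us_share
    other_country = rng.choice(len(_OTHER_COUNTRIES), size=n)

    lm = config.ime_logit
    logit_p = lm.intercept + lm.male * male + lm.age * age + lm.weight * weight
    p_ime = 1.0 / (1.0 + np.exp(-logit_p))
    ime = rng.random(n) < p_ime
    ime_code_idx = rng.choice(4, size=n, p=[0.25, 0.12, 0.60, 0.03])
    ime_codes = np.array(["DE", "LT", "HO", "DS"])
    nonime_other = rng.random(n) < 0.60

    pt_idx = np.empty(n, dtype=int)
    for di, name in enumerate(all_drugs):
        mask = drug_idx == di
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        w = pt_probs.get(name, bg_pt_probs)
        pt_idx[mask] = rng.choice(len(pts), size=cnt, p=w)

    tto_cont = np.empty(n)
    for di, d in enumerate(config.drugs):
        mask = drug_idx == di
        tto_cont[mask] = d.tto_scale * rng.weibull(d.tto_shape, size=int(mask.sum()))
    bg_mask = drug_idx >= len(config.drugs)
    tto_cont[bg_mask] = 45.0 * rng.weibull(0.9, size=int(bg_mask.sum()))
    tto_days = np.maximum(1, np.ceil(tto_cont)).astype(int)

    tto_missing = rng.random(n) < config.tto_missing_rate
    tto_missing_mode = rng.choice(3, size=n, p=[0.5, 0.3, 0.2])

    span_start = _dt.date(config.start_year, 1, 1)
    span_days = (_dt.date(config.end_year, 12, 31) - span_start).days
    fda_offset = rng.integers(0, span_days + 1, size=n)
    event_gap = rng.integers(0, 180, size=n)

    duplicated = rng.random(n) < config.duplicate_rate
    dup_back = rng.integers(10, 400, size=n)

    concomitant = rng.random(n) < config.concomitant_rate
    conc_idx = rng.integers(0, len(bg_names), size=n)

    # ---- assemble rows ----------------------------------------------------
    demo_rows, drug_rows, reac_rows, ther_rows, outc_rows = [], [], [], [], []
    records = []
    annual = {}

    for i in range(n):
        caseid = str(10_000_000 + i)
        drug = all_drugs[drug_idx[i]]
        pt = pts[pt_idx[i]]
        fda_date = span_start + _dt.timedelta(days=int(fda_offset[i]))
        fda_str = fda_date.strftime("%Y%m%d")

        survivor_pid = caseid + "1"
        versions = [(survivor_pid, fda_str)]
        if duplicated[i]:
            early = fda_date - _dt.timedelta(days=int(dup_back[i]))
            # duplicate gets the *larger* primaryid so receipt date must win
            versions.insert(0, (caseid + "9", early.strftime("%Y%m%d")))

        sex = "" if gender_missing[i] else ("M" if male[i] else "F")
        age_str = "" if age_missing[i] else f"{age[i]:.1f}"
        wt_str = "" if weight_missing[i] else f"{weight[i]:.1f}"
        occp = _OCCP_REVERSE[rep_labels[rep_idx[i]]]
        country = "US" if is_us[i] else _OTHER_COUNTRIES[other_country[i]]

        event_date = fda_date - _dt.timedelta(days=int(event_gap[i]))
        start_date = event_date - _dt.timedelta(days=int(tto_days[i]) - 1)
        if tto_missing[i]:
            mode = tto_missing_mode[i]
            if mode == 0:
                start_str, event_str = "", event_date.strftime("%Y%m%d")
            elif mode == 1:
                start_str = start_date.strftime("%Y%m")
                event_str = event_date.strftime("%Y%m%d")
            else:
                start_str = start_date.strftime("%Y%m%d")
                event_str = ""
            tto_observed = None
        else:
            start_str = start_date.strftime("%Y%m%d")
            event_str = event_date.strftime("%Y%m%d")
            tto_observed = int(tto_days[i])

        if ime[i]:
            out_codes = [str(ime_codes[ime_code_idx[i]])]
        elif nonime_other[i]:
            out_codes = ["OT"]
        else:
            out_codes = []

        for pid, fda in versions:
            demo_rows.append((pid, caseid, fda, sex, age_str, "YR" if age_str else "",
                              wt_str, "KG" if wt_str else "", occp, country))
            drug_rows.append((pid, drug, "PS"))
            if concomitant[i]:
                drug_rows.append((pid, bg_names[conc_idx[i]], "C"))
            reac_rows.append((pid, pt, event_str))
            ther_rows.append((pid, start_str))
            for code in out_codes:
                outc_rows.append((pid, code))

        annual[fda_date.year] = annual.get(fda_date.year, 0) + 1
        records.append({
            "caseid": caseid, "survivor_primaryid": survivor_pid,
            "all_primaryids": [v[0] for v in versions],
            "drug": drug, "pt": pt,
            "gender_true": "M" if male[i] else "F",
            "gender_observed": sex or "UNK",
            "age": None if age_missing[i] else round(float(age[i]), 1),
            "age_true": float(age[i]),
            "weight": None if weight_missing[i] else round(float(weight[i]), 1),
            "weight_true": float(weight[i]),
            "ime": bool(ime[i]),
            "outcome_codes": out_codes,
            "tto_days": tto_observed,
            "tto_days_true": int(tto_days[i]),
            "tto_continuous": float(tto_cont[i]),
            "year": fda_date.year,
        })

    tables = {
        "demo": pd.DataFrame(demo_rows, columns=[
            "primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
            "wt", "wt_cod", "occp_cod", "reporter_country"]),
        "drug": pd.DataFrame(drug_rows, columns=["primaryid", "drugname", "role_cod"]),
        "reac": pd.DataFrame(reac_rows, columns=["primaryid", "pt", "event_dt"]),
        "ther": pd.DataFrame(ther_rows, columns=["primaryid", "start_dt"]),
        "outc": pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]),
    }

    ledger = {
        "schema": "pvsignal-faers-truth/1",
        "seed": config.seed,
        "n_cases": n,
        "planted_effects": {d.name: dict(d.event_effects) for d in config.drugs},
        "tto_laws": {d.name: {"shape": d.tto_shape, "scale": d.tto_scale}
                     for d in config.drugs},
        "ime_logit": asdict(config.ime_logit),
        "duplicate_rate": config.duplicate_rate,
        "annual_counts": {str(y): annual[y] for y in sorted(annual)},
        "records": records,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name.upper()}.txt", sep=delimiter, index=False,
                      lineterminator="\n")
        with open(outdir / "truth_ledger.json", "w") as fh:
            json.dump(ledger, fh, indent=1, sort_keys=True)
        pd.DataFrame(sorted(config.background_pts.items()),
                     columns=["pt", "soc"]).to_csv(
            outdir / "pt_soc.tsv", sep="\t", index=False, lineterminator="\n")

    return tables, ledger
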