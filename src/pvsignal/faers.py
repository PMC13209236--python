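"""FAERS-dialect report store.

Reads the quarterly-extract ASCII dialect (one ``$``-delimited file per table:
DEMO, DRUG, REAC, THER, OUTC), normalizes rows into :class:`CaseReport`
objects, applies the FDA-recommended deduplication rule (per CASEID keep the
most recent FDA_DT, ties broken by the largest PRIMARYID), filters on the
primary-suspect role, and computes descriptive summaries.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MeddraLookupError, SchemaError

#: outcome codes accepted in OUTC, most severe first.  Reports are tabulated
#: once, by their most severe outcome; CA sits between DS and OT so that
#: congenital anomalies (an IME) are not folded into "Other".
OUTCOME_PRECEDENCE = ("DE", "LT", "HO", "DS", "CA", "OT")

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "OT": "Other",
}

DRUG_ROLES = ("PS", "SS", "C", "I")

#: FAERS occupation codes -> reporter classes
_OCCP_MAP = {
    "MD": "physician",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
    "PH": "pharmacist",
    "CN": "consumer",
}

REPORTER_LABELS = {
    "physician": "Physician",
    "other_health_professional": "Other health-professional",
    "pharmacist": "Pharmacist",
    "consumer": "Consumer",
    "unknown": "Unknown",
}

#: mandatory columns per table in the FAERS ASCII dialect
REQUIRED_COLUMNS = {
    "demo": ("primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
             "wt", "wt_cod", "occp_cod", "reporter_country"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid", "start_dt"),
    "outc": ("primaryid", "outc_cod"),
}


@dataclass(frozen=True)
class FaersDate:
    """A FAERS date of possibly partial precision (YYYYMMDD / YYYYMM / YYYY).

    ``date`` is set only for full day-resolution values; ``year`` is set for
    any parseable precision so annual tallies can still use partial dates.
    """

    raw: str
    date: _dt.date | None
    year: int | None

    @property
    def complete(self) -> bool:
        return self.date is not None

    def sort_key(self) -> str:
        # right-pad so YYYY/YYYYMM compare sensibly against full dates
        return self.raw.ljust(8, "0") if self.raw.isdigit() else ""


def parse_faers_date(value) -> FaersDate:
    """Parse a FAERS date string; unparseable input yields an all-missing date."""
    s = "" if value is None else str(value).strip()
    if s.endswith(".0"):  # numeric round-trip artifacts
        s = s[:-2]
    if not s.isdigit():
        return FaersDate(raw=s, date=None, year=None)
    if len(s) == 8:
        try:
            d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return FaersDate(raw=s, date=None, year=None)
        return FaersDate(raw=s, date=d, year=d.year)
    if len(s) == 6:
        return FaersDate(raw=s, date=None, year=int(s[:4]))
    if len(s) == 4:
        return FaersDate(raw=s, date=None, year=int(s))
    return FaersDate(raw=s, date=None, year=None)


def normalize_drug_name(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace."""
    return " ".join(str(name).split()).casefold()


def normalize_pt(pt: str) -> str:
    return " ".join(str(pt).split()).casefold()


@dataclass(frozen=True)
class DrugEntry:
    name: str          # normalized
    role: str          # PS / SS / C / I
    start_dt: FaersDate | None = None


@dataclass(frozen=True)
class ReactionEntry:
    pt: str
    event_dt: FaersDate | None = None


@dataclass
class CaseReport:
    """One safety report (one DEMO row plus its child-table rows)."""

    primaryid: str
    caseid: str
    fda_dt: FaersDate
    gender: str = "UNK"              # M / F / UNK
    age_years: float | None = None
    weight_kg: float | None = None
    reporter: str = "unknown"
    country: str = ""
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    reactions: list = field(default_factory=list)

    def pt_set(self) -> set[str]:
        """Distinct normalized PTs on this report."""
        return {normalize_pt(r.pt) for r in self.reactions if str(r.pt).strip()}

    def has_primary_suspect(self, names: set[str]) -> bool:
        return any(d.role == "PS" and d.name in names for d in self.drugs)

    def outcome_class(self) -> str:
        for code in OUTCOME_PRECEDENCE:
            if code in self.outcomes:
                return code
        return "Unknown"


class MeddraDict:
    """Flat PT -> primary SOC mapping (MedDRA-like, two levels only)."""

    def __init__(self, mapping: Mapping[str, str]):
        self._display = {}
        self._mapping = {}
        for pt, soc in mapping.items():
            key = normalize_pt(pt)
            self._mapping[key] = str(soc).strip()
            self._display[key] = str(pt).strip()
        self.socs = sorted(set(self._mapping.values()))

    @classmethod
    def from_tsv(cls, path) -> "MeddraDict":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "pt" not in cols or "soc" not in cols:
            raise SchemaError("PT->SOC dictionary must have columns 'pt' and 'soc'")
        return cls(dict(zip(df[cols["pt"]], df[cols["soc"]])))

    def soc_of(self, pt: str) -> str:
        key = normalize_pt(pt)
        if key not in self._mapping:
            raise MeddraLookupError(f"PT not in dictionary: {pt!r}")
        return self._mapping[key]

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self._mapping

    def pts_in(self, soc: str) -> list[str]:
        soc = str(soc).strip()
        return sorted(d for k, d in self._display.items() if self._mapping[k] == soc)

    def to_tsv(self, path) -> None:
        rows = sorted((d, self._mapping[k]) for k, d in self._display.items())
        pd.DataFrame(rows, columns=["pt", "soc"]).to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self._mapping)


def read_faers_tables(paths: Mapping[str, object], delimiter: str = "$") -> dict:
    """Read the five FAERS ASCII tables into raw string DataFrames.

    ``paths`` maps lowercase table names (demo/drug/reac/ther/outc) to file
    locations.  Missing mandatory columns raise :class:`SchemaError` naming
    the column; value-level problems are deferred to :func:`build_store`.
    """
    tables = {}
    for name, path in paths.items():
        name = name.lower()
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{name.upper()} table not found: {path}")
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                         engine="python")
        df.columns = [c.strip().lower() for c in df.columns]
        for col in REQUIRED_COLUMNS.get(name, ()):
            if col not in df.columns:
                raise SchemaError(
                    f"{name.upper()} table {path} is missing mandatory column {col!r}")
        tables[name] = df
    return tables


_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 7 / 365.25,
                "DY": 1 / 365.25, "HR": 1 / (24 * 365.25), "": 1.0}


def _parse_age(age: str, cod: str, warnings: Counter) -> float | None:
    s = str(age).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        warnings["age_unparseable"] += 1
        return None
    factor = _AGE_FACTORS.get(str(cod).strip().upper())
    if factor is None:
        warnings["age_cod_unknown"] += 1
        factor = 1.0
    years = v * factor
    if years < 0:
        warnings["age_negative"] += 1
        return None
    return years


def _parse_weight(wt: str, cod: str, warnings: Counter) -> float | None:
    s = str(wt).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        warnings["weight_unparseable"] += 1
        return None
    cod = str(cod).strip().upper()
    if cod in ("LBS", "LB"):
        v *= 0.453592
    elif cod not in ("KG", "KGS", ""):
        warnings["weight_cod_unknown"] += 1
    if v <= 0:
        warnings["weight_nonpositive"] += 1
        return None
    return v


def build_store(tables: Mapping[str, pd.DataFrame]):
    """Assemble :class:`CaseReport` objects from raw tables.

    Returns ``(reports, warnings)`` where ``warnings`` is a Counter of
    row-level problems (kept rows with a field set missing).
    """
    warnings: Counter = Counter()
    demo = tables["demo"]

    drugs_by_pid: dict[str, list] = {}
    if "drug" in tables:
        for row in tables["drug"].itertuples(index=False):
            role = str(row.role_cod).strip().upper()
            if role not in DRUG_ROLES:
                warnings["drug_role_unknown"] += 1
            start = None
            if hasattr(row, "start_dt"):
                start = parse_faers_date(row.start_dt)
            drugs_by_pid.setdefault(str(row.primaryid).strip(), []).append(
                DrugEntry(name=normalize_drug_name(row.drugname), role=role,
                          start_dt=start))

    reac_by_pid: dict[str, list] = {}
    if "reac" in tables:
        reac = tables["reac"]
        has_event = "event_dt" in reac.columns
        for row in reac.itertuples(index=False):
            pt = str(row.pt).strip()
            if not pt:
                warnings["reaction_empty_pt"] += 1
                continue
            ev = parse_faers_date(row.event_dt) if has_event else None
            reac_by_pid.setdefault(str(row.primaryid).strip(), []).append(
                ReactionEntry(pt=pt, event_dt=ev))

    ther_by_pid: dict[str, FaersDate] = {}
    if "ther" in tables:
        for row in tables["ther"].itertuples(index=False):
            pid = str(row.primaryid).strip()
            d = parse_faers_date(row.start_dt)
            # keep the earliest complete therapy start for the report
            prev = ther_by_pid.get(pid)
            if prev is None or (d.complete and (not prev.complete or d.date < prev.date)):
                ther_by_pid[pid] = d

    outc_by_pid: dict[str, set] = {}
    if "outc" in tables:
        for row in tables["outc"].itertuples(index=False):
            code = str(row.outc_cod).strip().upper()
            if not code:
                continue
            if code not in OUTCOME_PRECEDENCE and code != "RI":
                warnings["outcome_code_unknown"] += 1
            outc_by_pid.setdefault(str(row.primaryid).strip(), set()).add(code)

    reports = []
    for row in demo.itertuples(index=False):
        pid = str(row.primaryid).strip()
        fda = parse_faers_date(row.fda_dt)
        if fda.year is None:
            warnings["fda_dt_unparseable"] += 1
        sex = str(row.sex).strip().upper()
        gender = sex if sex in ("M", "F") else "UNK"
        occp = str(row.occp_cod).strip().upper()
        reporter = _OCCP_MAP.get(occp, "unknown")

        # therapy start attaches to the first drug entry lacking one
        entries = drugs_by_pid.get(pid, [])
        ther_start = ther_by_pid.get(pid)
        if ther_start is not None and entries:
            entries = [DrugEntry(d.name, d.role, d.start_dt or ther_start)
                       for d in entries]

        reports.append(CaseReport(
            primaryid=pid,
            caseid=str(row.caseid).strip(),
            fda_dt=fda,
            gender=gender,
            age_years=_parse_age(row.age, row.age_cod, warnings),
            weight_kg=_parse_weight(row.wt, row.wt_cod, warnings),
            reporter=reporter,
            country=str(row.reporter_country).strip(),
            outcomes=frozenset(outc_by_pid.get(pid, set())
                               & set(OUTCOME_PRECEDENCE)),
            drugs=entries,
            reactions=reac_by_pid.get(pid, []),
        ))
    return reports, warnings


def load_store(paths: Mapping[str, object], delimiter: str = "$"):
    """Convenience: read tables and build the report store in one call."""
    return build_store(read_faers_tables(paths, delimiter=delimiter))


def _primaryid_key_numeric(pid: str):
    return int(pid)


def deduplicate(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep one report per CASEID: the most recent FDA_DT, ties broken by the
    largest PRIMARYID (numeric comparison when all competing ids are
    all-digit strings, else lexicographic).  Output is sorted by caseid."""
    groups: dict[str, list[CaseReport]] = {}
    for r in reports:
        groups.setdefault(r.caseid, []).append(r)

    kept = []
    for caseid in sorted(groups):
        cands = groups[caseid]
        if len(cands) == 1:
            kept.append(cands[0])
            continue
        numeric = all(r.primaryid.isdigit() for r in cands)
        pid_key = _primaryid_key_numeric if numeric else str
        kept.append(max(cands, key=lambda r: (r.fda_dt.sort_key(),
                                              pid_key(r.primaryid))))
    return kept


def select_primary_suspect(store: Sequence[CaseReport],
                           drug_names: Iterable[str]) -> list[CaseReport]:
    """Reports in which at least one query drug appears with role PS."""
    names = {normalize_drug_name(n) for n in drug_names}
    names.discard("")
    if not names:
        raise ValueError("drug_names must contain at least one non-empty name")
    return [r for r in store if r.has_primary_suspect(names)]


def age_band(age: float | None) -> str:
    if age is None or pd.isna(age):
        return "Unknown"
    if age < 18:
        return "<18 years"
    if age <= 64:
        return "18-64 years"
    return ">64 years"


def weight_band(wt: float | None) -> str:
    if wt is None or pd.isna(wt):
        return "Unknown"
    if wt < 80:
        return "<80 kg"
    if wt <= 100:
        return "80-100 kg"
    return ">100 kg"


AGE_BANDS = ("<18 years", "18-64 years", ">64 years", "Unknown")
WEIGHT_BANDS = ("<80 kg", "80-100 kg", ">100 kg", "Unknown")
GENDER_LABELS = {"M": "Male", "F": "Female", "UNK": "Unknown"}


def summarize_demographics(reports: Sequence[CaseReport]) -> pd.DataFrame:
    """Descriptive table: counts and percentages per category partition.

    Percentages use the subset size as denominator and are reported to two
    decimals.  The frame's ``attrs`` carry mean/SD of age and weight over
    non-missing values (None when everything is missing).
    """
    if not reports:
        raise ValueError("cannot summarize an empty report subset")
    n = len(reports)
    rows = []

    def emit(section, labels, counter):
        for label in labels:
            count = counter.get(label, 0)
            rows.append((section, label, count, round(100.0 * count / n, 2)))

    emit("Gender", ("Male", "Female", "Unknown"),
         Counter(GENDER_LABELS[r.gender] for r in reports))
    emit("Age", AGE_BANDS, Counter(age_band(r.age_years) for r in reports))
    emit("Weight", WEIGHT_BANDS, Counter(weight_band(r.weight_kg) for r in reports))
    emit("Reporter", tuple(REPORTER_LABELS.values()),
         Counter(REPORTER_LABELS[r.reporter] for r in reports))

    def country_class(c: str) -> str:
        return ("United States"
                if c.strip().upper() in ("US", "USA", "UNITED STATES")
                else "Other country")

    emit("Country", ("United States", "Other country"),
         Counter(country_class(r.country) for r in reports))

    outcome_labels = tuple(OUTCOME_LABELS[c] for c in OUTCOME_PRECEDENCE) + ("Unknown",)
    emit("Outcome", outcome_labels,
         Counter(OUTCOME_LABELS.get(r.outcome_class(), "Unknown") for r in reports))

    df = pd.DataFrame(rows, columns=["section", "category", "count", "percent"])

    import numpy as np
    for attr, values in (("age", [r.age_years for r in reports]),
                         ("weight", [r.weight_kg for r in reports])):
        vals = np.array([v for v in values if v is not None], dtype=float)
        if vals.size:
            df.attrs[f"{attr}_mean"] = float(vals.mean())
            df.attrs[f"{attr}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        else:
            df.attrs[f"{attr}_mean"] = None
            df.attrs[f"{attr}_sd"] = None
    df.attrs["n"] = n
    return df


def annual_counts(reports: Sequence[CaseReport]) -> dict[int, int]:
    """Report counts per calendar year of FDA_DT; interior years zero-filled."""
    years = [r.fda_dt.year for r in reports if r.fda_dt.year is not None]
    if not years:
        return {}
    counts = Counter(years)
    return {y: counts.get(y, 0) for y in range(min(years), max(years) + 1)}
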