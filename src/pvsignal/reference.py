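"""Published FAERS demographic counts for the four HDAC inhibitors.

These are the deduplicated primary-suspect report tallies (market entry
through 2023-12-31) for Vorinostat, Romidepsin, Belinostat and Panobinostat,
kept here as a fixed reference so the percentage arithmetic of
:func:`pvsignal.faers.summarize_demographics` can be validated against the
printed values.  ``reports_from_counts`` expands a count table into a
minimal synthetic report list whose category marginals match the counts
exactly (categories are assigned independently, so only the per-category
percentages — not joint distributions or means — are meaningful).
"""

from __future__ import annotations

from .faers import CaseReport, FaersDate

#: per-drug counts; each section lists (category, count) in summary order
HDACI_DEMOGRAPHIC_COUNTS = {
    "vorinostat": {
        "n": 1360,
        "Gender": [("Male", 699), ("Female", 558), ("Unknown", 103)],
        "Age": [("<18 years", 102), ("18-64 years", 570), (">64 years", 471),
                ("Unknown", 217)],
        "Weight": [("<80 kg", 437), ("80-100 kg", 153), (">100 kg", 55),
                   ("Unknown", 715)],
        "Reporter": [("Physician", 340), ("Other health-professional", 398),
                     ("Pharmacist", 81), ("Consumer", 350), ("Unknown", 191)],
        "Country": [("United States", 940), ("Other country", 420)],
        "Outcome": [("Death", 242), ("Life-threatening", 185),
                    ("Hospitalization", 558), ("Disability", 10),
                    ("Other", 145), ("Unknown", 220)],
    },
    "romidepsin": {
        "n": 1065,
        "Gender": [("Male", 519), ("Female", 388), ("Unknown", 158)],
        "Age": [("<18 years", 4), ("18-64 years", 336), (">64 years", 353),
                ("Unknown", 372)],
        "Weight": [("<80 kg", 310), ("80-100 kg", 75), (">100 kg", 38),
                   ("Unknown", 642)],
        "Reporter": [("Physician", 591), ("Other health-professional", 328),
                     ("Pharmacist", 98), ("Consumer", 41), ("Unknown", 7)],
        "Country": [("United States", 418), ("Other country", 647)],
        "Outcome": [("Death", 344), ("Life-threatening", 56),
                    ("Hospitalization", 276), ("Disability", 7),
                    ("Other", 248), ("Unknown", 134)],
    },
    "belinostat": {
        "n": 225,
        "Gender": [("Male", 116), ("Female", 82), ("Unknown", 27)],
        "Age": [("<18 years", 1), ("18-64 years", 88), (">64 years", 60),
                ("Unknown", 76)],
        "Weight": [("<80 kg", 52), ("80-100 kg", 26), (">100 kg", 13),
                   ("Unknown", 134)],
        "Reporter": [("Physician", 130), ("Other health-professional", 33),
                     ("Pharmacist", 19), ("Consumer", 43), ("Unknown", 0)],
        "Country": [("United States", 138), ("Other country", 87)],
        "Outcome": [("Death", 66), ("Life-threatening", 9),
                    ("Hospitalization", 41), ("Disability", 1),
                    ("Other", 50), ("Unknown", 58)],
    },
    "panobinostat": {
        "n": 1234,
        "Gender": [("Male", 490), ("Female", 414), ("Unknown", 330)],
        "Age": [("<18 years", 28), ("18-64 years", 231), (">64 years", 367),
                ("Unknown", 608)],
        "Weight": [("<80 kg", 160), ("80-100 kg", 58), (">100 kg", 21),
                   ("Unknown", 995)],
        "Reporter": [("Physician", 509), ("Other health-professional", 295),
                     ("Pharmacist", 63), ("Consumer", 289), ("Unknown", 78)],
        "Country": [("United States", 551), ("Other country", 683)],
        "Outcome": [("Death", 343), ("Life-threatening", 43),
                    ("Hospitalization", 289), ("Disability", 6),
                    ("Other", 279), ("Unknown", 274)],
    },
}

#: the percentages printed alongside the counts above, for cross-checking
HDACI_PRINTED_PERCENTAGES = {
    "vorinostat": {("Gender", "Male"): 51.40, ("Gender", "Female"): 41.03,
                   ("Gender", "Unknown"): 7.57,
                   ("Outcome", "Hospitalization"): 41.03,
                   ("Country", "United States"): 69.12},
    "romidepsin": {("Gender", "Male"): 48.73, ("Age", "Unknown"): 34.93,
                   ("Outcome", "Death"): 32.30,
                   ("Reporter", "Physician"): 55.49},
    "belinostat": {("Gender", "Male"): 51.56, ("Weight", "Unknown"): 59.56,
                   ("Outcome", "Unknown"): 25.78,
                   ("Country", "United States"): 61.33},
    "panobinostat": {("Gender", "Male"): 39.71, ("Age", ">64 years"): 29.74,
                     ("Outcome", "Death"): 27.80,
                     ("Reporter", "Consumer"): 23.42},
}

_GENDER_CODE = {"Male": "M", "Female": "F", "Unknown": "UNK"}
_AGE_VALUE = {"<18 years": 10.0, "18-64 years": 45.0, ">64 years": 75.0,
              "Unknown": None}
_WEIGHT_VALUE = {"<80 kg": 65.0, "80-100 kg": 90.0, ">100 kg": 110.0,
                 "Unknown": None}
_REPORTER_CODE = {"Physician": "physician",
                  "Other health-professional": "other_health_professional",
                  "Pharmacist": "pharmacist", "Consumer": "consumer",
                  "Unknown": "unknown"}
_OUTCOME_CODE = {"Death": "DE", "Life-threatening": "LT",
                 "Hospitalization": "HO", "Disability": "DS",
                 "Congenital anomaly": "CA", "Other": "OT", "Unknown": None}


def _expand(section_counts, mapping) -> list:
    values = []
    for category, count in section_counts:
        values.extend([mapping[category]] * count)
    return values


def reports_from_counts(counts: dict) -> list:
    """Expand a demographic count table into synthetic CaseReport marginals."""
    n = counts["n"]
    for section in ("Gender", "Age", "Weight", "Reporter", "Country", "Outcome"):
        total = sum(c for _, c in counts[section])
        if total != n:
            raise ValueError(f"{section} counts sum to {total}, expected {n}")

    genders = _expand(counts["Gender"], _GENDER_CODE)
    ages = _expand(counts["Age"], _AGE_VALUE)
    weights = _expand(counts["Weight"], _WEIGHT_VALUE)
    reporters = _expand(counts["Reporter"], _REPORTER_CODE)
    countries = _expand(counts["Country"],
                        {"United States": "US", "Other country": "JP"})
    outcomes = _expand(counts["Outcome"], _OUTCOME_CODE)

    date = FaersDate(raw="20230101", date=None, year=2023)
    reports = []
    for i in range(n):
        reports.append(CaseReport(
            primaryid=str(i + 1), caseid=str(i + 1), fda_dt=date,
            gender=genders[i], age_years=ages[i], weight_kg=weights[i],
            reporter=reporters[i], country=countries[i],
            outcomes=frozenset() if outcomes[i] is None else frozenset({outcomes[i]}),
        ))
    return reports
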