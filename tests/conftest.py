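import datetime as dt

import pytest

from pvsignal.faers import (CaseReport, DrugEntry, FaersDate, ReactionEntry,
                            normalize_drug_name)


def make_date(s: str) -> FaersDate:
    from pvsignal.faers import parse_faers_date
    return parse_faers_date(s)


def make_report(primaryid="1", caseid=None, fda="20230101", gender="M",
                age=None, weight=None, reporter="physician", country="US",
                outcomes=(), drugs=(), reactions=()):
    """Terse CaseReport builder; drugs as (name, role[, start]) tuples,
    reactions as pt strings or (pt, event_dt) tuples."""
    drug_entries = []
    for d in drugs:
        name, role = d[0], d[1]
        start = make_date(d[2]) if len(d) > 2 else None
        drug_entries.append(DrugEntry(name=normalize_drug_name(name),
                                      role=role, start_dt=start))
    reaction_entries = []
    for r in reactions:
        if isinstance(r, str):
            reaction_entries.append(ReactionEntry(pt=r))
        else:
            reaction_entries.append(ReactionEntry(pt=r[0], event_dt=make_date(r[1])))
    return CaseReport(
        primaryid=str(primaryid), caseid=str(caseid or primaryid),
        fda_dt=make_date(fda), gender=gender, age_years=age, weight_kg=weight,
        reporter=reporter, country=country, outcomes=frozenset(outcomes),
        drugs=drug_entries, reactions=reaction_entries)


@pytest.fixture
def four_report_store():
    """Four deduplicated reports, one PT each, for pair-count enumeration."""
    return [
        make_report("1", drugs=[("drugx", "PS")], reactions=["PT1"]),
        make_report("2", drugs=[("drugx", "PS")], reactions=["PT2"]),
        make_report("3", drugs=[("drugy", "PS")], reactions=["PT1"]),
        make_report("4", drugs=[("drugy", "PS")], reactions=["PT3"]),
    ]


def write_faers_files(tmpdir, demo_rows, drug_rows=(), reac_rows=(),
                      ther_rows=(), outc_rows=(), demo_header=None):
    """Write a minimal five-table FAERS fixture; returns the path map."""
    header = demo_header or ("primaryid$caseid$fda_dt$sex$age$age_cod$wt$"
                             "wt_cod$occp_cod$reporter_country")
    paths = {}
    specs = {
        "demo": (header, demo_rows),
        "drug": ("primaryid$drugname$role_cod", drug_rows),
        "reac": ("primaryid$pt$event_dt", reac_rows),
        "ther": ("primaryid$start_dt", ther_rows),
        "outc": ("primaryid$outc_cod", outc_rows),
    }
    for name, (head, rows) in specs.items():
        p = tmpdir / f"{name.upper()}.txt"
        p.write_text("\n".join([head, *rows]) + "\n")
        paths[name] = p
    return paths
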