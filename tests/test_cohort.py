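"""Cohort derivation: ICD classification, severity hierarchy, diagnosis-date
modes, rolling periods and period subcohorts."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifeyears.cohort import (ClassificationError, DataConsistencyError,
                              Period, build_cohort, classify_cause,
                              classify_smi, period_subcohort, rolling_periods)

# ---------------------------------------------------------------------------
# cause-of-death classification
# ---------------------------------------------------------------------------

SUICIDE = (["X60", "X70", "X84", "Y10", "Y25", "Y34", "Y87.0", "Y87.2", "X609"])
ACCIDENT = (["V01", "V02", "W00", "X00", "X59", "Y85", "Y86"])
OTHER_EXT = (["Y40", "Y62", "Y84", "X85", "X99", "Y00", "Y09", "Y87.1",
              "Y88", "Y89"])
NATURAL = (["I21", "A00", "C34", "F03", "J44", "R99", "Y35", "Y39", "Y90",
            "V00", "U07", "Y87"])


@pytest.mark.parametrize("code,expected", (
    [(c, ("unnatural", "suicide")) for c in SUICIDE]
    + [(c, ("unnatural", "accident")) for c in ACCIDENT]
    + [(c, ("unnatural", "other_external")) for c in OTHER_EXT]
    + [(c, ("natural", "natural")) for c in NATURAL]
))
def test_classify_cause_boundaries(code, expected):
    assert classify_cause(code) == expected


def test_classify_cause_missing_is_natural():
    assert classify_cause(None) == ("natural", "natural")
    assert classify_cause("") == ("natural", "natural")
    assert classify_cause(float("nan")) == ("natural", "natural")


def test_classify_cause_malformed_raises():
    for bad in ("123", "X", "!X60", "9A1"):
        with pytest.raises(ClassificationError):
            classify_cause(bad)


@given(st.sampled_from("VWXY"), st.integers(0, 99), st.integers(0, 9))
@settings(max_examples=200, deadline=None)
def test_classify_cause_total_and_dot_insensitive(letter, num, sub):
    """Every well-formed external-cause code classifies, identically with
    or without the dot, and lands in exactly one of the two groups."""
    code = f"{letter}{num:02d}.{sub}"
    group, detail = classify_cause(code)
    assert classify_cause(code.replace(".", "")) == (group, detail)
    assert (group == "natural") == (detail == "natural")
    assert group in ("natural", "unnatural")


# ---------------------------------------------------------------------------
# SMI classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("code,system,expected", [
    ("F20", "ICD10", "schizophrenia"), ("F25", "ICD10", "schizophrenia"),
    ("F20.0", "ICD10", "schizophrenia"), ("F259", "ICD10", "schizophrenia"),
    ("F30", "ICD10", "bipolar"), ("F31.9", "ICD10", "bipolar"),
    ("F32", "ICD10", "depression"), ("F33.2", "ICD10", "depression"),
    ("F23", "ICD10", None), ("F34", "ICD10", None), ("F29", "ICD10", None),
    ("295.0", "ICD9", "schizophrenia"), ("295.3", "ICD9", "schizophrenia"),
    ("295.6", "ICD9", "schizophrenia"), ("295.9", "ICD9", "schizophrenia"),
    ("295.4", "ICD9", None), ("295.5", "ICD9", None), ("295", "ICD9", None),
    ("296.0", "ICD9", "bipolar"), ("296.2", "ICD9", "bipolar"),
    ("296.6", "ICD9", "bipolar"), ("296.7", "ICD9", None),
    ("296.1", "ICD9", "depression"), ("298.0", "ICD9", "depression"),
    ("300.4", "ICD9", "depression"), ("311", "ICD9", "depression"),
    ("311.0", "ICD9", "depression"), ("298.1", "ICD9", None),
    ("300.0", "ICD9", None), ("F20", "ICD9", None),
])
def test_classify_smi(code, system, expected):
    assert classify_smi(code, system) == expected


# ---------------------------------------------------------------------------
# rolling periods
# ---------------------------------------------------------------------------

def test_rolling_periods_paper_window():
    periods = rolling_periods(2000, 2017)
    assert len(periods) == 18
    assert periods[0].start_date == date(2000, 1, 1)
    assert periods[0].end_date == date(2002, 12, 31)
    assert periods[-1].start_date == date(2017, 1, 1)
    assert periods[-1].end_date == date(2019, 12, 31)


def test_rolling_periods_degenerate_and_errors():
    assert len(rolling_periods(2000, 2000)) == 1
    assert len(rolling_periods(2005, 2007)) == 3
    with pytest.raises(ValueError):
        rolling_periods(2010, 2009)


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def _adm(pid, when, dx, system="ICD10", birth="1960-01-01", sex="male"):
    row = {"person_id": pid, "admission_date": when, "sex": sex,
           "birth_date": birth, "code_system": system, "deprivation": 3}
    for i, code in enumerate(dx if isinstance(dx, list) else [dx], 1):
        row[f"dx{i}"] = code
    for i in range(1, 7):
        row.setdefault(f"dx{i}", None)
    return row


def _deaths(rows):
    return pd.DataFrame(rows, columns=["person_id", "death_date",
                                       "underlying_cause"])


def test_hierarchy_and_diagnosis_date_modes():
    """Depression-then-schizophrenia is schizophrenia; the diagnosis date is
    the first SMI record in first_any_smi mode and the first schizophrenia
    record in the sensitivity mode."""
    adm = pd.DataFrame([
        _adm("p1", "1995-03-01", "F32"),
        _adm("p1", "2005-06-01", "F20"),
    ])
    a = build_cohort(adm, _deaths([]), date(2000, 1, 1), "first_any_smi")
    assert a.loc[0, "smi"] == "schizophrenia"
    assert a.loc[0, "diagnosis_date"] == pd.Timestamp("1995-03-01")
    b = build_cohort(adm, _deaths([]), date(2000, 1, 1),
                     "first_of_most_severe")
    assert b.loc[0, "smi"] == "schizophrenia"
    assert b.loc[0, "diagnosis_date"] == pd.Timestamp("2005-06-01")


def test_hierarchy_idempotent_under_extra_depression():
    """Adding a later depression admission to a schizophrenia case changes
    neither the category nor the most-severe diagnosis date."""
    base = [_adm("p1", "2001-01-01", "F32"), _adm("p1", "2003-05-01", "F20")]
    extra = base + [_adm("p1", "2010-01-01", "F33")]
    for mode in ("first_any_smi", "first_of_most_severe"):
        x = build_cohort(pd.DataFrame(base), _deaths([]), date(2000, 1, 1), mode)
        y = build_cohort(pd.DataFrame(extra), _deaths([]), date(2000, 1, 1), mode)
        assert x.loc[0, "smi"] == y.loc[0, "smi"] == "schizophrenia"
        assert x.loc[0, "diagnosis_date"] == y.loc[0, "diagnosis_date"]


def test_non_smi_only_person_excluded():
    adm = pd.DataFrame([_adm("p1", "2001-01-01", "F41")])
    assert build_cohort(adm, _deaths([]), date(2000, 1, 1)).empty


def test_multiple_codes_on_one_admission():
    adm = pd.DataFrame([_adm("p1", "2001-01-01", ["F41", "F31", "F33"])])
    c = build_cohort(adm, _deaths([]), date(2000, 1, 1))
    assert c.loc[0, "smi"] == "bipolar"


def test_dead_before_study_start_excluded_and_causes_attached():
    adm = pd.DataFrame([_adm("p1", "1990-01-01", "F20"),
                        _adm("p2", "1990-01-01", "F20")])
    deaths = _deaths([("p1", "1999-06-01", "I21"),
                      ("p2", "2005-06-01", "X70")])
    c = build_cohort(adm, deaths, date(2000, 1, 1))
    assert list(c["person_id"]) == ["p2"]
    assert c.loc[0, "death_cause"] == "unnatural"
    assert c.loc[0, "death_cause_detail"] == "suicide"


def test_death_before_any_admission_is_inconsistent():
    adm = pd.DataFrame([_adm("p1", "2001-01-01", "F20")])
    with pytest.raises(DataConsistencyError):
        build_cohort(adm, _deaths([("p1", "2000-06-01", "I21")]),
                     date(2000, 1, 1))


def test_unknown_person_in_deaths_ignored(caplog):
    adm = pd.DataFrame([_adm("p1", "2001-01-01", "F20")])
    c = build_cohort(adm, _deaths([("ghost", "2005-01-01", "I21")]),
                     date(2000, 1, 1))
    assert len(c) == 1 and pd.isna(c.loc[0, "death_date"])


def test_onset_age_int_floor_and_clamp():
    adm = pd.DataFrame([_adm("p1", "2010-08-01", "F20", birth="1960-01-01"),
                        _adm("p2", "2010-08-01", "F20", birth="1910-01-01")])
    c = build_cohort(adm, _deaths([]), date(2000, 1, 1))
    c = c.set_index("person_id")
    assert c.loc["p1", "onset_age_int"] == 50  # 50.58 floors to 50
    assert c.loc["p2", "onset_age_int"] == 94  # clamped to the grid


# ---------------------------------------------------------------------------
# period subcohorts
# ---------------------------------------------------------------------------

def _cohort_df(rows):
    df = pd.DataFrame(rows, columns=["person_id", "smi", "sex",
                                     "diagnosis_date", "birth_date",
                                     "death_date", "death_cause"])
    for c in ("diagnosis_date", "birth_date", "death_date"):
        df[c] = pd.to_datetime(df[c])
    df["death_cause_detail"] = None
    df["onset_age_int"] = np.clip(
        ((df["diagnosis_date"] - df["birth_date"]).dt.days // 365.25
         ).astype(int), 18, 94)
    return df


def test_prevalent_member_enters_at_period_start():
    coh = _cohort_df([("p1", "depression", "male", "1990-01-01",
                       "1950-01-01", None, None)])
    iv = period_subcohort(coh, Period(2000))
    assert len(iv) == 1
    assert iv.loc[0, "entry_age"] == pytest.approx(50.0, abs=0.01)
    assert iv.loc[0, "exit_age"] == pytest.approx(53.0, abs=0.01)
    assert iv.loc[0, "event"] == "censored"


def test_incident_member_enters_at_diagnosis_and_dies():
    coh = _cohort_df([("p1", "depression", "male", "2001-06-01",
                       "1961-01-05", "2002-02-01", "natural")])
    iv = period_subcohort(coh, Period(2000))
    assert iv.loc[0, "entry_age"] == pytest.approx(40.4, abs=0.02)
    assert iv.loc[0, "exit_age"] == pytest.approx(41.07, abs=0.02)
    assert iv.loc[0, "event"] == "death_natural"


def test_not_alive_at_period_start_excluded():
    coh = _cohort_df([("p1", "depression", "male", "1980-01-01",
                       "1950-01-01", "1999-06-01", "natural")])
    assert period_subcohort(coh, Period(2000)).empty


def test_death_on_period_boundary_belongs_to_period():
    coh = _cohort_df([("p1", "depression", "male", "1990-01-01",
                       "1950-01-01", "2002-12-31", "natural")])
    iv = period_subcohort(coh, Period(2000))
    assert iv.loc[0, "event"] == "death_natural"


def test_age_95_truncation():
    coh = _cohort_df([
        # age 96 at period start: excluded
        ("p1", "depression", "male", "1990-01-01", "1904-01-01", None, None),
        # turns 95 mid-period, dies after the cap: censored at 95
        ("p2", "depression", "male", "1990-01-01", "1906-06-01",
         "2002-06-01", "natural")])
    iv = period_subcohort(coh, Period(2000))
    assert list(iv["person_id"]) == ["p2"]
    assert iv.loc[0, "exit_age"] == pytest.approx(95.0)
    assert iv.loc[0, "event"] == "censored"


def test_subcohort_counts_monotone_after_last_diagnosis():
    """Once no new diagnoses can enter, successive period subcohorts can
    only shrink (deaths remove members, nobody arrives)."""
    rng = np.random.default_rng(4)
    rows = []
    for i in range(300):
        dyear = rng.integers(1985, 2000)
        byear = dyear - rng.integers(20, 60)
        dead = rng.random() < 0.6
        death = f"{rng.integers(2000, 2020)}-06-15" if dead else None
        rows.append((f"p{i}", "depression", "male", f"{dyear}-03-01",
                     f"{byear}-01-01", death, "natural" if dead else None))
    coh = _cohort_df(rows)
    counts = [len(period_subcohort(coh, Period(y))) for y in range(2000, 2018)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_death_event_exit_age_matches_death_date():
    coh = _cohort_df([("p1", "depression", "female", "1995-01-01",
                       "1940-07-01", "2001-03-15", "natural")])
    iv = period_subcohort(coh, Period(2000))
    expect = (pd.Timestamp("2001-03-15") - pd.Timestamp("1940-07-01")).days / 365.25
    assert iv.loc[0, "exit_age"] == pytest.approx(expect, abs=1e-9)
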