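"""Cohort derivation from psychiatric hospital admissions and death records.

Builds a severe-mental-illness (SMI) cohort from registry-shaped admission
records carrying up to six ICD-9/ICD-10 discharge diagnoses, applies the
severity hierarchy schizophrenia > bipolar > depression, classifies causes
of death into natural/unnatural per the ICD-10 external-cause ranges, and
slices the cohort into rolling 3-year period subcohorts of follow-up
intervals on the age timescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
MAX_AGE = 95.0
MIN_ADULT_AGE = 18

#: severity hierarchy; higher wins when one person has several SMI diagnoses
SEVERITY = {"schizophrenia": 3, "bipolar": 2, "depression": 1}

EVENT_CENSORED = "censored"
EVENT_NATURAL = "death_natural"
EVENT_UNNATURAL = "death_unnatural"


class ClassificationError(ValueError):
    """Raised for a malformed ICD-10 cause-of-death code."""


class DataConsistencyError(ValueError):
    """Raised when linked records contradict each other (e.g. death precedes
    every admission of the same person)."""


def _norm(code: object) -> str:
    return str(code).replace(".", "").replace(" ", "").strip().upper()


# ---------------------------------------------------------------------------
# cause-of-death classification (ICD-10 underlying cause)
# ---------------------------------------------------------------------------

# 4-character special cases: sequelae of intentional self-harm / undetermined
# intent count as suicide, sequelae of assault as other external.
_FOUR_CHAR = {"Y870": ("unnatural", "suicide"),
              "Y872": ("unnatural", "suicide"),
              "Y871": ("unnatural", "other_external")}

_SUICIDE_RANGES = [("X60", "X84"), ("Y10", "Y34")]
_ACCIDENT_RANGES = [("V01", "X59"), ("Y85", "Y86")]
_OTHER_EXTERNAL_RANGES = [("Y40", "Y84"), ("X85", "Y09"), ("Y88", "Y89")]


def classify_cause(code: object) -> tuple[str, str]:
    """Classify an ICD-10 underlying cause of death.

    Returns ``(group, detail)`` where group is ``natural``/``unnatural`` and
    detail one of ``suicide`` (incl. self-harm and undetermined intent),
    ``accident``, ``other_external`` or ``natural``. A missing/empty code is
    natural; a present but malformed code raises :class:`ClassificationError`.
    Dots are permitted ("Y87.0" == "Y870").
    """
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return ("natural", "natural")
    c = _norm(code)
    if not c or c == "NAN":  # empty / pandas NaN rendered as text
        return ("natural", "natural")
    if len(c) < 3 or not c[0].isalpha() or not c[1:3].isdigit():
        raise ClassificationError(f"malformed ICD-10 code: {code!r}")
    if c[:4] in _FOUR_CHAR:
        return _FOUR_CHAR[c[:4]]
    c3 = c[:3]
    for lo, hi in _SUICIDE_RANGES:
        if lo <= c3 <= hi:
            return ("unnatural", "suicide")
    for lo, hi in _ACCIDENT_RANGES:
        if lo <= c3 <= hi:
            return ("unnatural", "accident")
    for lo, hi in _OTHER_EXTERNAL_RANGES:
        if lo <= c3 <= hi:
            return ("unnatural", "other_external")
    return ("natural", "natural")


# ---------------------------------------------------------------------------
# SMI diagnosis classification
# ---------------------------------------------------------------------------

_ICD10_SMI = {
    "F20": "schizophrenia", "F25": "schizophrenia",
    "F30": "bipolar", "F31": "bipolar",
    "F32": "depression", "F33": "depression",
}
# ICD-9: 295.0-295.3, 295.6-295.9 schizophrenia; 296.0, 296.2-296.6 bipolar;
# 296.1, 298.0, 300.4, 311 depression. Four-digit prefixes after dot removal.
_ICD9_SMI = {}
for _d in (0, 1, 2, 3, 6, 7, 8, 9):
    _ICD9_SMI[f"295{_d}"] = "schizophrenia"
for _d in (0, 2, 3, 4, 5, 6):
    _ICD9_SMI[f"296{_d}"] = "bipolar"
_ICD9_SMI["2961"] = "depression"
_ICD9_SMI["2980"] = "depression"
_ICD9_SMI["3004"] = "depression"


def classify_smi(code: object, system: str) -> str | None:
    """Map a diagnosis code to an SMI category, or None if not an SMI.

    ``system`` is ``"ICD9"`` or ``"ICD10"``. Matching is by normalised prefix
    (dots stripped, upper-cased) so registry codes with 4th/5th characters
    match: "F251" -> schizophrenia, "2953X" -> schizophrenia.
    """
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return None
    c = _norm(code)
    if not c or c == "NAN":
        return None
    system = system.upper().replace("-", "")
    if system == "ICD10":
        return _ICD10_SMI.get(c[:3])
    if system == "ICD9":
        hit = _ICD9_SMI.get(c[:4])
        if hit:
            return hit
        if c[:3] == "311":
            return "depression"
        return None
    raise ValueError(f"unknown code system: {system!r}")


# ---------------------------------------------------------------------------
# rolling 3-year periods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Period:
    """A 3-calendar-year analysis window starting 1 Jan of ``index_year``."""

    index_year: int

    @property
    def start_date(self) -> date:
        return date(self.index_year, 1, 1)

    @property
    def end_date(self) -> date:
        return date(self.index_year + 2, 12, 31)

    @property
    def label(self) -> str:
        return f"{self.index_year}-{self.index_year + 2}"


def rolling_periods(first_index_year: int, last_index_year: int) -> list[Period]:
    """Overlapping 3-year periods, one per index year (inclusive)."""
    if first_index_year > last_index_year:
        raise ValueError("first_index_year must be <= last_index_year")
    return [Period(y) for y in range(first_index_year, last_index_year + 1)]


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

_DX_COLS = [f"dx{i}" for i in range(1, 7)]


def _age_years(at: pd.Series, birth: pd.Series) -> pd.Series:
    """Continuous age in decimal years, actuarial 365.25-day convention."""
    return (at - birth).dt.days / DAYS_PER_YEAR


def build_cohort(admissions: pd.DataFrame, deaths: pd.DataFrame,
                 study_start: date = date(2000, 1, 1),
                 diagnosis_date_mode: str = "first_any_smi") -> pd.DataFrame:
    """Derive the SMI cohort: one row per person with at least one SMI
    admission who is alive on ``study_start``.

    ``diagnosis_date_mode``:

    * ``first_any_smi`` — date of the first admission with any SMI code,
      irrespective of condition (primary analysis).
    * ``first_of_most_severe`` — earliest admission carrying a code of the
      person's most severe SMI (sensitivity analysis).

    Admission rows need columns person_id, admission_date, sex, birth_date,
    dx1..dx6, code_system and optionally deprivation. Death rows need
    person_id, death_date, underlying_cause. Returns a DataFrame with columns
    person_id, sex, smi, diagnosis_date, birth_date, onset_age_int,
    death_date, death_cause, death_cause_detail, deprivation.
    """
    if diagnosis_date_mode not in ("first_any_smi", "first_of_most_severe"):
        raise ValueError(f"unknown diagnosis_date_mode {diagnosis_date_mode!r}")
    adm = admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])
    adm["birth_date"] = pd.to_datetime(adm["birth_date"])

    dx_cols = [c for c in _DX_COLS if c in adm.columns]
    if not dx_cols:
        raise ValueError("admissions must carry diagnosis columns dx1..dx6")

    # severity of the most severe SMI code on each admission row
    sev = np.zeros(len(adm), dtype=int)
    for c in dx_cols:
        cats = [classify_smi(v, s) for v, s in zip(adm[c], adm["code_system"])]
        sev = np.maximum(sev, [SEVERITY.get(k, 0) if k else 0 for k in cats])
    adm["_sev"] = sev
    smi_adm = adm[adm["_sev"] > 0].copy()

    # adult cohort: ignore SMI admissions before age 18
    age_at_adm = _age_years(smi_adm["admission_date"], smi_adm["birth_date"])
    under = age_at_adm < MIN_ADULT_AGE
    if under.any():
        log.warning("ignoring %d SMI admissions before age 18", int(under.sum()))
        smi_adm = smi_adm[~under]
    if smi_adm.empty:
        return _empty_cohort()

    grp = smi_adm.groupby("person_id", sort=True)
    person_sev = grp["_sev"].max()
    first_any = grp["admission_date"].min()
    # earliest admission carrying the person's most severe SMI
    top = smi_adm[smi_adm["_sev"] == smi_adm["person_id"].map(person_sev)]
    first_severe = top.groupby("person_id")["admission_date"].min()

    inv_sev = {v: k for k, v in SEVERITY.items()}
    out = pd.DataFrame({
        "person_id": person_sev.index,
        "smi": person_sev.map(inv_sev).values,
        "diagnosis_date": (first_any if diagnosis_date_mode == "first_any_smi"
                           else first_severe).reindex(person_sev.index).values,
    })
    firsts = grp.first()
    out["sex"] = firsts["sex"].values
    out["birth_date"] = firsts["birth_date"].values
    out["deprivation"] = (firsts["deprivation"].values
                          if "deprivation" in firsts.columns else np.nan)

    # attach deaths
    d = deaths.copy()
    if len(d):
        d["death_date"] = pd.to_datetime(d["death_date"])
        known = d["person_id"].isin(adm["person_id"])
        if (~known).any():
            log.warning("ignoring %d death records for persons with no "
                        "admission", int((~known).sum()))
        d = d[known]
        first_adm_all = adm.groupby("person_id")["admission_date"].min()
        bad = d["death_date"].values < first_adm_all.reindex(d["person_id"]).values
        if bad.any():
            pid = d.loc[bad, "person_id"].iloc[0]
            raise DataConsistencyError(
                f"death precedes every admission for person {pid!r}")
        if d["person_id"].duplicated().any():
            raise DataConsistencyError("multiple death records for one person")
    out = out.merge(d[["person_id", "death_date", "underlying_cause"]]
                    if len(d) else
                    pd.DataFrame(columns=["person_id", "death_date",
                                          "underlying_cause"]),
                    on="person_id", how="left")
    out["death_date"] = pd.to_datetime(out["death_date"])

    causes = [classify_cause(c) if pd.notna(dd) else (None, None)
              for c, dd in zip(out["underlying_cause"], out["death_date"])]
    out["death_cause"] = [c[0] for c in causes]
    out["death_cause_detail"] = [c[1] for c in causes]
    out = out.drop(columns=["underlying_cause"])

    # alive on study start
    start_ts = pd.Timestamp(study_start)
    dead_before = out["death_date"].notna() & (out["death_date"] < start_ts)
    if dead_before.any():
        log.info("excluding %d persons who died before %s",
                 int(dead_before.sum()), study_start)
    out = out[~dead_before].reset_index(drop=True)

    onset_age = _age_years(out["diagnosis_date"], out["birth_date"])
    out["onset_age_int"] = np.clip(np.floor(onset_age).astype(int),
                                   MIN_ADULT_AGE, 94)
    return out


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(columns=["person_id", "smi", "diagnosis_date", "sex",
                                 "birth_date", "deprivation", "death_date",
                                 "death_cause", "death_cause_detail",
                                 "onset_age_int"])


# ---------------------------------------------------------------------------
# period subcohorts of follow-up intervals
# ---------------------------------------------------------------------------

def period_subcohort(cohort: pd.DataFrame, period: Period,
                     max_age: float = MAX_AGE) -> pd.DataFrame:
    """Follow-up intervals (entry_age, exit_age, event) for one 3-year period.

    Membership: alive at the period start, first SMI diagnosis on or before
    the period end. Prevalent members (diagnosed before the period) enter at
    their age on 1 Jan of the index year; incident members enter at their age
    at diagnosis. Exit is at death within the period (event classified by
    cause) or at the age on 31 Dec of the final year (censored). Deaths on the
    period end date belong to the period. Ages past ``max_age`` are truncated:
    entry >= max_age excludes the person, exit is capped at max_age with the
    event forced to censored.
    """
    if cohort.empty:
        return _empty_intervals()
    start = pd.Timestamp(period.start_date)
    end = pd.Timestamp(period.end_date)
    c = cohort
    alive_at_start = c["death_date"].isna() | (c["death_date"] >= start)
    diagnosed = pd.to_datetime(c["diagnosis_date"]) <= end
    c = cohort[alive_at_start & diagnosed].copy()
    if c.empty:
        return _empty_intervals()

    entry_date = pd.to_datetime(c["diagnosis_date"]).clip(lower=start)
    birth = pd.to_datetime(c["birth_date"])
    entry_age = _age_years(entry_date, birth)

    died_in = c["death_date"].notna() & (c["death_date"] <= end)
    exit_date = pd.to_datetime(c["death_date"]).where(died_in, end)
    exit_age = _age_years(exit_date, birth)
    event = np.where(
        died_in,
        np.where(c["death_cause"].eq("unnatural"), EVENT_UNNATURAL,
                 EVENT_NATURAL),
        EVENT_CENSORED)

    # age-95 truncation
    over = exit_age > max_age
    exit_age = exit_age.where(~over, max_age)
    event = np.where(over, EVENT_CENSORED, event)

    iv = pd.DataFrame({
        "person_id": c["person_id"].values,
        "entry_age": entry_age.values,
        "exit_age": exit_age.values,
        "event": event,
        "onset_age_int": c["onset_age_int"].values,
        "smi": c["smi"].values,
        "sex": c["sex"].values,
    })
    keep = (iv["entry_age"] < max_age) & (iv["exit_age"] > iv["entry_age"])
    if (~keep).any():
        log.info("period %s: dropped %d degenerate intervals (entry >= %.0f "
                 "or exit <= entry)", period.label, int((~keep).sum()), max_age)
    return iv[keep].reset_index(drop=True)


def _empty_intervals() -> pd.DataFrame:
    return pd.DataFrame(columns=["person_id", "entry_age", "exit_age",
                                 "event", "onset_age_int", "smi", "sex"])
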