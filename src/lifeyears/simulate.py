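"""Synthetic registry generator with closed-form ground truth.

Emits admission and death records shaped like a psychiatric hospital
discharge register linked to national death registrations, plus matching
reference life tables, under a known piecewise-exponential competing-risks
mortality model. Because event times come from inverse-transform sampling
of piecewise-constant natural/unnatural hazards, every quantity the
estimation pipeline produces has an analytic oracle (:func:`analytic_lyl`).

What is emulated: an onset-age distribution over 18–94, diagnosis calendar
years spanning 1981–2019 (so both prevalent and incident cases exist at any
study start), ICD-9 coding before April 1996 and ICD-10 after, an optional
earlier less-severe admission (exercising the severity hierarchy and the
two diagnosis-date modes), cause-coded deaths including deaths before the
study start, and multiplicative calendar-period hazard factors for trend
scenarios. Not emulated: coding noise, readmissions, emigration,
deprivation gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .cohort import DAYS_PER_YEAR

_ICD10_POOL = {"schizophrenia": ["F20.0", "F25"],
               "bipolar": ["F31.1", "F30"],
               "depression": ["F32.2", "F33"]}
_ICD9_POOL = {"schizophrenia": ["295.1", "295.7"],
              "bipolar": ["296.0", "296.4"],
              "depression": ["296.1", "311"]}
_NON_SMI_CODES = ["F41.1", "F10.2", "G40"]  # present but never qualifying
_NATURAL_CAUSES = ["I21", "I25.1", "C34", "J44.0", "I64"]
_UNNATURAL_CAUSES = ["X70", "X61", "Y25", "V03.1", "W13", "Y87.0"]
_ICD9_CUTOVER = date(1996, 4, 1)
_MAX_SIM_AGE = 120.0


@dataclass
class HazardSpec:
    """Piecewise-constant cause-specific hazards on the age axis.

    ``natural[i]``/``unnatural[i]`` apply on [``ages[i]``, ``ages[i+1]``),
    the last piece extending indefinitely. Rates are per person-year.
    """

    ages: list = field(default_factory=lambda: [0.0])
    natural: list = field(default_factory=lambda: [0.02])
    unnatural: list = field(default_factory=lambda: [0.005])

    def __post_init__(self) -> None:
        if not (len(self.ages) == len(self.natural) == len(self.unnatural)):
            raise ValueError("ages, natural, unnatural must share a length")
        if any(r < 0 for r in self.natural + self.unnatural):
            raise ValueError("hazard rates must be non-negative")
        if list(self.ages) != sorted(self.ages):
            raise ValueError("age breakpoints must be sorted")

    def rates_at(self, age: float) -> tuple[float, float]:
        i = int(np.searchsorted(self.ages, age, side="right") - 1)
        i = max(i, 0)
        return float(self.natural[i]), float(self.unnatural[i])


@dataclass
class CalendarEffect:
    """Multiplicative hazard factors applying from 1 Jan ``from_year`` on."""

    from_year: int
    natural: float = 1.0
    unnatural: float = 1.0


@dataclass
class SimulationConfig:
    """Scenario definition; defaults mirror a realistic national SMI
    register (stratum mix 24.4% schizophrenia / 14.1% bipolar / 61.5%
    depression)."""

    n_individuals: int = 1000
    seed: int = 0
    sex_mix: dict = field(default_factory=lambda: {"male": 0.5, "female": 0.5})
    smi_mix: dict = field(default_factory=lambda: {
        "schizophrenia": 0.244, "bipolar": 0.141, "depression": 0.615})
    #: truncated log-normal onset age on [18, 94]: exp(N(log(median), sigma))
    onset: dict = field(default_factory=lambda: {
        "kind": "lognormal", "median": 38.0, "sigma": 0.45})
    diagnosis_years: dict = field(default_factory=lambda: {
        "start": 1981, "end": 2019})
    #: hazards keyed "default" or "smi:sex"
    hazards: dict = field(default_factory=lambda: {"default": HazardSpec()})
    calendar_effects: list = field(default_factory=list)
    #: probability that a schizophrenia/bipolar case has an earlier
    #: depression admission (exercises hierarchy + diagnosis-date modes)
    prob_prior_less_severe: float = 0.0
    #: extra persons whose only admission carries no SMI code
    n_non_smi: int = 0
    study_start_year: int = 2000
    study_end_year: int = 2019

    def __post_init__(self) -> None:
        for mix in (self.sex_mix, self.smi_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
        self.hazards = {k: (v if isinstance(v, HazardSpec) else HazardSpec(**v))
                        for k, v in self.hazards.items()}
        self.calendar_effects = [
            c if isinstance(c, CalendarEffect) else CalendarEffect(**c)
            for c in self.calendar_effects]
        self.calendar_effects.sort(key=lambda c: c.from_year)

    def hazard_for(self, smi: str, sex: str) -> HazardSpec:
        return self.hazards.get(f"{smi}:{sex}", self.hazards["default"])

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "n_individuals": self.n_individuals, "seed": self.seed,
            "sex_mix": dict(self.sex_mix), "smi_mix": dict(self.smi_mix),
            "onset": dict(self.onset),
            "diagnosis_years": dict(self.diagnosis_years),
            "hazards": {k: {"ages": list(map(float, v.ages)),
                            "natural": list(map(float, v.natural)),
                            "unnatural": list(map(float, v.unnatural))}
                        for k, v in self.hazards.items()},
            "calendar_effects": [{"from_year": c.from_year,
                                  "natural": c.natural,
                                  "unnatural": c.unnatural}
                                 for c in self.calendar_effects],
            "prob_prior_less_severe": self.prob_prior_less_severe,
            "n_non_smi": self.n_non_smi,
            "study_start_year": self.study_start_year,
            "study_end_year": self.study_end_year,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _draw_categorical(rng: np.random.Generator, mix: dict, n: int) -> np.ndarray:
    keys = list(mix.keys())
    return rng.choice(keys, size=n, p=[mix[k] for k in keys])

def _draw_onset_ages(rng: np.random.Generator, spec: dict, n: int) -> np.ndarray:
    kind = spec.get("kind", "lognormal")
    if kind == "lognormal":
        mu, sigma = np.log(spec["median"]), spec["sigma"]
        out = np.empty(n)
        filled = 0
        while filled < n:  # rejection sampling onto [18, 94]
            draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
            ok = draw[(draw >= 18.0) & (draw < 94.0)]
            take = min(len(ok), n - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out
    if kind == "empirical":
        ages = np.array(sorted(spec["weights"]), dtype=float)
        w = np.array([spec["weights"][a] for a in sorted(spec["weights"])],
                     dtype=float)
        idx = rng.choice(len(ages), size=n, p=w / w.sum())
        return ages[idx] + rng.random(n)  # uniform within the year of age
    if kind == "fixed":
        return np.full(n, float(spec["age"])) + rng.random(n) * spec.get(
            "jitter", 0.0)
    raise ValueError(f"unknown onset spec kind {kind!r}")


def _calendar_factors(effects: list, year: float) -> tuple[float, float]:
    fn = fu = 1.0
    for e in effects:
        if year >= e.from_year:
            fn, fu = e.natural, e.unnatural
    return fn, fu


def sample_death(onset_age: float, birth_year: float, spec: HazardSpec,
                 effects: list, rng: np.random.Generator):
    """Inverse-transform draw of (death_age, cause) from the competing
    piecewise-exponential model, starting at onset_age conditional on being
    alive there. Returns (None, None) for survival past age 120.

    ``birth_year`` is the birth date in fractional calendar years, used to
    translate calendar-effect boundaries onto the age axis.
    """
    knots = {onset_age, _MAX_SIM_AGE}
    knots.update(a for a in spec.ages if onset_age < a < _MAX_SIM_AGE)
    for e in effects:
        a = e.from_year - birth_year
        if onset_age < a < _MAX_SIM_AGE:
            knots.add(a)
    knots = sorted(knots)
    target = rng.exponential()
    cum = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        ln, lu = spec.rates_at(lo)
        fn, fu = _calendar_factors(effects, birth_year + lo)
        ln, lu = ln * fn, lu * fu
        lam = ln + lu
        seg = lam * (hi - lo)
        if cum + seg >= target:
            t = lo + (target - cum) / lam
            cause = "unnatural" if rng.random() < lu / lam else "natural"
            return t, cause
        cum += seg
    return None, None


def _to_date(year_frac: float) -> date:
    return date(1800, 1, 1) + timedelta(
        days=round((year_frac - 1800.0) * DAYS_PER_YEAR))


def _smi_code(smi: str, when: date, rng: np.random.Generator,
              icd9_era: bool = True) -> tuple[str, str]:
    if icd9_era and when < _ICD9_CUTOVER:
        return rng.choice(_ICD9_POOL[smi]), "ICD9"
    return rng.choice(_ICD10_POOL[smi]), "ICD10"


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (admissions, deaths) record tables for one scenario.

    Deaths occurring before the study start are still emitted — excluding
    them is the cohort builder's job. Identical seeds give byte-identical
    tables (PCG64 generator).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    sexes = _draw_categorical(rng, config.sex_mix, n)
    smis = _draw_categorical(rng, config.smi_mix, n)
    onset_ages = _draw_onset_ages(rng, config.onset, n)
    y0, y1 = config.diagnosis_years["start"], config.diagnosis_years["end"]
    diag_years = y0 + rng.random(n) * (y1 + 1 - y0)

    adm_rows, death_rows = [], []
    for i in range(n):
        pid = f"P{i:06d}"
        sex, smi, a0 = sexes[i], smis[i], float(onset_ages[i])
        diag_year = float(diag_years[i])
        birth_year = diag_year - a0
        diag_date = _to_date(diag_year)
        birth_date = _to_date(birth_year)

        if (smi in ("schizophrenia", "bipolar")
                and rng.random() < config.prob_prior_less_severe):
            gap = 0.5 + rng.random() * 4.5
            if a0 - gap >= 18.5:
                d = _to_date(diag_year - gap)
                code, system = _smi_code("depression", d, rng)
                adm_rows.append((pid, d.isoformat(), sex,
                                 birth_date.isoformat(), code, system))

        code, system = _smi_code(smi, diag_date, rng)
        adm_rows.append((pid, diag_date.isoformat(), sex,
                         birth_date.isoformat(), code, system))

        spec = config.hazard_for(smi, sex)
        t_death, cause = sample_death(a0, birth_year, spec,
                                      config.calendar_effects, rng)
        if t_death is not None:
            pool = (_UNNATURAL_CAUSES if cause == "unnatural"
                    else _NATURAL_CAUSES)
            death_rows.append((pid, _to_date(birth_year + t_death).isoformat(),
                               rng.choice(pool)))

    for j in range(config.n_non_smi):
        pid = f"N{j:06d}"
        sex = _draw_categorical(rng, config.sex_mix, 1)[0]
        a = 18.0 + rng.random() * 60.0
        year = y0 + rng.random() * (y1 + 1 - y0)
        d = _to_date(year)
        adm_rows.append((pid, d.isoformat(), sex,
                         _to_date(year - a).isoformat(),
                         rng.choice(_NON_SMI_CODES), "ICD10"))

    admissions = pd.DataFrame(adm_rows, columns=[
        "person_id", "admission_date", "sex", "birth_date", "dx1",
        "code_system"])
    for c in ("dx2", "dx3", "dx4", "dx5", "dx6"):
        admissions[c] = ""
    admissions["deprivation"] = rng.integers(1, 6, size=len(admissions))
    admissions = admissions[["person_id", "admission_date", "sex",
                             "birth_date", "dx1", "dx2", "dx3", "dx4", "dx5",
                             "dx6", "code_system", "deprivation"]]
    deaths = pd.DataFrame(death_rows, columns=["person_id", "death_date",
                                               "underlying_cause"])
    return admissions, deaths


def simulate_life_table(spec: HazardSpec, sexes=("male", "female"),
                        periods=("all",), calendar_effects: list | None = None,
                        max_age: int = 100) -> pd.DataFrame:
    """Reference life table rows from a hazard spec.

    q_x = 1 - exp(-integral of the total hazard over [x, x+1)), with any
    calendar factor evaluated at each period's index year; l_x follows by
    the survivorship recursion from l_0 = 100 000.
    """
    effects = calendar_effects or []
    rows = []
    for period in periods:
        try:
            idx_year = int(str(period).split("-")[0])
        except ValueError:
            idx_year = None
        for sex in sexes:
            lx = 100_000.0
            for x in range(0, max_age + 1):
                # hazard may break within the year; integrate piecewise
                sub = [x, x + 1] + [a for a in spec.ages if x < a < x + 1]
                sub.sort()
                h = 0.0
                for lo, hi in zip(sub[:-1], sub[1:]):
                    ln, lu = spec.rates_at(lo)
                    if idx_year is not None:
                        fn, fu = _calendar_factors(effects, idx_year)
                        ln, lu = ln * fn, lu * fu
                    h += (ln + lu) * (hi - lo)
                qx = 1.0 - np.exp(-h)
                rows.append({"age": x, "sex": sex, "period": period,
                             "lx": lx, "qx": qx})
                lx *= 1.0 - qx
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Closed-form LYL for one onset age under a hazard spec."""

    onset_age: float
    total: float
    natural: float
    unnatural: float
    tau: float


def analytic_lyl(spec: HazardSpec, onset_age: float,
                 tau: float = 95.0) -> GroundTruth:
    """Exact LYL under the piecewise-exponential model, conditional on
    being alive at ``onset_age``.

    Per constant-hazard piece [t0, t1) with rates (ln, lu), lam = ln + lu:
    survival decays exponentially, the cause-k incidence gains
    (lam_k/lam) * (S(t0) - S(t1)), and both integrate in closed form. For a
    single piece this reduces to
    LYL = (tau - a) - (1 - exp(-lam (tau - a))) / lam with the cause split
    proportional to lam_k / lam.
    """
    knots = sorted({onset_age, tau, *[a for a in spec.ages
                                      if onset_age < a < tau]})
    S = 1.0
    cif_n = cif_u = 0.0
    int_s = int_cn = int_cu = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        ln, lu = spec.rates_at(lo)
        lam = ln + lu
        dt = hi - lo
        if lam == 0.0:
            seg_s = S * dt
            S_end = S
        else:
            decay = np.exp(-lam * dt)
            seg_s = S * (1.0 - decay) / lam
            S_end = S * decay
        int_s += seg_s
        drop = S - S_end
        for lam_k, cif, acc in ((ln, cif_n, "n"), (lu, cif_u, "u")):
            share = lam_k / lam if lam > 0 else 0.0
            seg = cif * dt + share * (S * dt - seg_s)
            if acc == "n":
                int_cn += seg
                cif_n = cif + share * drop
            else:
                int_cu += seg
                cif_u = cif + share * drop
        S = S_end
    span = tau - onset_age
    return GroundTruth(onset_age=onset_age, total=span - int_s,
                       natural=int_cn, unnatural=int_cu, tau=tau)
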