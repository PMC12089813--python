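"""Life Years Lost (LYL) with competing-risks decomposition.

For onset age a and horizon tau (default 95), LYL(a) is the gap between the
full span tau - a and the restricted mean residual lifetime:

    LYL(a) = (tau - a) - int_a^tau S(t | a) dt
           = int_a^tau [CIF_nat(t | a) + CIF_unnat(t | a)] dt

where S and the cause-specific cumulative incidences are conditioned on
survival to a. The decomposition into natural and unnatural causes is exact
because S + CIF_nat + CIF_unnat = 1 pointwise for the product-limit /
Aalen–Johansen pair. Cohort-level LYL is the weighted average of LYL(a) over
the onset-age distribution of the ENTIRE cohort (held fixed across periods
and bootstrap replicates so that trends reflect survival change only).

Conditioning uses the ratio form of a single overall fit,
S(t|a) = S(t)/S(a) and CIF_k(t|a) = (CIF_k(t) - CIF_k(a))/S(a), which under
the entry < t <= exit risk-set convention is identical to refitting the
estimator from age a.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Period, period_subcohort, MIN_ADULT_AGE, MAX_AGE
from .survival import (EmptyRiskSetError, _as_arrays, _fit, aalen_johansen,
                       integrate_step, km_estimate)

log = logging.getLogger(__name__)

AGE_GRID = np.arange(MIN_ADULT_AGE, 95)  # integer onset ages 18..94


@dataclass
class AgeSpecificLYL:
    """Total and per-cause life-years lost for one onset age."""

    onset_age: int
    total: float
    natural: float
    unnatural: float
    max_age: float = MAX_AGE


@dataclass
class OnsetDistribution:
    """Probability weights over integer onset ages 18..94 (sum to 1)."""

    weights: np.ndarray  # aligned with AGE_GRID

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != AGE_GRID.shape:
            raise ValueError(f"weights must cover ages {AGE_GRID[0]}..{AGE_GRID[-1]}")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"weights must sum to 1 (got {s})")
        self.weights = w

    @classmethod
    def from_ages(cls, onset_ages: np.ndarray) -> "OnsetDistribution":
        ages = np.asarray(onset_ages, dtype=int)
        if len(ages) == 0:
            raise ValueError("no onset ages given")
        counts = np.bincount(np.clip(ages, AGE_GRID[0], AGE_GRID[-1])
                             - AGE_GRID[0], minlength=len(AGE_GRID))
        return cls(counts / counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=AGE_GRID, name="weight")


@dataclass
class LYLResult:
    """Cohort-level LYL for one SMI x sex x period stratum."""

    smi: str
    sex: str
    period: str
    total: float
    natural: float
    unnatural: float
    ci: dict = field(default_factory=dict)  # component -> (low, high)
    n_individuals: int = 0
    n_deaths: int = 0
    bootstrap_reps: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# vectorised per-age profile from a single fit
# ---------------------------------------------------------------------------

def _right_integrals(times: np.ndarray, vals_after: np.ndarray,
                     start: float, tau: float, start_val: float):
    """Right cumulative integrals int_x^tau of a step function with value
    ``start_val`` on [start, times[0]) and ``vals_after[j]`` after times[j].
    Returns (edges, seg_vals, rc) with rc[i] = integral from edges[i] to tau.
    """
    edges = np.concatenate([[start], times, [tau]])
    seg_vals = np.concatenate([[start_val], vals_after])
    seg_len = np.diff(edges)
    contrib = seg_vals * seg_len
    rc = np.concatenate([np.cumsum(contrib[::-1])[::-1], [0.0]])
    return edges, seg_vals, rc


def _eval_and_tail(edges, seg_vals, rc, ages):
    """Value at each age and integral from that age to tau."""
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1,
                  0, len(seg_vals) - 1)
    val = seg_vals[idx]
    tail = rc[idx + 1] + seg_vals[idx] * (edges[idx + 1] - ages)
    return val, tail


def lyl_profile(intervals: pd.DataFrame, ages: np.ndarray = AGE_GRID,
                tau: float = MAX_AGE) -> pd.DataFrame:
    """LYL(a) with cause decomposition for each onset age, from one fit.

    Returns a DataFrame indexed by age with columns total, natural,
    unnatural, estimable. An age is estimable when someone is at risk just
    after it (n(a) = #{entry <= a < exit} > 0) and S(a) > 0; inestimable
    ages carry NaN.
    """
    entry, exit_, ecode = _as_arrays(intervals)
    ages = np.asarray(ages, dtype=float)
    from_age = float(min(entry.min(), ages.min()))
    times, surv, cif_nat, cif_unnat = _fit(entry, exit_, ecode, from_age, tau)

    eS, vS, rS = _right_integrals(times, surv, from_age, tau, 1.0)
    eN, vN, rN = _right_integrals(times, cif_nat, from_age, tau, 0.0)
    eU, vU, rU = _right_integrals(times, cif_unnat, from_age, tau, 0.0)

    s_a, tail_s = _eval_and_tail(eS, vS, rS, ages)
    cn_a, tail_n = _eval_and_tail(eN, vN, rN, ages)
    cu_a, tail_u = _eval_and_tail(eU, vU, rU, ages)

    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    n_after = (np.searchsorted(entry_sorted, ages, side="right")
               - np.searchsorted(exit_sorted, ages, side="right"))
    estimable = (n_after > 0) & (s_a > 0) & (ages < tau)

    span = tau - ages
    with np.errstate(divide="ignore", invalid="ignore"):
        total = span - tail_s / s_a
        natural = (tail_n - cn_a * span) / s_a
        unnatural = (tail_u - cu_a * span) / s_a
    total[~estimable] = np.nan
    natural[~estimable] = np.nan
    unnatural[~estimable] = np.nan
    return pd.DataFrame({"total": total, "natural": natural,
                         "unnatural": unnatural, "estimable": estimable},
                        index=ages.astype(int) if np.allclose(ages % 1, 0)
                        else ages)


def lyl_at_age(intervals: pd.DataFrame, onset_age: int,
               max_age: float = MAX_AGE) -> AgeSpecificLYL:
    """LYL at a single onset age, by direct refit from that age.

    Equivalent to the ratio-form conditioning used by :func:`lyl_profile`;
    kept as the transparent reference path.
    """
    a = float(onset_age)
    surv = km_estimate(intervals, a, max_age)
    cifs = aalen_johansen(intervals, a, max_age)
    rmst = integrate_step(surv, a, max_age)
    nat = integrate_step(cifs["natural"], a, max_age)
    unnat = integrate_step(cifs["unnatural"], a, max_age)
    return AgeSpecificLYL(onset_age=int(onset_age),
                          total=(max_age - a) - rmst,
                          natural=nat, unnatural=unnat, max_age=max_age)


# ---------------------------------------------------------------------------
# onset weighting, bootstrap, trend
# ---------------------------------------------------------------------------

def onset_distribution(cohort: pd.DataFrame, smi: str,
                       sex: str) -> OnsetDistribution:
    """Empirical onset-age distribution for one stratum over the ENTIRE
    cohort (not a period subcohort)."""
    sel = cohort[(cohort["smi"] == smi) & (cohort["sex"] == sex)]
    if sel.empty:
        raise ValueError(f"empty stratum smi={smi!r} sex={sex!r}")
    return OnsetDistribution.from_ages(sel["onset_age_int"].to_numpy())


def weighted_lyl(per_age: pd.DataFrame,
                 dist: OnsetDistribution) -> dict[str, float]:
    """Weighted average of per-age LYL over the onset distribution.

    ``per_age`` is a :func:`lyl_profile` frame. Ages with positive weight
    but no estimate are dropped and the weights renormalised (logged).
    """
    w = dist.weights.copy()
    est = per_age["estimable"].to_numpy(dtype=bool)
    usable = est & (w > 0)
    if not usable.any():
        raise ValueError("no estimable onset age carries positive weight")
    dropped = (~est) & (w > 0)
    if dropped.any():
        log.debug("renormalising onset weights: %d inestimable ages "
                  "(weight %.4f)", int(dropped.sum()), float(w[dropped].sum()))
    w = np.where(usable, w, 0.0)
    w = w / w.sum()
    return {k: float(np.nansum(per_age[k].to_numpy() * w))
            for k in ("total", "natural", "unnatural")}


def _weighted_point(intervals: pd.DataFrame, dist: OnsetDistribution,
                    tau: float) -> dict[str, float]:
    return weighted_lyl(lyl_profile(intervals, AGE_GRID, tau), dist)


def bootstrap_ci(intervals: pd.DataFrame, dist: OnsetDistribution,
                 B: int = 500, seed: int | np.random.SeedSequence = 0,
                 tau: float = MAX_AGE,
                 return_replicates: bool = False):
    """Percentile bootstrap CIs for total/natural/unnatural weighted LYL.

    Individuals (whole follow-up intervals) are resampled with replacement;
    the onset distribution stays fixed. Returns component -> (low, high),
    plus the replicate table when ``return_replicates``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    base = intervals.reset_index(drop=True)
    n = len(base)
    reps = {"total": np.empty(B), "natural": np.empty(B),
            "unnatural": np.empty(B)}
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            pt = _weighted_point(base.iloc[idx], dist, tau)
        except (EmptyRiskSetError, ValueError):
            pt = {k: np.nan for k in reps}
        for k in reps:
            reps[k][b] = pt[k]
    ci = {k: (float(np.nanpercentile(v, 2.5)),
              float(np.nanpercentile(v, 97.5))) for k, v in reps.items()}
    if return_replicates:
        return ci, pd.DataFrame(reps)
    return ci


def lyl_trend(cohort: pd.DataFrame, periods: list[Period], B: int = 500,
              seed: int = 0, tau: float = MAX_AGE,
              strata: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Rolling-period LYL trend, one row per stratum x period x component.

    For every SMI x sex stratum and period: build the period subcohort,
    compute the onset-weighted LYL with natural/unnatural decomposition
    using the whole-cohort onset distribution, and attach percentile
    bootstrap CIs (B replicates). Sub-seeds are derived deterministically
    per stratum and period from ``seed``. Returns a tidy table with columns
    smi, sex, period_start, component, estimate, ci_low, ci_high, n,
    n_deaths.
    """
    if strata is None:
        strata = sorted({(r.smi, r.sex) for r in
                         cohort[["smi", "sex"]].drop_duplicates().itertuples()})
    rows = []
    for si, (smi, sex) in enumerate(strata):
        dist = onset_distribution(cohort, smi, sex)
        sub_cohort = cohort[(cohort["smi"] == smi) & (cohort["sex"] == sex)]
        for pi, period in enumerate(periods):
            iv = period_subcohort(sub_cohort, period, max_age=tau)
            n = len(iv)
            n_deaths = int((iv["event"] != "censored").sum()) if n else 0
            rec = {"smi": smi, "sex": sex, "period_start": period.index_year,
                   "n": n, "n_deaths": n_deaths}
            try:
                point = _weighted_point(iv, dist, tau)
                ss = np.random.SeedSequence([int(seed), si, pi])
                ci = (bootstrap_ci(iv, dist, B=B, seed=ss, tau=tau)
                      if B > 0 else {k: (np.nan, np.nan) for k in point})
            except (EmptyRiskSetError, ValueError):
                log.warning("stratum %s/%s period %s: no estimate",
                            smi, sex, period.label)
                point = {k: np.nan for k in ("total", "natural", "unnatural")}
                ci = {k: (np.nan, np.nan) for k in point}
            for comp in ("total", "natural", "unnatural"):
                rows.append({**rec, "component": comp,
                             "estimate": point[comp],
                             "ci_low": ci[comp][0], "ci_high": ci[comp][1]})
    return pd.DataFrame(rows)
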