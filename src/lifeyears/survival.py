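"""Nonparametric estimation on the age timescale with delayed entry.

Product-limit (Kaplan–Meier) survival and Aalen–Johansen cause-specific
cumulative incidence, both with left truncation (individuals enter the risk
set at their entry age), plus exact integration of the resulting step
functions — the backbone of restricted-mean life-years-lost computation.

Conventions
-----------
* Risk set at age t counts intervals with entry_age < t <= exit_age, so a
  late entrant at exactly a death age is not at risk for that death and a
  censoring at exactly a death age is.
* Tied deaths are aggregated; deaths precede censorings at the same age.
* All step functions are right-continuous; over an age span with an empty
  risk set the last value is carried forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EVENT_CENSORED, EVENT_NATURAL, EVENT_UNNATURAL

log = logging.getLogger(__name__)

_EVENT_CODE = {EVENT_CENSORED: 0, EVENT_NATURAL: 1, EVENT_UNNATURAL: 2}


class EmptyRiskSetError(ValueError):
    """No follow-up interval overlaps the requested age window."""


class DegenerateConditioningError(ValueError):
    """Attempt to condition a survival curve on an age where S = 0."""


@dataclass
class StepSurvival:
    """Right-continuous step function for S(t) or a cumulative incidence.

    ``values[i]`` is the function value on ``[jump_ages[i], jump_ages[i+1])``
    (the last segment extends to ``domain_end``). ``jump_ages[0]`` equals
    ``domain_start``.
    """

    jump_ages: np.ndarray
    values: np.ndarray
    domain_start: float
    domain_end: float
    kind: str = "survival"

    def __post_init__(self) -> None:
        self.jump_ages = np.asarray(self.jump_ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_ages.shape != self.values.shape:
            raise ValueError("jump_ages and values must align")

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        """Evaluate at age(s) t (right-continuous)."""
        idx = np.searchsorted(self.jump_ages, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        out = self.values[idx]
        return float(out) if np.isscalar(t) else out

    def to_frame(self) -> pd.DataFrame:
        """Two-column (age, value) table, e.g. for plotting survival curves."""
        return pd.DataFrame({"age": self.jump_ages, "value": self.values})


def _event_codes(event: np.ndarray | pd.Series) -> np.ndarray:
    arr = np.asarray(event)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array([_EVENT_CODE[e] for e in arr], dtype=np.int64)


def _as_arrays(intervals: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    entry = np.asarray(intervals["entry_age"], dtype=float)
    exit_ = np.asarray(intervals["exit_age"], dtype=float)
    ecode = _event_codes(intervals["event"])
    return entry, exit_, ecode


def risk_table(entry: np.ndarray, exit_: np.ndarray, ecode: np.ndarray,
               from_age: float, to_age: float):
    """Distinct death ages in (from_age, to_age] with at-risk and death
    counts by cause. Returns (times, n_at_risk, d_natural, d_unnatural)."""
    overlap = (exit_ > from_age) & (entry < to_age)
    if not overlap.any():
        raise EmptyRiskSetError(
            f"no follow-up interval overlaps ({from_age}, {to_age}]")
    death = (ecode > 0) & (exit_ > from_age) & (exit_ <= to_age)
    t = exit_[death]
    times, inv = np.unique(t, return_inverse=True)
    if len(times):
        d_nat = np.bincount(inv, weights=(ecode[death] == 1).astype(float),
                            minlength=len(times))
        d_unnat = np.bincount(inv, weights=(ecode[death] == 2).astype(float),
                              minlength=len(times))
    else:
        d_nat = d_unnat = np.zeros(0)
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    # at risk at t: entered strictly before t, not yet exited before t
    n_at = (np.searchsorted(entry_sorted, times, side="left")
            - np.searchsorted(exit_sorted, times, side="left"))
    return times, n_at.astype(float), d_nat, d_unnat


def _fit(entry, exit_, ecode, from_age, to_age):
    times, n_at, d_nat, d_unnat = risk_table(entry, exit_, ecode,
                                             from_age, to_age)
    d = d_nat + d_unnat
    surv = np.cumprod(1.0 - d / n_at) if len(times) else np.zeros(0)
    s_minus = np.concatenate([[1.0], surv[:-1]]) if len(times) else np.zeros(0)
    cif_nat = np.cumsum(s_minus * d_nat / n_at) if len(times) else np.zeros(0)
    cif_unnat = np.cumsum(s_minus * d_unnat / n_at) if len(times) else np.zeros(0)
    return times, surv, cif_nat, cif_unnat


def km_estimate(intervals: pd.DataFrame, from_age: float,
                to_age: float) -> StepSurvival:
    """Kaplan–Meier survival with delayed entry on (from_age, to_age].

    S(from_age) = 1; at each distinct death age t, S is multiplied by
    1 - d(t)/n(t) with n(t) the left-truncated risk set.
    """
    if not from_age < to_age:
        raise ValueError("from_age must be < to_age")
    entry, exit_, ecode = _as_arrays(intervals)
    times, surv, _, _ = _fit(entry, exit_, ecode, from_age, to_age)
    return StepSurvival(np.concatenate([[from_age], times]),
                        np.concatenate([[1.0], surv]),
                        from_age, to_age, kind="survival")


def aalen_johansen(intervals: pd.DataFrame, from_age: float,
                   to_age: float) -> dict[str, StepSurvival]:
    """Aalen–Johansen cumulative incidence for natural and unnatural death.

    CIF_k(t) = sum over death ages u <= t of S(u-) d_k(u)/n(u). Together with
    the Kaplan–Meier survival the identity S + CIF_nat + CIF_unnat = 1 holds
    at every age (only deaths remove individuals).
    """
    if not from_age < to_age:
        raise ValueError("from_age must be < to_age")
    entry, exit_, ecode = _as_arrays(intervals)
    times, _, cif_nat, cif_unnat = _fit(entry, exit_, ecode, from_age, to_age)
    ages = np.concatenate([[from_age], times])
    return {
        "natural": StepSurvival(ages, np.concatenate([[0.0], cif_nat]),
                                from_age, to_age, kind="cumulative_incidence"),
        "unnatural": StepSurvival(ages, np.concatenate([[0.0], cif_unnat]),
                                  from_age, to_age, kind="cumulative_incidence"),
    }


def integrate_step(curve: StepSurvival, a: float, b: float) -> float:
    """Exact integral of a step function over [a, b] (no quadrature error)."""
    if a > b:
        raise ValueError("a must be <= b")
    tol = 1e-9
    if a < curve.domain_start - tol or b > curve.domain_end + tol:
        raise ValueError(
            f"[{a}, {b}] outside curve domain "
            f"[{curve.domain_start}, {curve.domain_end}]")
    edges = np.concatenate([curve.jump_ages, [curve.domain_end]])
    lo = np.clip(edges[:-1], a, b)
    hi = np.clip(edges[1:], a, b)
    return float(np.dot(curve.values, hi - lo))


def conditional_survival(curve: StepSurvival, a: float) -> StepSurvival:
    """Survival conditioned on being alive at age a: t -> S(t)/S(a) on
    [a, domain_end]."""
    if curve.kind != "survival":
        raise ValueError("conditioning requires a survival-kind curve")
    s_a = curve(a)
    if s_a <= 0.0:
        raise DegenerateConditioningError(f"S({a}) = 0")
    keep = curve.jump_ages > a
    ages = np.concatenate([[a], curve.jump_ages[keep]])
    vals = np.concatenate([[s_a], curve.values[keep]]) / s_a
    return StepSurvival(ages, vals, a, curve.domain_end, kind="survival")
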