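import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def three_person_intervals() -> pd.DataFrame:
    """Hand-checkable instance: A dies (natural) at 20, B censored at 25,
    C dies (unnatural) at 24, all entering at 18.

    Product-limit by hand: S(20) = 2/3 (risk set {A,B,C}),
    S(24) = 2/3 * 1/2 = 1/3 (risk set {B,C}). Aalen-Johansen:
    CIF_nat(26) = 1 * 1/3, CIF_unnat(26) = 2/3 * 1/2 = 1/3.
    """
    return pd.DataFrame({
        "person_id": ["A", "B", "C"],
        "entry_age": [18.0, 18.0, 18.0],
        "exit_age": [20.0, 25.0, 24.0],
        "event": ["death_natural", "censored", "death_unnatural"],
        "onset_age_int": [18, 18, 18],
    })


def exponential_intervals(n: int, onset: float, lam_natural: float,
                          lam_unnatural: float = 0.0, tau: float = 95.0,
                          seed: int = 0) -> pd.DataFrame:
    """Cohort with constant competing hazards from a common onset age,
    administratively censored at tau — the closed-form oracle's sampling
    counterpart."""
    rng = np.random.default_rng(seed)
    lam = lam_natural + lam_unnatural
    t = onset + rng.exponential(1.0 / lam, n)
    unnat = rng.random(n) < lam_unnatural / lam
    event = np.where(t >= tau, "censored",
                     np.where(unnat, "death_unnatural", "death_natural"))
    return pd.DataFrame({
        "person_id": [f"P{i}" for i in range(n)],
        "entry_age": np.full(n, float(onset)),
        "exit_age": np.minimum(t, tau),
        "event": event,
        "onset_age_int": int(onset),
    })


def brute_force_km(entry, exit_, event_is_death, from_age, to_age):
    """Independent product-limit oracle: explicit loop over death ages with
    risk sets counted from the definition entry < t <= exit."""
    deaths = sorted({x for x, d in zip(exit_, event_is_death)
                     if d and from_age < x <= to_age})
    s = 1.0
    out = {}
    for t in deaths:
        n_at = sum(1 for e, x in zip(entry, exit_) if e < t <= x)
        d = sum(1 for x, dd in zip(exit_, event_is_death)
                if dd and x == t)
        s *= 1.0 - d / n_at
        out[t] = s
    return out


def brute_force_cif(entry, exit_, ecode, from_age, to_age):
    """Independent Aalen-Johansen oracle, cause codes 1/2."""
    deaths = sorted({x for x, k in zip(exit_, ecode)
                     if k > 0 and from_age < x <= to_age})
    s = 1.0
    cif = {1: 0.0, 2: 0.0}
    path = {}
    for t in deaths:
        n_at = sum(1 for e, x in zip(entry, exit_) if e < t <= x)
        dk = {k: sum(1 for x, kk in zip(exit_, ecode) if kk == k and x == t)
              for k in (1, 2)}
        for k in (1, 2):
            cif[k] += s * dk[k] / n_at
        s *= 1.0 - (dk[1] + dk[2]) / n_at
        path[t] = (s, cif[1], cif[2])
    return path
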