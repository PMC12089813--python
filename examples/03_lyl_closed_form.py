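"""Life Years Lost at a single onset age, checked against the closed form.

Under a constant all-cause hazard lambda the LYL before age 95 for onset
age a is (95 - a) - (1 - exp(-lambda (95 - a))) / lambda. The estimator
recovers it from 20 000 simulated lifetimes.
"""

import numpy as np
import pandas as pd

from lifeyears import HazardSpec, analytic_lyl, lyl_at_age

lam, a, n = 0.05, 35, 20_000
rng = np.random.default_rng(1)
t = a + rng.exponential(1 / lam, n)
intervals = pd.DataFrame({
    "entry_age": np.full(n, float(a)),
    "exit_age": np.minimum(t, 95.0),
    "event": np.where(t < 95, "death_natural", "censored"),
    "onset_age_int": a})

est = lyl_at_age(intervals, a)
truth = analytic_lyl(HazardSpec(ages=[0.0], natural=[lam],
                                unnatural=[0.0]), a).total
print(f"estimated LYL({a}) = {est.total:.3f} years")
print(f"closed form        = {truth:.3f} years")
print(f"difference         = {est.total - truth:+.3f} (Monte-Carlo noise)")
print("Interpretation: a person diagnosed at 35 under this mortality loses "
      f"about {truth:.0f} of the {95 - a} years remaining to the age-95 "
      "horizon.")
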