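"""How long does a mutant HSC clone take to expand?

A single mutant arises in the blood, attaches to a niche, and competes
with the host population.  The reduced one-dimensional diffusion gives the
probability that the clone reaches a target clonality and the mean and SD
of the conditional waiting time.
"""

from hscniche import mouse_observables
from hscniche.diffusion import (conditional_time_moments, fixation_probability,
                                neutral_expansion_time, required_advantage,
                                summary_from_observables)
from hscniche.parameters import DAYS_PER_YEAR

obs = mouse_observables(s_star=100.0, ell_minutes=3.0)

# Neutral clone, 1% clonality, across the observable range
for s_star, ell in ((1.0, 5.0), (100.0, 1.0)):
    o = mouse_observables(s_star, ell)
    s = summary_from_observables(o, epsilon=0.0, dose=1.0, sigma=0.01)
    print(f"neutral clone to 1% (s*={s_star:g}, ell={ell:g} min): "
          f"{neutral_expansion_time(s) / DAYS_PER_YEAR:5.1f} years")

# A dose of 8 donor cells with a 10% division advantage
s8 = summary_from_observables(obs, epsilon=0.1, dose=8.0, sigma=1.0)
phi = fixation_probability(s8)
T, sd = conditional_time_moments(s8)
print(f"dose 8, eps=0.1: P(takeover) = {phi:.3f}, "
      f"time = {T / DAYS_PER_YEAR:.1f} +/- {sd / DAYS_PER_YEAR:.1f} years")

# Required division advantage for fixed two-year horizons
two_years = 2 * DAYS_PER_YEAR
print(f"fold advantage for takeover in 2 y:  "
      f"{required_advantage(two_years, 1.0, 1.0, obs):.2f}")
print(f"fold advantage for 1% in 2 y:        "
      f"{required_advantage(two_years, 0.01, 1.0, obs):.2f}")

# Expected: a neutral clone needs ~5-45 years just to reach 1%, so clones
# observed within a mouse lifetime almost certainly carry an advantage;
# even 8 advantaged cells need ~16 years to take over completely.
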