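"""Deduce the unmeasured model rates from steady-state observables.

Murine observations pin down five quantities: N = 10,000 niches, n* = 9,900
occupied, a blood pool of s* = 1-100 HSCs, a division rate of 1/39 per day,
and a blood residence time of 1-5 minutes.  The model's remaining rates
(blood death delta, detachment d, attachment a) follow from the steady
state, and with them the daily marrow<->blood flux and the mean time a cell
stays in its niche.
"""

from hscniche import blood_flux, deduce_rates
from hscniche.parameters import mouse_grid

print(f"{'s*':>5} {'ell(min)':>8} {'delta/d':>10} {'d/d':>10} {'a/d':>12} "
      f"{'flux/day':>10} {'niche residency':>16}")
for obs in mouse_grid():
    p = deduce_rates(obs)
    f = blood_flux(obs)
    print(f"{obs.s_star:5g} {obs.ell_minutes:8g} {p.delta1:10.4g} "
          f"{p.d1:10.4g} {p.a1:12.5g} {f.flux_per_day:10.0f} "
          f"{f.bm_residency_days:13.3g} d")

# The flux column shows that even a tiny blood pool (s* = 1) turns over
# more than a thousand HSCs per day, while niche residency spans two hours
# (s*=100, ell=1) to nearly a year (s*=1, ell=5): the same observables are
# compatible with very different migration regimes.
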