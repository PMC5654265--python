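"""Can a single donor HSC rebuild a conditioned host?

After myeloablative conditioning the marrow is empty.  An injected donor
cell either dies in the blood or attaches, and once attached it can still
detach and face the same race again.  Accounting for every
detach/reattach/divide combination gives a closed-form success
probability, checked here against stochastic simulation.
"""

from hscniche import deduce_rates
from hscniche.gillespie import reconstitution_mc
from hscniche.parameters import mouse_grid
from hscniche.transplant import (reconstitution_first_order,
                                 reconstitution_full)

print(f"{'s*':>5} {'ell(min)':>8} {'first-order':>12} {'full':>8} "
      f"{'simulated (95% CI)':>22}")
for obs in mouse_grid():
    params = deduce_rates(obs)
    naive = reconstitution_first_order(1, params)
    full = reconstitution_full(1, params)
    ens = reconstitution_mc(1, params, reps=1_000, seed=42)
    lo, hi = ens.ci()
    print(f"{obs.s_star:5g} {obs.ell_minutes:8g} {naive:12.4f} {full:8.4f} "
          f"{ens.estimate:8.3f} ({lo:.3f}-{hi:.3f})")

# Expected: the full (branching) formula lands inside every simulation CI,
# while the first-order formula overestimates wherever detachment matters;
# a single cell suffices in ~92-100% of cases across the observable grid.
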