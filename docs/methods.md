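# Methods

## Model

Two compartments: a bone marrow of `N` niches, each holding at most one
HSC, and an unbounded peripheral-blood pool. State is the count vector
(n₁, s₁, n₂, s₂) for the host (1) and mutant/donor (2) populations. Events
and propensities (all rates per day):

- division: βᵢ nᵢ — a niche-resident divides; the daughter enters a free
  niche with probability ρᵢ·1[n < N] (default ρ = 0) or is ejected into
  the blood;
- blood death: δᵢ sᵢ;
- in-niche death: δ′ᵢ nᵢ, parameterised as δ′ = α δ (default α = 0);
- detachment: dᵢ nᵢ (niche → blood);
- attachment: aᵢ sᵢ (N − n)/N (blood → free niche), n = n₁ + n₂.

The default configuration (α = ρ = 0, all rates equal across species
except β₂ = (1 + ε)β) is the one all analytics address; the simulator
additionally accepts per-species values of every rate, so selection on
parameters other than β can be explored numerically.

Assumptions worth stating: HSCs divide only in niches; blood and marrow
are each well mixed (no spatial structure); chimerism/clonality is the
HSC fraction in the marrow, used as a proxy for mature-cell chimerism;
the host is at demographic steady state except where an experiment
(transplant, conditioning) says otherwise.

## Parameters

Measurable steady-state observables and their murine defaults:

| symbol | meaning | default | unit |
|---|---|---|---|
| N | total niches | 10,000 | — |
| n\* | occupied niches | 9,900 | — |
| s\* | blood HSC pool | 1–100 (grid) | cells |
| β | division rate | 1/39 | per day |
| ℓ | blood residence time | 1–5 (grid) | minutes |

The unmeasured rates follow from the single-species steady state:
δ = β n\*/s\*, d = s\*/(ℓ n\*) − β, a = (1/ℓ − β n\*/s\*)·N/(N − n\*),
with ℓ converted to days (ℓ/1440). These obey a(N − n\*)/N + δ = 1/ℓ
exactly — the blood exit rate decomposes into attachment and death. The
literature ranges for s\* and ℓ are treated as a discrete 3×2 grid of
scenarios, not as an uncertainty distribution. Observables with
s\*/(ℓ n\*) ≤ β imply d ≤ 0 and are rejected as an invalid regime.

Human-scale presets: β = 1/40 per week, ℓ = 60 minutes, s\* = 0.01 N,
n\* = 0.99 N — a tenfold slow-down of the murine timescales matching the
division-rate scaling. Unit conventions throughout: rates per day, one
year = 365 days.

## Deterministic dynamics and transplant regimes

The rate equations for (n₁, s₁, n₂, s₂) are integrated with LSODA and an
analytic Jacobian (relative tolerance 1e-9 by default; the rates span
~1e-3 to 1e5 per day, so a stiff-capable solver is required). For a dose S
injected into the blood of a host at equilibrium:

- small doses (S ≪ N − n\*): each cell independently attaches before dying
  with probability a(N−n\*)/N / (δ + a(N−n\*)/N) = 1 − βℓ n\*/s\*, so the
  expected engrafted count is that fraction times S;
- large doses (S ≳ N − n\*): the marrow is treated as full from t = 0; the
  total blood pool follows ṡ = βN − δs (closed form), and the donor counts
  obey linear equations in which attachment happens only at the
  detachment-replacement flux dN, split by blood composition s₂/s.

Both approximations are validated against full integration; their error is
below 1% outside the cross-over region S ≈ N − n\*, where neither regime's
assumption (constant free-niche pool / saturated marrow) holds. The
signed error of the saturated form crosses zero within the saturated range,
so its magnitude is small but not strictly monotone in the dose.

Dose schedules are handled as impulsive increments of s₂ between exact
integrations. The chimerism read-out time ("end of the initial phase") is
defined as the first time the total blood pool is within 1% of s\* while
|dn₂/dt| < 1e-6 n\* per day, and can be overridden with a fixed time.

## Clonal expansion analytics

A system-size expansion in N followed by projection onto the slow
direction reduces the model to one SDE for the mutant niche fraction
z ∈ [0, ξ], ξ = n\*/N:

    dz = (ΛB/N) z(ξ − z) dt + sqrt(2 B z(ξ − z)/N) dW,

with Λ = εN(1 + s\*/n\* − βℓ) (dimensionless drift-to-diffusion ratio,
linear in ε) and B = (βN/s\*)(s\*/n\* − βℓ)/(1 + s\*/n\* − βℓ)² (per day).
Both constants are also computed directly from (β, δ, d); the two forms
agree to 1e-12 and are asserted in the tests. The derivation assumes weak
selection (0 ≤ ε ≪ 1); calling the timing functions with ε ≥ ~1 emits a
warning rather than refusing.

Hitting probability of clonality σ from initial fraction z₀:
φ = (1 − e^{−Λz₀})/(1 − e^{−Λσξ}), evaluated through expm1 so the neutral
limit z₀/(σξ) and very large |Λ| are exact. z₀ is continuous — for a dose
it is the expected attachment count divided by N; simulation comparisons
round the dose, never z₀.

The conditional mean time solves θ″ + Λθ′ = −(N/B)φ(z)/(z(ξ − z)) with
θ(0) = θ(σξ) = 0 and T = θ/φ. Variation of parameters gives the closed
integral form

    T(z₀) = ∫₀^{σξ} f(u) g(σξ−u) du − φ(z₀)^{-1} ∫₀^{z₀} f(u) g(z₀−u) du,

f(u) = (N/B)φ(u)/(u(ξ−u)), g(w) = (1 − e^{−Λw})/Λ. The apparent endpoint
singularities cancel analytically (φ(u)/u is finite at 0; at u = σξ = ξ
the g factor cancels the pole), so the integrand is smooth and adaptive
quadrature (relative tolerance 1e-10, with breakpoints at the 1/Λ
boundary layers) applies directly. At ε = 0 this reproduces the closed
neutral form T = (N/B)[((ξ−z₀)/z₀)ln(ξ/(ξ−z₀)) + ((1−σ)/σ)ln(1−σ)] to
better than 1e-6 (asserted on a (z₀, σ) grid). The second moment solves
the same operator with source −2(N/B)θ(z)/(z(ξ−z)); the inner θ values
use fixed 120-point Gauss–Legendre quadrature. A variance that comes out
negative beyond a 1e-6 relative epsilon is reported as an error rather
than clipped. Incidence curves are Gaussian in the conditional moments,
scaled by φ.

The required-advantage inversion brackets ε in [1e-6, 30] and root-finds
the mean conditional time with Brent's method; a target slower than the
neutral time returns a fold advantage of 1.

## Reconstitution of a conditioned host

With an empty marrow the attachment rate per blood cell is a, and the
donor lineage is a two-type branching process (blood cell / niche cell).
Writing q and r for the respective lineage-extinction probabilities,
q = (δ + a r)/(δ + a) and r = (d q + β q r)/(d + β) solve exactly to
q = δ(d+β)/((δ+a)β), giving the reconstitution probability
φ = 1 − q^S for a dose S. The first-attachment-only estimate
φ₁ = 1 − (δ/(δ+a))^S ignores post-attachment death routes and therefore
*over*-estimates φ whenever d > 0 (equality iff d = 0); it is kept as the
documented naive baseline. If the branching process is subcritical the
per-cell extinction probability is clamped to 1. Monte-Carlo estimates
run the exact model until total extinction or a configurable success
threshold (default 100 cells, beyond which extinction is negligible).

## Stochastic simulation

Direct-method SSA (exponential waiting times from the total propensity,
event chosen proportionally — two uniform draws per event; no
tau-leaping, exactness is part of the contract). Hot loops are
numba-compiled with a pure-Python fallback. Trajectories are recorded
either event-exactly (capped) or on a fixed time grid; identical seeds
give identical trajectories, and per-replicate seeds are spawned from a
named SeedSequence. Clonality is evaluated at event times; reaching the
target means n₂/(n₁+n₂) ≥ σ with n₁+n₂ > 0, and species-2 extinction
means n₂ = s₂ = 0. Note that for σ = 1 this "momentary clonality"
definition can trigger while host blood cells remain; at very small N
with heavy niche churn it departs substantially from lineage fixation,
which is why Moran-type comparisons are made on near-full marrows
(n\* = N − 1 at N = 50).

Logistic niche growth is available as a discrete niche-addition event
with propensity rN(1 − N/K) (r given per year), keeping the process
Markovian.

## Exact oracle

For small systems the absorption probabilities are solved exactly on the
truncated continuous-time chain: states are enumerated by breadth-first
reachability from the initial state, the blood pool is capped (events
that would exceed the cap are disallowed), and the embedded jump chain's
linear system is solved sparsely. Truncation bias is reported by
re-solving with the cap raised by 5. Memory for the sparse solve limits
two-species enumerations to tiny N (≲ 4 with moderate caps); the
single-species reduction stays two-dimensional and supports N of a few
hundred, which is how the branching reconstitution formula is verified
to ~1% without relying on simulation.

## Validation strategy and reduced systems

Full-scale murine simulations (N = 10⁴, multi-year horizons) are not
desk-scale, so stochastic-vs-analytic checks run on a scaled system that
keeps the observable shape (N = 500, n\* = 0.99 N, s\* = 0.01 N, ℓ = 5
min) with 400–600 replicates. At this size the projection's finite-N bias
is visible outside its regime: at ε = 0.5 the predicted mean conditional
time exceeds the simulated one by ~12% (the prediction itself is
confirmed independently by Euler–Maruyama simulation of the reduced SDE),
while at ε = 0.1 prediction and simulation agree within ~3 standard
errors. The cross-validation suite therefore runs at ε = 0.1 — inside the
weak-selection regime the analytics claim — and the ε-dependence of the
bias is documented here rather than hidden.

What the synthetic conditions do and do not show: they emulate the
steady-state murine observable grid and its scaled-down analogues, with
all model assumptions holding by construction. Passing tests demonstrate
internal consistency (simulation ↔ ODE ↔ diffusion ↔ exact linear solve)
and correct reproduction of the deduced-parameter arithmetic; they cannot
validate the biological assumptions (well-mixed compartments, HSC-driven
hematopoiesis, steady state, functional equivalence of donor cells), nor
the extrapolation of murine observables to humans.

## Known limitations

- The diffusion analytics cover selection on β only; selection on other
  rates is simulation-only territory.
- No mature-cell compartment or differentiation tree; clonality is HSC
  clonality.
- No modelling of conditioning toxicity or partial conditioning beyond
  what initial conditions express.
- The momentary-clonality stopping rule slightly advances σ = 1 hitting
  times relative to true lineage fixation (the recording-resolution
  choice is event-exact, an upper bound on detection resolution).
- Config files are flat key–value documents; no provenance beyond the
  JSON run manifests written next to each output table.
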