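# Methods

## The model

A biocide-releasing antifouling surface is colonized by microbes
arriving from a well-mixed ocean. Space is discretised into a column of
microhabitats (1-µm slices of lateral area δa = 0.5 mm × 0.5 mm),
indexed *i* = 0 at the paint surface. Biocide diffuses from the surface
and is degraded at a uniform rate, giving the stationary exponential
profile c_i = c_max·e^{−α(i+½)δz}; the slice concentration is fixed for
the whole run (no depletion by biomass, no flow).

Each microbe carries one heritable trait, its MIC (ppm). A single
pharmacodynamic curve ϕ(c, MIC) = r_max(1 − 6(c/MIC)²/(5 + (c/MIC)²))
sets both growth and killing: at c = 0 it equals r_max, it crosses zero
exactly at c = MIC, and it saturates at −5 r_max for c ≫ MIC. A microbe
with c < MIC divides at rate ϕ·(1 − N/K) (N = total population of its
slice; the logistic factor is clamped at zero if migration pushes
N above K) and dies at the background rate d_uniform; with c > MIC it
does not divide and dies at |ϕ| + d_uniform. At the measure-zero
boundary c = MIC the organism is classified on the growth branch (birth
rate 0, death rate d_uniform), which avoids a kill-rate discontinuity.
There is no mutation: every immigration event founds a fresh "ecotype"
whose continuous MIC is inherited unchanged.

Slices are in one of two states: loosely attached (pre-biofilm) or
biofilm. Only the outermost slice is loosely attached; it alone receives
immigrants (rate r_imm, MICs log-normal) and loses microbes by
detachment (per-capita rate r_det). Microbes migrate between adjacent
slices at total per-capita rate r_mig, the destination drawn uniformly
among existing neighbours (one at the column ends, two in the interior);
a lone slice has no neighbours and no migration. When the outer slice's
population reaches N* it flips to the biofilm state and a new empty
outer slice is created. *Establishment* is the first such event, i.e.
the surface slice reaching N*. A run ends at the simulated-time cap
t_max or when a transition would exceed L_max slices.

"Reaches N*" is implemented as integer count ≥ N*; with the default
N* = 0.75 K = 412.5 that means 413 microbes. Six months is taken as
4380 h and one year as 8760 h (365-day year).

## Immigrant MIC calibration

Immigrant MICs are log-normal: ln MIC ~ Normal(µ, σ²). The mean MIC is
e^{µ+σ²/2} and the resistant fraction is P(MIC > c_max) =
½[1 − erf((ln c_max − µ)/(σ√2))]. Given targets (MIC_ave, pc_res),
write z for the upper-tail normal quantile of pc_res; then σ solves
σ²/2 − zσ + ln(c_max/MIC_ave) = 0 and µ = ln MIC_ave − σ²/2. Both real
positive roots satisfy the two constraints; the solver deterministically
returns the smallest positive root (the narrower distribution), which
for the baseline targets (3.179 ppm, 16%, 5 ppm) gives σ = 0.706 and
e^µ = 2.48 ppm (the location is quoted on the ppm scale, as a median
MIC). A negative discriminant means no log-normal has that mean/tail
combination and the solver raises an explicit infeasibility error —
note that holding MIC_ave = 3.179 at c_max = 5 the resistant fraction
can be calibrated only up to about 17%.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| c_max | surface biocide concentration | 5.0 | ppm |
| alpha | gradient steepness | 0.01 | 1/µm |
| delta_z | slice thickness | 1.0 | µm |
| delta_a | slice lateral area | 0.25 | mm² |
| r_max | max growth rate / kill-rate scale | 0.083 | 1/h |
| d_uniform | biocide-independent mortality | 0.018 | 1/h |
| K | slice carrying capacity | 550 | microbes |
| N_star | biofilm transition threshold | 0.75·K | microbes |
| mic_ave | mean immigrant MIC | 3.179 | ppm |
| pc_res | immigrants with MIC > c_max | 0.16 | — |
| r_imm | immigration rate (edge slice) | 20 | 1/h |
| r_mig | per-capita migration rate | 0.1 | 1/h |
| r_det | per-capita detachment (edge) | 0.22·r_max | 1/h |
| t_max | simulated-time cap | 4380 | h |
| L_max | slice-count cap | 40 | — |
| tau | leap interval | 0.1 | h |
| record_dt | snapshot interval | 10 | h |

The defaults describe a marine AF coating (copper-type biocide solubility
near 5 ppm), marine bacterial growth and ocean mortality rates, and a
biofilm density consistent with K = 550 microbes per 2.5·10⁻⁴ mm³ slice
(2.2·10⁶ mm⁻³). τ = 0.1 h keeps per-leap exit probabilities below ~4% at
baseline rates; the SSA-convergence tests document the residual bias.

## Simulation algorithm

Fixed-step tau leaping with parallel updates: all rates are evaluated at
the interval start. For every (ecotype, slice) subpopulation of size n,
the number leaving during the leap is Binomial(n, 1 − e^{−r_exit·τ})
with r_exit the total per-capita exit rate (death + detachment +
migration), so a subpopulation can never go negative by construction.
Exits are then split among the exit channels in proportion to their
rates (migrants re-inserted into the chosen neighbour); births are
Poisson with mean ϕ(1 − N/K)·n·τ and immigrants Poisson(r_imm·τ), each
with a fresh MIC. The transition check runs after every leap; one
transition per leap suffices because new slices start empty.

Internally the population is a dense (ecotype × slice) integer matrix in
preallocated buffers. Per-capita exit probabilities, birth coefficients
and migration fractions depend only on (MIC, slice), not on N, so they
are cached and recomputed only when rows (immigration) or columns
(expansion) appear. Extinct ecotypes are compacted away every 25 leaps
(a six-month baseline run sees ~87,000 immigration events but carries
only a few hundred live ecotypes).

Establishment-only ensembles (`stop_at_establishment=True` without
snapshots) use an exact reformulation of the same process: while the
column is a single slice, immigration is state-independent, so all
arrivals and their MICs are pre-sampled; immigrants with MIC below the
local concentration never divide and die at a state-independent rate, so
each one's per-leap Bernoulli exit history collapses to a single
geometric removal-leap draw kept in a calendar. Only lineages able to
grow are stepped per leap (their birth rate couples to N through the
logistic term). The grower loop is JIT-compiled with numba when
available, with a pure-numpy fallback. The kernel is validated against
the general path by two-sample KS tests on establishment times and by
the SSA comparisons; it is a distributional, not bitwise, equivalence
(the draw order differs).

Reproducibility: replicate r of an ensemble uses the stream
`numpy.random.SeedSequence(base_seed, spawn_key=(r,))`. Identical
(parameters, seed, options) give bit-identical trajectories.

### Oracles

Two independent implementations guard the engine. `ssa_reference_run` is
an exact Gillespie simulation of the same event channels, used on small
systems; the test suite checks three-way agreement (mean, variance,
establishment fraction) as τ → 0 and monotone shrinkage of the leap
bias over τ ∈ {0.4, 0.2, 0.1, 0.05}. `mean_field_trajectory` integrates
the single-slice ODE dN/dt = max(ϕ,0)(1−N/K)N − (d_uniform +
max(−ϕ,0) + r_det)N + r_imm (LSODA); closed-form fixed points (logistic
balance K(1 − d/ϕ), linear balance r_imm/d, M/M/∞ Poisson occupancy for
r_max = 0) anchor the stochastic means in the tests.

## Analysis layer

Diversity is computed on abundances pooled over the whole column:
S = number of ecotypes present, H = −Σ pᵢ ln pᵢ (nats),
E = H/ln S. For S = 1, E is defined as 1 (a single species is trivially
even); for S = 0 it is NaN. Ensemble averages are taken over established
runs only, aligned by absolute time, each grid point averaging the runs
still being simulated then.

Establishment times are Type-I right-censored at t_max. The default t_f
estimator is the censored-exponential MLE, t_f = (Σ observation times,
censored runs contributing t_max)/n_events, with SE ≈ t_f/√n_events.
A survival-curve alternative (least squares of ln p_s(t) against t
through the origin, on the record_dt grid, restricted to p_s > 0)
mirrors normalized-histogram fitting; the two agree within a few percent
on well-populated ensembles in the memoryless regime. Exponentiality is
tested by parametric bootstrap: a KS-type supremum distance between the
censored empirical survival curve and the fitted exponential, calibrated
by refitting simulated censored exponential samples of the same size
(this accounts for both the censoring and the estimated parameter).

Parameter sweeps rerun independent ensembles per value. Sweeping pc_res
re-solves (µ, σ) holding MIC_ave fixed — the distribution itself is the
swept quantity. Sweeping c_max, by contrast, keeps (µ, σ) fixed at the
reference calibration: the ocean community is a property of the
environment, not of the paint, and re-solving per c_max value would
narrow the distribution and (empirically) destroy the monotone c_max
dependence of t_f. Infeasible cells are reported per-row rather than
aborting the sweep.

## The baseline regime: an honest account

With the default rates, the surface slice supports a quasi-stationary
population of mean ≈ 316 and s.d. ≈ 18 (tau-leap and exact SSA agree).
That is the fully resistant logistic fixed point K(1 − (d_uniform +
r_det)/r_max) ≈ 309.7 plus a small standing crowd of doomed immigrants
— by construction *below* the threshold N* = 412.5, which is the
premise of the stochastic-initiation picture: establishment requires an
upward fluctuation. But the required fluctuation is ≈5σ, and an
Ornstein–Uhlenbeck crossing estimate (relaxation ≈ 0.047/h, event flux
≈ 22 /h) puts the mean waiting time near 10⁷–10⁸ h: at this threshold
establishment is effectively unobservable in six simulated months, and
the tests that assert an appreciable baseline establishment fraction
fail and say so. The waiting time is extraordinarily sensitive here —
moving N*/K from 0.65 to 0.75 sweeps the six-month establishment
probability from ~100% to ~0 — so small unprinted implementation
details (effective death rates, threshold bookkeeping) move t_f by
orders of magnitude. The package therefore validates the *phenomena* —
exponential waiting times in the rare-event regime, t_f increasing
exponentially with c_max, decreasing with r_imm, increasing with r_det,
non-monotone in r_max, and the rising-S/falling-H,E diversity trend —
at thresholds of 0.63–0.69 K where the events can be sampled, and keeps
the published threshold for the headline checks.

Problem sizes used by the shipped tests and acceptance script (chosen
as desk-scale defaults): 625 replicates for the baseline establishment
percentage; 150–200 replicates per ensemble for waiting-time
distributions; 50–80 replicates per sweep cell; 200 replicates per
tau-value for the SSA comparisons on a small (K = 120) system.

## What the model leaves out

Fluid flow and convective transport of biocide; biocide depletion or
shielding by biomass; multiple co-biocides; fitness costs of resistance
and MIC changes upon the biofilm transition; retention of dead biomass;
lateral (2-D/3-D) structure; explicit quorum-sensing molecules (the
density threshold is a proxy whose spatial range is encoded in δa).
Passing tests demonstrate internal consistency of the stochastic model
and its statistics, not agreement with field fouling data — the
quantities predicted here (establishment-time distributions) are rarely
measured systematically.
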