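# Methods

## Model

The utility model maps a light stimulus to an expected avoidance index:

    f(t) = α · l · [1 − erf(β/√t)],    AI_model(t) = min(f(t), 1)

with *l* in lux, *t* in minutes, α in AI per lux, β in min^1/2. The form is
the semi-infinite-domain solution of the diffusion equation with a
constant-concentration boundary, V(x,t) = Vs[1 − erf(x/(2√(Dt)))], read as
a phenomenological response curve: the erf argument carries √t, the
signature of diffusive build-up. (α, β) are treated as free constants; no
mapping onto the physical Vs, D, x is assumed or needed. f is nonnegative,
strictly increasing in t for l > 0, linear in l below the cap, and
saturates at α·l. The cap encodes that once every larva is in the dark
half the AI cannot rise further. t = 0 is outside the model's domain (the
erf argument diverges), so all grids start at the first observation time;
in the dynamics assay that is 0.5 min, giving 22 half-minute points over
an 11-minute test.

With the embedded fitted constants α = 0.001459, β = 0.56532 the model at
t = 11 min yields capped AIs 0.18/0.41/0.65/0.89/1.0 at 150–950 lux, the
950-lux raw value being 1.12. Comparisons against printed two-decimal
values use half-up rounding, applied only at reporting.

## Synthetic assay generator

`simulate_dynamics` emulates the dynamics experiment: `n_larvae` = 20,
half-minute counts over 11 min at a configurable intensity. At each grid
time the dark-half count is drawn Binomial(n, p(t)) with
p(t) = (AI_model(t)+1)/2, so E(AI) = 2p−1 equals the capped model value
and the per-point AI standard deviation is √(4p(1−p)/n) (about 0.2 at
p ≈ 0.8 with 20 larvae). Counts are independent across time points. Real
larvae have strongly autocorrelated positions, and the real assay starts
with all animals in the light half (AI = −1 at t = 0) before relaxing
toward the model curve; the generator reproduces neither feature.
Parameter-recovery results on this generator therefore show that the
fitting machinery works under honest counting noise of the right
magnitude, not that the model is identifiable from any particular real
trajectory. A noiseless mode returns the exact capped curve and is the
basis of the exact-recovery checks. Simulated AI values are not clipped
below zero: sampling noise may produce negative observations even though
the model mean is nonnegative.

## Posterior

The fit criterion is the variance-marginalised Gaussian likelihood with a
uniform prior on the parameter box: log p(θ|y) = −(N/2)·ln SSE(θ) inside
the box, −∞ outside. Residuals are observed AI minus the **capped**
prediction, since the observable is the capped AI. An SSE floor of 1e−12
bounds the density on noiseless data, where the true parameters drive SSE
to zero; the floor turns the singularity into a flat plateau without
affecting which parameters minimise SSE.

## SCEM-UA sampler

Population size s, complexes q with m = s/q members each. The population
is ranked by density (stable sort on ties) and striped: complex k takes
ranks k, k+q, k+2q, … so every complex spans the density range. Each
complex drives one Metropolis sequence for L steps: proposals are
N(current, c_n²·Σ) with Σ the complex covariance computed once per SEM
call and jittered by 1e−10·(bound width)² on the diagonal against
degeneracy; the proposal recentres on the complex mean when the sequence
density trails the complex mean log density by more than ln T or the
sequence acceptance rate falls below AR_min. Accepted draws replace the
worst complex member, so the best density per complex — and the best ever
seen — never decreases. After L steps per complex, complexes are merged
and re-ranked. Convergence is declared when every parameter's Gelman–Rubin
R̂ = √(((n−1)/n·W + B/n)/W), computed over the parallel sequences after
discarding the first half of each, falls below `gr_threshold`; chains with
zero within-chain variance yield an R̂ = +∞ sentinel rather than a
spurious pass.

Generic defaults follow the conventions of the classical scheme:
c_n = 2.4/√n, AR_min = 0.1, T = 1e6, L = m, R̂ < 1.2, burn fraction 0.5,
s = 50, q = 5, at most 60 shuffles. `run_scem` returns the highest-density
point ever evaluated together with the chains, flagged non-converged if
the shuffle budget ran out.

## ISCEM outer loop

Run 1 searches the initial box and pulls I_max down to its best point
θ_o. Each later run either tightens I_max (best density improved or tied)
or raises I_min (it regressed), stopping when consecutive best log
densities differ by at most ε (log densities are scalars, so the norm is
an absolute difference). The raw update can invert or collapse intervals
componentwise, so every update passes through a repair step: swap inverted
components, enforce a floor width (default 1e−9), and clip into the
initial box, which also guarantees the returned point never leaves the
original search region. The loop is capped at `max_outer_iters` (default
20) since nothing in the raw scheme forces termination, and the best point
across **all** runs is returned even if the last run regressed. Every
inner run draws an independent child seed from the configured seed, so a
fit is reproducible from one integer.

## Estimation-grade settings for fitting

`fit_utility_model` wraps ISCEM for point estimation and overrides the
sampling defaults: s = 100, q = 10, jump scale c_n = 1.0, R̂ < 1.005, up
to 400 shuffles per run, ε = 1e−2. The classical 2.4/√n ≈ 1.7 scale is
optimal for sampling a roughly Gaussian target, but the SSE^(−N/2) surface
of this model is a narrow curved valley in (α, β); on seed sweeps the unit
scale cut worst-case recovery error from tens of percent to a fraction of
a percent, and the larger population protects the first run (whose best
point fixes I_max, after which the optimum can lie outside every later
box) against landing in the flat high-β plateau where f ≈ 0. These
settings cost roughly 15 s per fit on one core; all are overridable.

The wide-box detail: the posterior's prior support is deliberately a box
twice the initial search region, because the sampler itself enforces the
current (refined) bounds — otherwise the prior would truncate refits near
the original box edge.

## Validation statistics

Error = observed − predicted; standard deviations use the sample (n−1)
denominator — both conventions verified against the printed reference
statistics (the alternatives reproduce neither the −0.03 mean nor the
0.07 standard deviation). R² = 1 − SSE/SST about the observed mean;
constant observed vectors are rejected. F = R²(n−2)/(1−R²) on (1, n−2)
degrees of freedom, the simple-regression form consistent with the
reference degrees of freedom (1, 20) at n = 22 dynamics points; a perfect
fit returns an infinite-F sentinel that passes the test. The critical
value is scipy's upper quantile of the F distribution.

## Problem sizes

The test suite and acceptance script use the assay-scale problems the
model describes: 22-point series, 5-intensity tables, fits from the box
α ∈ [0,1], β ∈ [0,10], plus a 20-replicate noisy-recovery study (one
binomial dataset and one ISCEM fit per replicate, distinct seeds). The
law-of-large-numbers check on the generator uses 200 replicates at a
single time point against a 10,000-draw binomial oracle.

## Identifiability under single-plate noise

A single noisy plate pins down α far better than β. In the 20-replicate
study, ISCEM's minima agree with an independent multistart
least-squares oracle to about four significant digits, yet both recover β
within 25% of the generating value in only 8 of 20 replicates (α: 18 of
20). The limit is the sampling variance of the least-squares estimator —
β is informed mainly by the few early time points, where binomial noise
with 20 larvae has an AI standard deviation near 0.2 — not the optimizer.
Recovering β tightly from real data therefore requires pooling several
plates; the noisy-recovery test records exactly these per-parameter rates.

## Known limitations

- The ISCEM interval-update rule can exclude the optimum after the first
  run (I_max = θ_o caps every component at the first run's best point);
  the best-ever return value bounds the damage but cannot repair a poor
  first run. The estimation-grade first-run settings above are the
  mitigation.
- The generator's independent-binomial noise understates the temporal
  correlation of real larval trajectories; recovery rates on synthetic
  data are accordingly optimistic.
- The sampler is single-process; "parallel" sequences are a logical
  contract, not concurrency.
- No posterior summarisation (credible intervals): the sampler is used as
  a global optimiser, and its chains are exposed only for convergence
  diagnostics and traceability.
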