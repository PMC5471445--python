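# Methods

## Model

A photoreceptor is modeled as N independent, statistically identical photon
sampling units (microvilli). Light of intensity E(I) photons/s is absorbed
uniformly across them, so each unit sees a homogeneous Poisson stream with
rate λ = E(I)/N (converted internally to photons/ms). Transduction in one
unit follows two rules:

1. an accepted photon at time t produces a quantum bump at t + L, with a
   random latency L;
2. from t until t + L + D + R the unit is blocked — the fixed bump duration
   D plus a random refractory period R — and photons arriving inside the
   half-open window [t, t + S), S = L + D + R, are lost.

Bumps are stereotyped: a fixed waveform B(t) normalized to unit peak,
scaled by amplitude h. The macroscopic light-induced current is the shot
noise superposition C(t) = Σ_n Σ_j h·B(t − b_{nj}) over all bump times of
all units.

L and R are gamma distributed, a flexible, experimentally motivated choice
for unimodal positive delays. B(t) uses a gamma shape as well.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| N | microvillus count | 30,000 | lower bound of the anatomical range |
| L | latency | Γ(a=9, b=3/ms) | mean 3 ms, sd 1 ms |
| R | refractory period | Γ(a=9, b=0.08/ms) | mean 112.5 ms, sd 37.5 ms |
| D | bump duration | 10 ms | order of the high-amplitude support of B |
| h | bump amplitude | 1 (a.u.) | no absolute current scale in this reduced model |
| B(t) | bump waveform | Γ(9, 1/ms), unit peak | peak at (a−1)/b = 8 ms |

The shape/rate table underlying these values carries no time units; the
calibration adopted here reads the latency and waveform rates as per-ms and
the refractory rate as per-100-ms. This is the only assignment consistent
with a mean refractory period of ~100 ms that simultaneously dominates a
latency and bump duration of a few ms; it is exposed through the
configuration file rather than hard-coded. D is likewise not fixed by any
published table; 10 ms is adopted and configurable. Headline quantum
efficiencies shift by well under ±15 % relative for reasonable alternative
choices of D.

## Analytic results

Let H ~ Exp(λ) be the next photon interval and

F(A) = P(H > S) = E[e^{−λS}] = e^{−λD} · (b_L/(b_L+λ))^{a_L} · (b_R/(b_R+λ))^{a_R}

the clearance probability, computed in closed form as the product of
component Laplace transforms. The inter-bump-interval density is the
mixture

f_T = F(A) · f_{L+D+I} + (1 − F(A)) · f_{S+I},   I ~ Exp(λ),

with expectation E(T) = E(L) + D + 1/λ + (1 − F(A))·E(R), and the quantum
efficiency is QE = 1/(λ·E(T)). The package also reports 1 − F(A) as the
refractory-period contribution: the probability that the next photon lands
inside the blocked window and is lost to refractoriness.

### The mixture is an approximation; the exact gain is kept separately

The mixture treats the two branches with unconditional component
distributions, ignoring the conditioning on {H > S} vs {H < S}. The exact
mechanism has a simpler renewal structure: because the exponential wait is
memoryless, consecutive accepted photons are separated by exactly S plus a
fresh Exp(λ) wait, so the stationary gain is

QE_exact = 1 / (1 + λ·E(S)),   E(S) = E(L) + D + E(R) = 125.5 ms.

`exact_mechanistic_qe` exposes this value; it is the oracle the Monte-Carlo
simulator is validated against. The relative gap between the two formulas
is exactly F(A)·E(R)/E(T): negligible in the bright limit (F(A) → 0) and in
the asymptotic dim limit, largest at intermediate light (≈ 18 % relative at
λ = 0.01/ms). The mixture expression is the package's primary QE
definition; the exact formula is never silently substituted.

A related consequence: the exact mechanism cannot produce inter-bump
intervals shorter than D + R (plus the latency difference), so the
small-interval hump visible in the analytic f_T at intermediate light —
created by the unconditioned L+D+I branch — is absent from simulated
interval histograms. Tests assert the hump on the analytic density and the
hump-free mechanistic support on the simulated one.

## Numerical choices

- **Grids.** Densities are discretized on uniform grids starting at 0.
  Spacing resolves the narrowest gamma component (sd/8; the clearance-
  probability oracle uses sd/64); extent covers each component's 1 − 1e-9
  quantile, so in dim light the exponential tail forces grids of ~10^6
  points (still < 100 ms of compute via FFT convolution). Every returned
  grid is renormalized to unit trapezoidal integral and construction
  asserts it within 1e-4.
- **Convolution.** FFT-based linear convolution scaled by dt, with a
  trapezoid end-correction (subtracting half the endpoint products) so
  densities that are nonzero at t = 0 (exponentials) still convolve with
  O(dt²) accuracy. Tails are truncated at cumulative mass 1 − 1e-8 and the
  result renormalized; truncated mass is recorded in grid metadata.
- **Delta shifts.** The fixed duration D is applied as an exact index shift
  (delay rounded to the nearest grid point, residual recorded), never as a
  gridded spike, to avoid mass leakage.
- **Clearance oracle.** The numeric path integrates f_S(s)·e^{−λs} by
  Simpson's rule on the fine grid; it agrees with the closed form within
  1e-8 absolute across λ ∈ [1e-5, 10]/ms.
- **Simulator.** Photon trains are cumulative exponential gaps. Thinning
  walks accepted events with `searchsorted` over the arrival array —
  O(bumps·log photons), semantically identical to a per-photon sweep.
  Latency/refractory variates come from pre-drawn pools refilled on
  exhaustion; per-microvillus RNG substreams are spawned from the master
  seed via `SeedSequence`, so results are bit-reproducible and independent
  of N changes. Bump onsets are binned to the trace grid (dt = 0.5 ms
  default) and convolved with the sampled waveform; onset rounding is the
  only discretization and superposition is exactly linear across units.
- **Burn-in.** Steady-state statistics discard an initial E(S) + 5·E(L)
  (140.5 ms at defaults); photon and bump counts are taken in the same
  window so the startup transient largely cancels from the QE ratio.
- **Degenerate refractory period.** `refractory=None` (or mean RP 0)
  denotes R ≡ 0 exactly — used by the no-RP bound QE = 1/(1 + λ(E(L)+D))
  and the `bump_blocking_only` simulator mode.

## Simulated experiment sizes

Monte-Carlo validation runs use 2,000 microvilli × 60 s light steps
(per-microvillus rates λ ∈ {1e-4, 1e-2, 1e-1, 1}/ms), which puts the
ratio-estimator standard error of the empirical QE at 3e-6 … 1e-3 depending
on intensity; intensity–response experiments use 2,000 microvilli × 5 s
steps across λ = 1e-4 … 1e-1/ms. Intensities for scaled-down populations
are chosen to match the per-microvillus rate λ, the physically meaningful
variable, rather than the full-size photoreceptor intensity. Between-mode
LIC comparisons reuse one master seed (common random numbers), so dim-light
mode differences are estimated far more precisely than independent runs
would allow.

## What the generator emulates — and what it does not

The synthetic photon input is a stationary, homogeneous Poisson process:
light steps of fixed intensity, uniform absorption probability across
microvilli, every incident photon absorbed. Real stimuli are dynamic and
real photoreceptors add mechanisms this model deliberately omits —
intracellular pupil, bump amplitude/latency adaptation, voltage-domain
filtering, photomechanical effects. Passing tests therefore demonstrate the
internal consistency of refractory gain control under idealized sampling,
not a quantitative prediction of recorded currents. Bump waveform
stochasticity is ignored (uniform waveform assumption), and only
steady-state step responses are modeled.

## Known limitations

- The mixture f_T and its E(T) are approximations (see above); their QE
  overestimates the exact mechanistic gain at intermediate intensities.
- The LIC has no absolute scale (h is unitless).
- Inter-bump intervals are collected per microvillus after burn-in; very
  short, dim runs can have few or no intervals (flagged by a duration
  warning on the result).
- The dynamic-range compression measured between 3×10³ and 1×10⁸ photons/s
  is ~420-fold with the default calibration; order-of-magnitude agreement
  with a several-hundred-fold figure is the appropriate reading, since the
  exact value is sensitive to the unit calibration and D.
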