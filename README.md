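# qbump

Refractory quantal sampling in microvillar photoreceptors: an analytic
renewal-theory calculator and an event-driven Monte-Carlo simulator for the
photon → quantum-bump transduction chain of a fly photoreceptor.

## The problem

A fly photoreceptor samples light with ~30,000 microvilli. Each microvillus
absorbs photons as an independent Poisson stream and converts an accepted
photon into a stereotyped quantum bump (QB) after a stochastic latency *L*;
the bump lasts a fixed duration *D* and is followed by a stochastic
refractory period *R* during which further photons are lost. Bumps from all
microvilli superpose into the macroscopic light-induced current (LIC). The
per-microvillus dead time *S* = *L* + *D* + *R* makes the photon→bump gain —
the quantum efficiency

QE = v/λ = 1/(λ·E(T))

(λ the photon rate per microvillus, *v* the bump rate, E(T) the mean
inter-bump interval) — fall automatically and nonlinearly with brightening.
This package computes that gain control exactly and by simulation, for
anyone studying adaptation in graded-potential sensory neurons.

## The model

With H ~ Exp(λ) the next photon interval and F(A) = P(H > S) = E[e^{−λS}]
the probability that it clears the blocked window, the inter-bump-interval
density is the two-branch convolution mixture

f_T(t) = F(A)·f_{L+D+I}(t) + (1 − F(A))·f_{S+I}(t),    I ~ Exp(λ),

whose expectation E(T) = E(L) + D + 1/λ + (1 − F(A))·E(R) gives the QE above.
*L* and *R* are gamma distributed (defaults Γ(9, 3/ms) and Γ(9, 0.08/ms),
i.e. mean latency 3 ms and mean refractory period 112.5 ms); D = 10 ms;
F(A) factorizes in closed form as e^{−λD}·(b_L/(b_L+λ))^{a_L}·(b_R/(b_R+λ))^{a_R}.
The simulator implements the mechanism directly — Poisson trains, half-open
blocking windows [t, t+S), bump superposition — and its empirical gain
converges to the exact renewal rate 1/(1 + λ·E(S)), which the package also
exposes as an independent oracle.

## Worked example

```python
import qbump as qb

p = qb.ModelParams()          # 30,000 microvilli, calibrated defaults
for inten in (3e3, 3e5, 3e6, 1e8):
    lam = qb.photon_rate_per_microvillus(inten, p)
    print(f"{inten:>9.2e} photons/s  lambda={lam:.5g}/ms  "
          f"F(A)={qb.clear_probability(p, lam):.4g}  "
          f"E(T)={qb.expected_interbump(p, lam):8.1f} ms  "
          f"QE={100*qb.quantum_efficiency(p, lam):7.3f} %")
```

prints

```
 3.00e+03 photons/s  lambda=0.0001/ms  F(A)=0.9875  E(T)= 10014.4 ms  QE= 99.856 %
 3.00e+05 photons/s  lambda=0.01/ms  F(A)=0.3042  E(T)=   191.3 ms  QE= 52.281 %
 3.00e+06 photons/s  lambda=0.1/ms  F(A)=0.0001853  E(T)=   135.5 ms  QE=  7.381 %
 1.00e+08 photons/s  lambda=3.3333/ms  F(A)=8.553e-33  E(T)=   125.8 ms  QE=  0.238 %
```

In dim light photons arrive ~10 s apart per microvillus, almost every one
clears the ~125 ms blocked window (F(A) ≈ 0.99) and nearly 100 % become
bumps. With brightening F(A) collapses, E(T) saturates toward E(S) = 125.5 ms
and the QE falls to a fraction of a percent — several-hundred-fold automatic
gain compression from refractoriness alone.

The same experiment by Monte-Carlo, from the shell:

```bash
qbump simulate --n-microvilli 2000 --intensity 20000 --duration-ms 60000 \
      --seed 1 --out demo
```

reports `1197482 photons -> 530733 bumps (QE 0.4432 +/- 0.00032)` at
λ = 0.01/ms, matching the mechanistic gain 1/(1 + 0.01·125.5) = 0.4435
within one standard error. Other commands: `qbump qe-curve` (analytic QE /
E(T) / RP-contribution sweep), `qbump interval-pdf` (f_T density),
`qbump intensity-response --mode {no_loss,bump_blocking_only,full}`
(steady-state LIC vs intensity), `qbump sensitivity` (QE curves versus mean
refractory period). All accept `--config` with a flat YAML/JSON file; see
`qbump <cmd> --help`.

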