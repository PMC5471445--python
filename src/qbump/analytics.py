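"""Renewal-theory analysis of refractory photon-to-bump transduction.

A microvillus absorbs photons as a Poisson stream with rate lambda (per ms).
An accepted photon triggers a quantum bump after a gamma latency L; the bump
lasts a fixed duration D and is followed by a gamma refractory period R.
Photons falling inside the blocked window S = L + D + R are lost.  This
module computes, in closed form and on density grids:

* the clearance probability F(A) = P(H > S) = E[exp(-lambda S)] that the next
  photon arrives after the blocked window ends,
* the inter-bump-interval density f_T, a two-branch convolution mixture
  weighted by F(A),
* the expected inter-bump interval E(T) and the quantum efficiency
  QE = 1/(lambda * E(T)), the fraction of absorbed photons transduced to
  bumps, and
* sweeps of these quantities over light intensity and over the mean
  refractory period.

An exact mechanistic gain formula QE = 1/(1 + lambda * E(S)) — the renewal
rate of the blocking mechanism itself — is kept as a separate operation and
serves as the independent oracle for the Monte-Carlo simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .kernels import (
    ExponentialSpec,
    GammaSpec,
    ParameterError,
    PdfGrid,
    convolve_pdfs,
    discretize,
    laplace_gamma,
    shift_pdf,
)

__all__ = [
    "ModelParams",
    "QEPoint",
    "QECurve",
    "photon_rate_per_microvillus",
    "clear_probability",
    "clear_probability_numeric",
    "minimum_interval_pdf",
    "interbump_pdf",
    "expected_interbump",
    "quantum_efficiency",
    "exact_mechanistic_qe",
    "rp_contribution",
    "qe_curve",
    "rp_sensitivity",
    "default_intensity_grid",
]


@dataclass(frozen=True)
class ModelParams:
    """The four biophysical parameters of the sampling model.

    Defaults are the calibrated physiologically realistic values for a
    Drosophila photoreceptor: 30,000 microvilli; latency L ~ Gamma(9, 3/ms)
    (mean 3 ms); refractory period R ~ Gamma(9, 0.08/ms) (mean 112.5 ms,
    i.e. rate 8 per 100 ms); fixed bump duration D = 10 ms; unit bump
    amplitude; bump waveform shaped as Gamma(9, 1/ms) normalized to peak 1.

    ``refractory=None`` denotes the degenerate no-refractory limit R = 0,
    used by sensitivity sweeps and the bump-blocking-only simulator mode.
    """

    n_microvilli: int = 30_000
    latency: GammaSpec = GammaSpec(9.0, 3.0)
    refractory: Optional[GammaSpec] = GammaSpec(9.0, 0.08)
    bump_duration: float = 10.0
    bump_amplitude: float = 1.0
    bump_shape: GammaSpec = GammaSpec(9.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_microvilli < 1:
            raise ParameterError(f"n_microvilli must be >= 1, got {self.n_microvilli}")
        if self.bump_duration < 0:
            raise ParameterError(f"bump_duration must be >= 0, got {self.bump_duration}")
        if not (self.bump_amplitude > 0):
            raise ParameterError(f"bump_amplitude must be > 0, got {self.bump_amplitude}")

    def mean_latency(self) -> float:
        return self.latency.mean()

    def mean_refractory(self) -> float:
        return 0.0 if self.refractory is None else self.refractory.mean()

    def mean_minimum_interval(self) -> float:
        """E(S) = E(L) + D + E(R), the mean blocked window (ms)."""
        return self.mean_latency() + self.bump_duration + self.mean_refractory()

    def with_mean_refractory(self, mean_rp: float) -> "ModelParams":
        """Rescale the refractory rate so the mean RP equals ``mean_rp`` ms.

        The gamma shape is held fixed; ``mean_rp = 0`` yields the degenerate
        R = 0 limit.
        """
        if mean_rp < 0:
            raise ParameterError(f"mean_rp must be >= 0, got {mean_rp}")
        if mean_rp == 0:
            return replace(self, refractory=None)
        shape = self.refractory.shape if self.refractory is not None else 9.0
        return replace(self, refractory=GammaSpec(shape, shape / mean_rp))

    def without_refractory(self) -> "ModelParams":
        return replace(self, refractory=None)

    def to_dict(self) -> dict:
        return {
            "n_microvilli": self.n_microvilli,
            "latency_shape": self.latency.shape,
            "latency_rate_per_ms": self.latency.rate,
            "refractory_shape": None if self.refractory is None else self.refractory.shape,
            "refractory_rate_per_ms": None if self.refractory is None else self.refractory.rate,
            "bump_duration_ms": self.bump_duration,
            "bump_amplitude": self.bump_amplitude,
            "bump_shape_shape": self.bump_shape.shape,
            "bump_shape_rate_per_ms": self.bump_shape.rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        refractory = None
        if d.get("refractory_rate_per_ms") is not None:
            refractory = GammaSpec(d["refractory_shape"], d["refractory_rate_per_ms"])
        return cls(
            n_microvilli=int(d["n_microvilli"]),
            latency=GammaSpec(d["latency_shape"], d["latency_rate_per_ms"]),
            refractory=refractory,
            bump_duration=float(d["bump_duration_ms"]),
            bump_amplitude=float(d["bump_amplitude"]),
            bump_shape=GammaSpec(d["bump_shape_shape"], d["bump_shape_rate_per_ms"]),
        )


@dataclass(frozen=True)
class QEPoint:
    """Per-intensity analytic results."""

    intensity: float  # photons/s per photoreceptor
    lam: float  # photons/ms per microvillus
    clear_prob: float  # F(A) = P(H > S)
    expected_interval: float  # E(T), ms
    bump_rate: float  # bumps/ms per microvillus, 1/E(T)
    qe: float  # fraction in (0, 1]
    rp_contribution: float  # 1 - F(A)


@dataclass
class QECurve:
    """An intensity sweep of :class:`QEPoint`, ordered by intensity."""

    points: list
    params: ModelParams

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intensity_photons_per_s": [p.intensity for p in self.points],
                "lambda_per_ms": [p.lam for p in self.points],
                "F_A": [p.clear_prob for p in self.points],
                "E_T_ms": [p.expected_interval for p in self.points],
                "bump_rate_per_ms": [p.bump_rate for p in self.points],
                "QE": [p.qe for p in self.points],
                "rp_contribution": [p.rp_contribution for p in self.points],
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "params": self.params.to_dict(),
            "points": self.to_dataframe().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def photon_rate_per_microvillus(intensity: float, params: ModelParams) -> float:
    """Photon-absorption rate lambda per microvillus, in photons/ms.

    The intensity (photons/s absorbed by the whole photoreceptor) is divided
    by the microvillus count, then converted from per-second to per-ms.
    """
    if not (intensity > 0):
        raise ParameterError(f"intensity must be > 0, got {intensity}")
    return intensity / params.n_microvilli / 1000.0


def clear_probability(params: ModelParams, lam: float) -> float:
    """F(A) = P(H > S) = E[exp(-lambda S)], in closed form.

    With H ~ Exp(lambda) independent of S = L + D + R,
    P(H > S) = E[exp(-lambda S)] factorizes into the product of the
    component Laplace transforms: exp(-lambda D) * (b_L/(b_L+lambda))^a_L *
    (b_R/(b_R+lambda))^a_R.
    """
    if not (lam > 0):
        raise ParameterError(f"lambda must be > 0, got {lam}")
    out = np.exp(-lam * params.bump_duration) * laplace_gamma(params.latency, lam)
    if params.refractory is not None:
        out *= laplace_gamma(params.refractory, lam)
    return float(out)


def clear_probability_numeric(
    params: ModelParams, lam: float, dt: Optional[float] = None
) -> float:
    """Numeric-integration oracle for F(A): integral of f_S(s) e^(-lambda s).

    Builds the blocked-window density f_S on a fine grid and integrates the
    survival-weighted density by Simpson's rule.  Independent of the
    closed-form Laplace product used by :func:`clear_probability`.
    """
    if not (lam > 0):
        raise ParameterError(f"lambda must be > 0, got {lam}")
    if dt is None:
        dt = _component_dt(params) / 8.0  # extra-fine oracle grid
    fs = minimum_interval_pdf(params, dt=dt)
    weight = np.exp(-lam * fs.times)
    return float(simpson(fs.density * weight, dx=fs.dt))


def _component_dt(params: ModelParams) -> float:
    """Grid spacing resolving the narrowest gamma component (sd/8)."""
    sds = [params.latency.sd()]
    if params.refractory is not None:
        sds.append(params.refractory.sd())
    return min(sds) / 8.0


def _discretize_component(spec, dt: float) -> PdfGrid:
    """Discretize one component on its own support at a shared spacing."""
    t_max = spec.quantile(1.0 - 1e-9)
    n = max(int(np.ceil(t_max / dt)) + 1, 8)
    return discretize(spec, t_max=n * dt, n_points=n + 1)


def minimum_interval_pdf(params: ModelParams, dt: Optional[float] = None) -> PdfGrid:
    """Density of the blocked window S = L + D + R (f_S = f_L * delta_D * f_R)."""
    if dt is None:
        dt = _component_dt(params)
    f = _discretize_component(params.latency, dt)
    f = shift_pdf(f, params.bump_duration)
    if params.refractory is not None:
        f = convolve_pdfs(f, _discretize_component(params.refractory, dt))
    return f


def interbump_pdf(params: ModelParams, lam: float, dt: Optional[float] = None) -> PdfGrid:
    """Inter-bump-interval density f_T as a two-branch convolution mixture.

    f_T = F(A) * f_{L+D+I} + (1 - F(A)) * f_{S+I}, with I ~ Exp(lambda).
    The first branch holds when the next photon clears the blocked window,
    the second when one or more photons were lost to it.  The grid spacing
    resolves the narrowest component; the extent covers the exponential tail
    even in dim light (where 1/lambda can reach tens of seconds).
    """
    if not (lam > 0):
        raise ParameterError(f"lambda must be > 0, got {lam}")
    if dt is None:
        dt = min(_component_dt(params), 1.0 / (8.0 * lam))
    f_a = clear_probability(params, lam)
    f_ld = shift_pdf(_discretize_component(params.latency, dt), params.bump_duration)
    f_i = _discretize_component(ExponentialSpec(lam), dt)
    branch_clear = convolve_pdfs(f_ld, f_i)  # f_{L+D+I}
    f_s = f_ld
    if params.refractory is not None:
        f_s = convolve_pdfs(f_ld, _discretize_component(params.refractory, dt))
    branch_blocked = convolve_pdfs(f_s, f_i)  # f_{S+I}
    n = max(branch_clear.density.size, branch_blocked.density.size)
    mix = np.zeros(n)
    mix[: branch_clear.density.size] += f_a * branch_clear.density
    mix[: branch_blocked.density.size] += (1.0 - f_a) * branch_blocked.density
    mass = np.trapezoid(mix, dx=dt)
    return PdfGrid(
        0.0,
        dt,
        mix / mass,
        meta={"F_A": f_a, "lambda_per_ms": lam, "renormalized_by": float(mass)},
    )


def expected_interbump(params: ModelParams, lam: float) -> float:
    """E(T) = E(L) + D + 1/lambda + (1 - F(A)) * E(R), in ms.

    Expectation of the two-branch mixture with unconditional component means.
    """
    f_a = clear_probability(params, lam)
    return (
        params.mean_latency()
        + params.bump_duration
        + 1.0 / lam
        + (1.0 - f_a) * params.mean_refractory()
    )


def quantum_efficiency(params: ModelParams, lam: float) -> float:
    """QE = v/lambda = 1/(lambda * E(T)), the photon-to-bump gain in (0, 1]."""
    return 1.0 / (lam * expected_interbump(params, lam))


def exact_mechanistic_qe(params: ModelParams, lam: float) -> float:
    """Exact gain of the blocking mechanism: 1/(1 + lambda * E(S)).

    Consecutive accepted photons are separated by exactly S plus a fresh
    Exp(lambda) wait, so the accepted-photon renewal rate is
    1/(E(S) + 1/lambda) and the gain follows.  Serves as the independent
    oracle for the Monte-Carlo simulator and quantifies the (small) bias of
    the mixture approximation behind :func:`quantum_efficiency`.
    """
    if not (lam > 0):
        raise ParameterError(f"lambda must be > 0, got {lam}")
    return 1.0 / (1.0 + lam * params.mean_minimum_interval())


def rp_contribution(params: ModelParams, lam: float) -> float:
    """1 - F(A): probability the next photon lands inside the blocked window."""
    return 1.0 - clear_probability(params, lam)


def default_intensity_grid(
    low: float = 3e3, high: float = 1e8, num: int = 40
) -> np.ndarray:
    """Logarithmic intensity sweep (photons/s), spanning the diurnal range."""
    return np.geomspace(low, high, num)


def qe_curve(params: ModelParams, intensities: Sequence[float]) -> QECurve:
    """One :class:`QEPoint` per intensity (ascending, all > 0)."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        raise ParameterError("intensities must be non-empty")
    if np.any(intensities <= 0):
        raise ParameterError("all intensities must be > 0")
    if np.any(np.diff(intensities) < 0):
        raise ParameterError("intensities must be sorted ascending")
    points = []
    for intensity in intensities:
        lam = photon_rate_per_microvillus(intensity, params)
        f_a = clear_probability(params, lam)
        e_t = expected_interbump(params, lam)
        points.append(
            QEPoint(
                intensity=float(intensity),
                lam=lam,
                clear_prob=f_a,
                expected_interval=e_t,
                bump_rate=1.0 / e_t,
                qe=1.0 / (lam * e_t),
                rp_contribution=1.0 - f_a,
            )
        )
    return QECurve(points=points, params=params)


def rp_sensitivity(
    params: ModelParams,
    mean_rps: Sequence[float],
    intensities: Sequence[float],
) -> list:
    """One QE curve per target mean refractory period (gamma shape fixed).

    The refractory rate is rescaled to b = a/mean for each requested mean RP;
    ``mean_rp = 0`` gives the degenerate no-refractory bound
    QE = 1/(1 + lambda (E(L) + D)).
    """
    curves = []
    for mean_rp in mean_rps:
        curves.append(qe_curve(params.with_mean_refractory(mean_rp), intensities))
    return curves
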