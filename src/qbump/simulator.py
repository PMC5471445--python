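"""Event-driven Monte-Carlo simulation of refractory quantal sampling.

Each microvillus receives an independent homogeneous Poisson photon train.
Photons are swept in arrival order against a blocking window: an accepted
photon at time t samples a latency L and refractory period R, emits a bump
onset at t + L, and blocks the microvillus over the half-open window
[t, t + L + D + R).  Bumps from all microvilli are superposed with a fixed
normalized waveform into the macroscopic light-induced current (LIC).

Randomness is fully reproducible: one master seed spawns independent
per-microvillus substreams via numpy's SeedSequence, so the microvillus
count can change without correlating streams.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .analytics import (
    ModelParams,
    expected_interbump,
    photon_rate_per_microvillus,
)
from .kernels import ParameterError, gamma_pdf

__all__ = [
    "PhotonTrain",
    "QBTrain",
    "LICTrace",
    "SimResult",
    "sample_photon_train",
    "transduce",
    "bump_waveform",
    "superpose",
    "run_experiment",
    "intensity_response",
    "MODES",
]

#: Simulator modes for intensity-response experiments.
#: "full" applies latency + bump + refractory blocking; "bump_blocking_only"
#: sets R = 0 (photons lost only during L + D); "no_loss" transduces every
#: photon into a stereotyped bump.
MODES = ("no_loss", "bump_blocking_only", "full")

#: Default LIC sampling interval (ms).
DEFAULT_TRACE_DT = 0.5


@dataclass
class PhotonTrain:
    """Sorted photon arrival times (ms) absorbed by one microvillus."""

    microvillus_id: int
    arrival_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        if self.arrival_times.size:
            if np.any(np.diff(self.arrival_times) <= 0):
                raise ParameterError("arrival times must be strictly increasing")
            if self.arrival_times[0] < 0 or self.arrival_times[-1] > self.duration:
                raise ParameterError("arrival times must lie within [0, duration]")

    @property
    def n_photons(self) -> int:
        return int(self.arrival_times.size)


@dataclass
class QBTrain:
    """Bump onsets produced by one microvillus, with bookkeeping.

    ``bump_onsets[i] = accepted_photon_times[i] + latencies[i]`` exactly;
    ``lost_photon_count`` counts photons deleted by the blocking window, so
    accepted + lost equals the source train's photon count.
    """

    microvillus_id: int
    bump_onsets: np.ndarray
    accepted_photon_times: np.ndarray
    lost_photon_count: int
    latencies: np.ndarray = field(default_factory=lambda: np.empty(0))
    refractories: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_bumps(self) -> int:
        return int(self.bump_onsets.size)


@dataclass
class LICTrace:
    """Macroscopic light-induced current sampled on a uniform grid.

    Current is in bump-amplitude units and is non-negative everywhere
    (bumps are unidirectional).
    """

    t0: float
    dt: float
    current: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.current.size)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"time_ms": self.times, "current_au": self.current}).to_csv(
            path, index=False, float_format="%.17g"
        )

    def steady_state_mean(self, after: float) -> float:
        mask = self.times >= after
        return float(self.current[mask].mean())


@dataclass
class SimResult:
    """Aggregated counts and statistics of one simulated experiment.

    Photon/bump counts are taken inside the steady-state counting window
    (after the burn-in), so ``empirical_qe`` estimates the stationary gain.
    """

    n_photons: int
    n_bumps: int
    duration: float
    interbump_intervals: np.ndarray
    seed: int
    lam: float
    intensity: float
    burn_in: float
    photons_per_microvillus: np.ndarray
    bumps_per_microvillus: np.ndarray
    trace: Optional[LICTrace] = None
    warnings: list = field(default_factory=list)

    @property
    def n_microvilli(self) -> int:
        return int(self.photons_per_microvillus.size)

    @property
    def empirical_qe(self) -> float:
        if self.n_photons == 0:
            return float("nan")
        return self.n_bumps / self.n_photons

    def qe_standard_error(self) -> float:
        """Ratio-estimator standard error of QE across microvilli.

        Treats per-microvillus (bumps, photons) pairs as i.i.d. and applies
        the standard ratio-estimator variance: SE = sqrt(sum(resid^2)) /
        total_photons with resid_i = bumps_i - QE * photons_i.
        """
        if self.n_photons == 0:
            return float("nan")
        resid = self.bumps_per_microvillus - self.empirical_qe * self.photons_per_microvillus
        return float(np.sqrt(np.sum(resid**2)) / self.n_photons)

    def to_json(self, path: Union[str, Path], params: Optional[ModelParams] = None) -> None:
        payload = {
            "n_photons": self.n_photons,
            "n_bumps": self.n_bumps,
            "empirical_qe": self.empirical_qe,
            "qe_standard_error": self.qe_standard_error(),
            "duration_ms": self.duration,
            "burn_in_ms": self.burn_in,
            "intensity_photons_per_s": self.intensity,
            "lambda_per_ms": self.lam,
            "n_microvilli": self.n_microvilli,
            "n_interbump_intervals": int(self.interbump_intervals.size),
            "seed": self.seed,
            "warnings": self.warnings,
        }
        if params is not None:
            payload["params"] = params.to_dict()
        Path(path).write_text(json.dumps(payload, indent=2))


def sample_photon_train(
    lam: float,
    duration: float,
    rng: np.random.Generator,
    microvillus_id: int = 0,
) -> PhotonTrain:
    """Homogeneous Poisson photon train via cumulative exponential gaps."""
    if lam < 0:
        raise ParameterError(f"lambda must be >= 0, got {lam}")
    if not (duration > 0):
        raise ParameterError(f"duration must be > 0, got {duration}")
    if lam == 0:
        return PhotonTrain(microvillus_id, np.empty(0), duration)
    expected = lam * duration
    chunk = int(expected + 6.0 * np.sqrt(expected) + 16)
    times = np.cumsum(rng.exponential(1.0 / lam, size=chunk))
    while times[-1] < duration:  # rare: extend until the window is covered
        extra = np.cumsum(rng.exponential(1.0 / lam, size=chunk))
        times = np.concatenate([times, times[-1] + extra])
    times = times[: np.searchsorted(times, duration, side="right")]
    return PhotonTrain(microvillus_id, times, duration)


class _GammaPool:
    """Pre-drawn gamma variates, refilled on exhaustion.

    Drawing in vectorized blocks keeps the per-accepted-photon cost low; the
    consumption order (alternating L, R per accepted photon) is fixed, so
    results are reproducible for a given stream.
    """

    def __init__(self, rng: np.random.Generator, shape: float, scale: float, size: int):
        self._rng = rng
        self._shape = shape
        self._scale = scale
        self._buf = rng.gamma(shape, scale, size=max(size, 8))
        self._i = 0

    def draw(self) -> float:
        if self._i >= self._buf.size:
            self._buf = self._rng.gamma(self._shape, self._scale, size=self._buf.size * 2)
            self._i = 0
        v = self._buf[self._i]
        self._i += 1
        return v


def transduce(
    train: PhotonTrain,
    params: ModelParams,
    rng: np.random.Generator,
) -> QBTrain:
    """Apply refractory dead-time thinning to a photon train.

    Photons are swept in order against ``blocked_until`` (initially 0).  A
    photon at t < blocked_until is lost; one at t >= blocked_until is
    accepted (half-open window), samples L and R, emits a bump at t + L and
    re-arms blocked_until = t + L + D + R.
    """
    times = train.arrival_times
    n = times.size
    if n == 0:
        empty = np.empty(0)
        return QBTrain(train.microvillus_id, empty, empty.copy(), 0, empty.copy(), empty.copy())
    mean_s = params.mean_minimum_interval()
    est = min(n, int(2.0 * train.duration / max(mean_s, 1e-9)) + 16)
    lat_pool = _GammaPool(rng, params.latency.shape, 1.0 / params.latency.rate, est)
    ref_pool = None
    if params.refractory is not None:
        ref_pool = _GammaPool(rng, params.refractory.shape, 1.0 / params.refractory.rate, est)

    accepted, onsets, lats, refs = [], [], [], []
    blocked_until = 0.0
    i = 0
    while True:
        i = int(np.searchsorted(times, blocked_until, side="left"))
        if i >= n:
            break
        t = times[i]
        lat = lat_pool.draw()
        ref = ref_pool.draw() if ref_pool is not None else 0.0
        accepted.append(t)
        onsets.append(t + lat)
        lats.append(lat)
        refs.append(ref)
        blocked_until = t + lat + params.bump_duration + ref
    return QBTrain(
        train.microvillus_id,
        np.asarray(onsets),
        np.asarray(accepted),
        n - len(accepted),
        np.asarray(lats),
        np.asarray(refs),
    )


def _transduce_no_loss(
    train: PhotonTrain, params: ModelParams, rng: np.random.Generator
) -> QBTrain:
    """Every photon becomes a bump after a sampled latency (no blocking)."""
    times = train.arrival_times
    lats = rng.gamma(params.latency.shape, 1.0 / params.latency.rate, size=times.size)
    onsets = np.sort(times + lats)
    return QBTrain(train.microvillus_id, onsets, times.copy(), 0, np.sort(lats), np.zeros(times.size))


def bump_waveform(params: ModelParams, dt: float) -> np.ndarray:
    """Unit-peak quantum-bump waveform sampled at spacing ``dt`` ms.

    Gamma-shaped (default Gamma(9, 1/ms), peaking at 8 ms), normalized to
    maximum 1 and truncated where it falls below 1e-4 of the peak.
    """
    if not (dt > 0):
        raise ParameterError(f"dt must be > 0, got {dt}")
    spec = params.bump_shape
    t_end = spec.quantile(1.0 - 1e-9)
    t = np.arange(0.0, t_end + dt, dt)
    w = gamma_pdf(spec, t)
    w = w / w.max()
    above = np.nonzero(w >= 1e-4)[0]
    return w[: above[-1] + 1]


def superpose(
    trains: Sequence[QBTrain],
    params: ModelParams,
    dt: float,
    duration: float,
) -> LICTrace:
    """Sum h * B(t - b_j) over all bumps of all microvilli.

    Bump onsets are binned onto the trace grid (nearest bin) and the binned
    counts convolved with the unit waveform — exactly linear across trains.
    """
    onsets = (
        np.concatenate([tr.bump_onsets for tr in trains])
        if trains
        else np.empty(0)
    )
    return _superpose_onsets(onsets, params, dt, duration)


def _superpose_onsets(
    onsets: np.ndarray, params: ModelParams, dt: float, duration: float
) -> LICTrace:
    n = int(np.floor(duration / dt)) + 1
    counts = np.zeros(n)
    if onsets.size:
        idx = np.round(onsets / dt).astype(int)
        idx = idx[idx < n]
        np.add.at(counts, idx, 1.0)
    wave = bump_waveform(params, dt)
    current = params.bump_amplitude * np.convolve(counts, wave)[:n]
    return LICTrace(0.0, dt, current)


def _burn_in(params: ModelParams, mode: str) -> float:
    eff = params.without_refractory() if mode != "full" else params
    return eff.mean_minimum_interval() + 5.0 * eff.mean_latency()


def run_experiment(
    params: ModelParams,
    intensity: float,
    duration: float,
    seed: int,
    with_trace: bool = False,
    trace_dt: float = DEFAULT_TRACE_DT,
    mode: str = "full",
) -> SimResult:
    """Simulate the whole microvillus population at one light step.

    Photons arrive at rate lambda = intensity / N per microvillus on N
    independent substreams spawned from ``seed``.  Steady-state statistics
    (photon/bump counts, inter-bump intervals) are collected after a burn-in
    of E(S) + 5 E(L).  A duration shorter than 100 expected inter-bump
    intervals is flagged in ``SimResult.warnings``.
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    lam = photon_rate_per_microvillus(intensity, params)
    eff_params = params.without_refractory() if mode == "bump_blocking_only" else params
    burn = _burn_in(params, mode)
    result_warnings = []
    e_t = 1.0 / lam if mode == "no_loss" else expected_interbump(eff_params, lam)
    if duration < 100.0 * e_t:
        msg = (
            f"duration {duration:g} ms < 100 expected inter-bump intervals "
            f"({100.0 * e_t:g} ms); steady-state statistics may be noisy"
        )
        result_warnings.append(msg)
        _warnings.warn(msg, stacklevel=2)
    if duration <= burn:
        raise ParameterError(
            f"duration {duration:g} ms does not exceed the burn-in {burn:g} ms"
        )

    n = params.n_microvilli
    children = np.random.SeedSequence(seed).spawn(n)
    photons_per = np.zeros(n, dtype=np.int64)
    bumps_per = np.zeros(n, dtype=np.int64)
    intervals = []
    all_onsets = [] if with_trace else None
    for mv_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        train = sample_photon_train(lam, duration, rng, mv_id)
        if mode == "no_loss":
            qb = _transduce_no_loss(train, eff_params, rng)
        else:
            qb = transduce(train, eff_params, rng)
        t_arr = train.arrival_times
        photons_per[mv_id] = t_arr.size - np.searchsorted(t_arr, burn, side="left")
        acc = qb.accepted_photon_times
        bumps_per[mv_id] = acc.size - np.searchsorted(acc, burn, side="left")
        if qb.bump_onsets.size >= 2:
            k0 = int(np.searchsorted(qb.bump_onsets, burn, side="left"))
            if qb.bump_onsets.size - k0 >= 2:
                intervals.append(np.diff(qb.bump_onsets[k0:]))
        if with_trace:
            all_onsets.append(qb.bump_onsets)

    trace = None
    if with_trace:
        onsets = np.concatenate(all_onsets) if all_onsets else np.empty(0)
        trace = _superpose_onsets(onsets, params, trace_dt, duration)
    return SimResult(
        n_photons=int(photons_per.sum()),
        n_bumps=int(bumps_per.sum()),
        duration=duration,
        interbump_intervals=(
            np.concatenate(intervals) if intervals else np.empty(0)
        ),
        seed=seed,
        lam=lam,
        intensity=intensity,
        burn_in=burn,
        photons_per_microvillus=photons_per,
        bumps_per_microvillus=bumps_per,
        trace=trace,
        warnings=result_warnings,
    )


def intensity_response(
    params: ModelParams,
    intensities: Sequence[float],
    mode: str,
    duration: float,
    seed: int,
    trace_dt: float = DEFAULT_TRACE_DT,
) -> pd.DataFrame:
    """Steady-state mean LIC per intensity for one simulator mode.

    The same seed is reused across intensities and modes (common random
    numbers), so between-mode comparisons at matched intensity share photon
    trains.  Returns a DataFrame with columns intensity_photons_per_s,
    lambda_per_ms, mean_lic_au, empirical_qe, mode.
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    rows = []
    for intensity in intensities:
        res = run_experiment(
            params,
            float(intensity),
            duration,
            seed,
            with_trace=True,
            trace_dt=trace_dt,
            mode=mode,
        )
        rows.append(
            {
                "intensity_photons_per_s": float(intensity),
                "lambda_per_ms": res.lam,
                "mean_lic_au": res.trace.steady_state_mean(res.burn_in),
                "empirical_qe": res.empirical_qe,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)
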