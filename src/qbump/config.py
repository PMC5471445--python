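"""Flat YAML/JSON run configuration with validated defaults."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .analytics import ModelParams, default_intensity_grid
from .kernels import GammaSpec, ParameterError

__all__ = ["ConfigError", "RunConfig", "load_config", "VALID_KEYS"]

log = logging.getLogger("qbump")


class ConfigError(ValueError):
    """A configuration file contains unknown keys or invalid values."""


#: Recognized flat configuration keys and their meanings.
VALID_KEYS = {
    "n_microvilli": "photon sampling units per photoreceptor (default 30000)",
    "latency_shape": "gamma shape of the bump latency L (default 9)",
    "latency_rate_per_ms": "gamma rate of L in 1/ms (default 3)",
    "refractory_shape": "gamma shape of the refractory period R (default 9)",
    "refractory_rate_per_ms": "gamma rate of R in 1/ms (default 0.08); null disables R",
    "bump_duration_ms": "fixed bump duration D in ms (default 10)",
    "bump_amplitude": "bump amplitude h, dimensionless (default 1)",
    "bump_shape_shape": "gamma shape of the bump waveform (default 9)",
    "bump_shape_rate_per_ms": "gamma rate of the bump waveform in 1/ms (default 1)",
    "intensities": "list of light intensities in photons/s (default 40-point log sweep 3e3..1e8)",
    "duration_ms": "simulated light-step duration in ms (default 60000)",
    "seed": "master RNG seed (required for stochastic commands)",
    "output_dir": "directory for result files (default ./qbump_out)",
    "n_points": "grid points for density discretization (default 32768)",
    "trace_dt_ms": "LIC trace sampling interval in ms (default 0.5)",
}


@dataclass
class RunConfig:
    """Effective configuration for any CLI command."""

    model: ModelParams = field(default_factory=ModelParams)
    intensities: np.ndarray = field(default_factory=default_intensity_grid)
    duration_ms: float = 60_000.0
    seed: Optional[int] = None
    output_dir: Path = Path("qbump_out")
    n_points: int = 2**15
    trace_dt_ms: float = 0.5

    def to_dict(self) -> dict:
        d = self.model.to_dict()
        d.update(
            intensities=[float(x) for x in self.intensities],
            duration_ms=self.duration_ms,
            seed=self.seed,
            output_dir=str(self.output_dir),
            n_points=self.n_points,
            trace_dt_ms=self.trace_dt_ms,
        )
        return d

    def digest(self, command: str) -> str:
        """Short deterministic hash naming output files for this command."""
        blob = command + json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:8]

    def echo(self) -> None:
        """Log the effective configuration, including derived means."""
        m = self.model
        log.info("effective config: %s", json.dumps(self.to_dict(), sort_keys=True))
        log.info(
            "latency mean %.4g ms (sd %.4g); refractory mean %.4g ms (sd %.4g); "
            "mean blocked window E(S) = %.4g ms",
            m.latency.mean(),
            m.latency.sd(),
            m.mean_refractory(),
            m.refractory.sd() if m.refractory is not None else 0.0,
            m.mean_minimum_interval(),
        )


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Parse a flat YAML (or JSON) key/value file into a :class:`RunConfig`.

    Omitted keys take the calibrated defaults.  Unknown keys are a hard
    error listing the valid keys; invalid values name the violated
    constraint.  An empty file yields the full default configuration.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config must be a flat key/value document, got {type(loaded).__name__}")
        raw = loaded
    unknown = sorted(set(raw) - set(VALID_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; valid keys are: "
            + ", ".join(sorted(VALID_KEYS))
        )

    defaults = ModelParams()
    refractory: Optional[GammaSpec]
    ref_rate = raw.get("refractory_rate_per_ms", defaults.refractory.rate)
    if ref_rate is None:
        refractory = None
    else:
        refractory = GammaSpec(
            float(raw.get("refractory_shape", defaults.refractory.shape)),
            float(ref_rate),
        )
    try:
        model = ModelParams(
            n_microvilli=int(raw.get("n_microvilli", defaults.n_microvilli)),
            latency=GammaSpec(
                float(raw.get("latency_shape", defaults.latency.shape)),
                float(raw.get("latency_rate_per_ms", defaults.latency.rate)),
            ),
            refractory=refractory,
            bump_duration=float(raw.get("bump_duration_ms", defaults.bump_duration)),
            bump_amplitude=float(raw.get("bump_amplitude", defaults.bump_amplitude)),
            bump_shape=GammaSpec(
                float(raw.get("bump_shape_shape", defaults.bump_shape.shape)),
                float(raw.get("bump_shape_rate_per_ms", defaults.bump_shape.rate)),
            ),
        )
    except ParameterError as exc:
        raise ConfigError(f"invalid model parameter: {exc}") from exc

    intensities = np.asarray(
        raw.get("intensities", default_intensity_grid()), dtype=float
    )
    _require(intensities.size > 0, "intensities must be a non-empty list")
    _require(bool(np.all(intensities > 0)), "all intensities must be > 0")
    _require(
        bool(np.all(np.diff(intensities) >= 0)),
        "intensities must be sorted ascending",
    )
    duration = float(raw.get("duration_ms", 60_000.0))
    _require(duration > 0, f"duration_ms must be > 0, got {duration}")
    n_points = int(raw.get("n_points", 2**15))
    _require(n_points >= 16, f"n_points must be >= 16, got {n_points}")
    trace_dt = float(raw.get("trace_dt_ms", 0.5))
    _require(trace_dt > 0, f"trace_dt_ms must be > 0, got {trace_dt}")
    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)

    cfg = RunConfig(
        model=model,
        intensities=intensities,
        duration_ms=duration,
        seed=seed,
        output_dir=Path(raw.get("output_dir", "qbump_out")),
        n_points=n_points,
        trace_dt_ms=trace_dt,
    )
    cfg.echo()
    return cfg
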