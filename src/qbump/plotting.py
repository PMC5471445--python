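"""Optional matplotlib helpers for the standard diagnostic panels.

matplotlib is imported lazily so the core package carries no plotting
dependency; install the ``plot`` extra to use these.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analytics import ModelParams, QECurve, interbump_pdf, photon_rate_per_microvillus


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_interval_pdfs(
    params: ModelParams,
    intensities: Sequence[float],
    t_max: Optional[float] = None,
):
    """Inter-bump-interval densities at several intensities, log-y."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for intensity in intensities:
        lam = photon_rate_per_microvillus(intensity, params)
        grid = interbump_pdf(params, lam)
        ax.plot(grid.times, grid.density, label=f"{intensity:.3g} photons/s")
    if t_max:
        ax.set_xlim(0, t_max)
    ax.set_yscale("log")
    ax.set_xlabel("inter-bump interval (ms)")
    ax.set_ylabel("density (1/ms)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_qe_curve(curve: QECurve):
    """QE, E(T) and RP contribution versus intensity (log-x)."""
    plt = _mpl()
    df = curve.to_dataframe()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogx(df.intensity_photons_per_s, df.QE, "r-", label="QE")
    ax.semilogx(df.intensity_photons_per_s, df.rp_contribution, "-", color="grey",
                label="RP contribution (1 - F(A))")
    ax.set_xlabel("intensity (photons/s)")
    ax.set_ylabel("fraction")
    ax2 = ax.twinx()
    ax2.loglog(df.intensity_photons_per_s, df.E_T_ms, "b-", label="E(T)")
    ax2.set_ylabel("E(T) (ms)")
    ax.legend(loc="center left", frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_intensity_response(tables: Sequence[pd.DataFrame]):
    """Steady-state mean LIC versus intensity for several simulator modes."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for table in tables:
        mode = table["mode"].iloc[0]
        ax.loglog(table.intensity_photons_per_s, table.mean_lic_au, "o-", label=mode)
    ax.set_xlabel("intensity (photons/s)")
    ax.set_ylabel("steady-state mean LIC (bump units)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
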