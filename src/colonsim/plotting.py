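"""Plotting hooks: crypt profiles, longitudinal trends, diet heat maps.

Thin matplotlib wrappers over the tidy tables; every function returns the
figure so callers can save or extend it.  Uses the non-interactive backend.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .crypt import CELL_TYPES, CRYPT_SOLUTES, CryptState


def plot_crypt_profiles(state: CryptState):
    """Cell densities and normalised solute profiles along the crypt axis."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    z = state.grid.z
    for k, name in enumerate(CELL_TYPES):
        ax1.plot(z, state.cells[k], label=name)
    ax1.plot(z, state.dcs, "--", label="dcs")
    ax1.set(xlabel="crypt height z", ylabel="cell density", title="cell densities")
    ax1.legend(fontsize=7)
    for k, name in enumerate(CRYPT_SOLUTES):
        prof = state.solutes[k]
        top = prof.max() or 1.0
        ax2.plot(z, prof / top, label=f"{name} (max {top:.3g})")
    ax2.set(xlabel="crypt height z", ylabel="normalised concentration",
            title="solute profiles")
    ax2.legend(fontsize=7)
    return fig


def plot_longitudinal(biomarker_table: pd.DataFrame):
    """Fig-6a-style normalised trends along the five sections."""
    fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    for col in ("scfa_lumen", "v_out", "f_B_lumen"):
        series = biomarker_table[col]
        ax.plot(series.index, series / series.max(), marker="o", label=col)
    ax.set(xlabel="section", ylabel="value / max", ylim=(0, 1.05))
    ax.legend()
    return fig


def plot_diet_heatmap(scan: pd.DataFrame, biomarker: str):
    """Raw-grid heat map of one biomarker over the fibre/protein plane."""
    sub = scan[scan.biomarker == biomarker]
    pivot = sub.pivot_table(index="f_prot", columns="f_pol", values="value")
    fig, ax = plt.subplots(figsize=(4.5, 3.5), constrained_layout=True)
    im = ax.pcolormesh(pivot.columns.to_numpy(), pivot.index.to_numpy(),
                       pivot.to_numpy(), shading="nearest")
    fig.colorbar(im, ax=ax, label=biomarker)
    ax.set(xlabel="fibre volume fraction", ylabel="protein volume fraction")
    return fig
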