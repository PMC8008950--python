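"""Optional figure panels: group stress-stretch and tangent-modulus curves.

Layout mirrors the usual myography presentation — mean curves per group
with error bars (SE or SD), circumferential and axial panels side by side,
plus tangent modulus versus stretch.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_group_stress_stretch(
    curve_table: pd.DataFrame,
    summaries: dict[str, pd.DataFrame],
    path: str | Path,
) -> Path:
    """Two-panel figure: circumferential and axial group mean stress-stretch."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    circ = summaries["circumferential"].merge(
        summaries["circumferential_stretch"], on=["group", "pressure_mmHg"]
    )
    for g, sub in circ.groupby("group"):
        sub = sub.sort_values("pressure_mmHg")
        axes[0].errorbar(
            sub["mean_stretch"], sub["mean"], yerr=sub["dispersion"],
            marker="o", ms=3, capsize=2, label=str(g),
        )
    axes[0].set_xlabel(r"circumferential stretch $\lambda_\theta$")
    axes[0].set_ylabel(r"$\sigma_\theta$ (kPa)")
    for g, sub in summaries["axial"].groupby("group"):
        sub = sub.sort_values("x")
        axes[1].errorbar(
            sub["x"], sub["mean"], yerr=sub["dispersion"],
            marker="o", ms=3, capsize=2, label=str(g),
        )
    axes[1].set_xlabel(r"axial stretch $\lambda_z$")
    axes[1].set_ylabel(r"$\sigma_z$ (kPa)")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_group_tangent_modulus(tangent_table: pd.DataFrame, path: str | Path) -> Path:
    """Per-axis tangent modulus vs stretch, one thin line per sample."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, axis_name in zip(axes, ("circumferential", "axial")):
        sub = tangent_table[tangent_table["axis"] == axis_name]
        for (g, sid), s in sub.groupby(["group", "sample_id"]):
            s = s.sort_values("x")
            ax.plot(s["x"], s["e_tan_kpa"], alpha=0.5, lw=1,
                    label=str(g) if sid.endswith("_01") else None)
        ax.set_xlabel("stretch")
        ax.set_ylabel(r"$E_{tan}$ (kPa)")
        ax.set_title(axis_name)
        ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
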