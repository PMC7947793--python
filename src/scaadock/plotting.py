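"""Figures: the E–C phase-space map and the positional energy heatmap."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import BinderWindow, HeatmapMatrix, PeptideRecord

__all__ = ["energy_contact_map", "heatmap_figure"]


def energy_contact_map(
    records: Sequence[PeptideRecord],
    window: BinderWindow | None = None,
):
    """Scatter of per-peptide (E_i, C_i) with window members and the
    translated reference highlighted."""
    fig, ax = plt.subplots(figsize=(6, 5))
    e = [r.e_mean for r in records]
    c = [r.c_mean for r in records]
    ax.scatter(e, c, s=12, c="black", label="peptides")
    if window is not None:
        members = [r for r in records if r.sequence in set(window.member_ids)]
        ax.scatter([r.e_mean for r in members], [r.c_mean for r in members],
                   s=12, c="tab:blue", label="±σ window")
        ax.axvline(window.e_center - window.e_sigma, ls="--", lw=0.6, c="gray")
        ax.axvline(window.e_center + window.e_sigma, ls="--", lw=0.6, c="gray")
        ax.axhline(window.c_center - window.c_sigma, ls="--", lw=0.6, c="gray")
        ax.axhline(window.c_center + window.c_sigma, ls="--", lw=0.6, c="gray")
    ref = [r for r in records if r.is_reference]
    if ref:
        ax.scatter([r.e_mean for r in ref], [r.c_mean for r in ref],
                   marker="*", s=180, c="gold", edgecolors="k",
                   label="translated reference")
    ax.set_xlabel(r"$E_i$ (kcal mol$^{-1}$)")
    ax.set_ylabel(r"$C_i$ (contacts)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def heatmap_figure(heatmap: HeatmapMatrix):
    """6-class × 3-position mean residual-energy heatmap."""
    fig, ax = plt.subplots(figsize=(4, 4.5))
    data = heatmap.mean_energy.to_numpy()
    im = ax.imshow(data, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(heatmap.mean_energy.columns)),
                  heatmap.mean_energy.columns)
    ax.set_yticks(range(len(heatmap.mean_energy.index)),
                  heatmap.mean_energy.index)
    fig.colorbar(im, ax=ax, label=r"mean $E_i$ (kcal mol$^{-1}$)")
    fig.tight_layout()
    return fig
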