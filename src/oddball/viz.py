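"""Plotting helpers: AUC traces, temporal-generalization matrices, topographies.

All functions draw on a provided or fresh matplotlib Axes and return the
figure; ``standard_report_figures`` renders the JSON results written by
:func:`oddball.pipeline.run_experiment` into PNG files.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_auc", "plot_gat_matrix", "plot_topography", "standard_report_figures"]


def plot_auc(times, auc, mask=None, ax=None, label=None):
    """AUC(t) with the chance line and optional significance markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(times, auc, label=label)
    ax.axhline(0.5, color="k", lw=0.5, ls="--")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        ax.plot(np.asarray(times)[mask], np.full(mask.sum(), 0.45), "s",
                ms=3, color="C3")
    ax.set_xlabel("time re fifth sound (s)")
    ax.set_ylabel("AUC")
    return ax.figure


def plot_gat_matrix(times, auc_matrix, ax=None, vlim=(0.3, 0.7)):
    """Train-time x test-time AUC matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    t = np.asarray(times)
    im = ax.imshow(
        np.asarray(auc_matrix), origin="lower", aspect="auto", cmap="RdBu_r",
        vmin=vlim[0], vmax=vlim[1],
        extent=[t[0], t[-1], t[0], t[-1]],
    )
    ax.set_xlabel("test time (s)")
    ax.set_ylabel("train time (s)")
    ax.figure.colorbar(im, ax=ax, label="AUC")
    return ax.figure


def plot_topography(positions, values, ax=None, mask=None, cmap="RdBu_r", vlim=None):
    """Scatter topography over 2-D sensor positions (+y anterior)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    values = np.asarray(values, dtype=float)
    if vlim is None:
        v = np.max(np.abs(values)) or 1.0
        vlim = (-v, v)
    sc = ax.scatter(positions[:, 0], positions[:, 1], c=values, s=90,
                    cmap=cmap, vmin=vlim[0], vmax=vlim[1], edgecolors="k",
                    linewidths=0.3)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        ax.scatter(positions[m, 0], positions[m, 1], facecolors="none",
                   edgecolors="lime", s=160, linewidths=1.5)
    circ = plt.Circle((0, 0), 1.05, fill=False, color="k", lw=0.8)
    ax.add_patch(circ)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.figure.colorbar(sc, ax=ax, shrink=0.8)
    return ax.figure


def standard_report_figures(outdir) -> list:
    """Render decoding AUC / GAT figures from a run's JSON results."""
    outdir = Path(outdir)
    figs = []
    dec = outdir / "decoding_results.json"
    if dec.exists():
        with open(dec) as f:
            results = json.load(f)
        for state, res in results.items():
            fig = plot_auc(res["times"], res["auc"],
                           mask=res.get("significant"), label=state)
            path = outdir / f"auc_{state}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            figs.append(path)
            if "gat_auc" in res:
                fig = plot_gat_matrix(res["gat_times"], res["gat_auc"])
                path = outdir / f"gat_{state}.png"
                fig.savefig(path, dpi=120, bbox_inches="tight")
                plt.close(fig)
                figs.append(path)
    return figs
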