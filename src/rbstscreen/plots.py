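"""Score-plot and S-plot renderings for fitted models."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .multivariate import OPLSDAResults, PCAResults

__all__ = ["plot_pca_scores", "plot_oplsda_scores", "plot_s_plot"]


def plot_pca_scores(pca: PCAResults, groups: pd.Series | None = None,
                    path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    t = pca.scores
    if groups is not None:
        for g, marker in zip(sorted(groups.unique()), "os^v"):
            m = groups.loc[t.index] == g
            ax.scatter(t.loc[m, "t1"], t.loc[m, "t2"], label=str(g),
                       marker=marker, alpha=0.7)
        ax.legend()
    else:
        ax.scatter(t["t1"], t["t2"], alpha=0.7)
    ax.set_xlabel(f"t1 ({100 * pca.r2x[0]:.1f}% of X)")
    ax.set_ylabel(f"t2 ({100 * pca.r2x[1]:.1f}% of X)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_oplsda_scores(opls: OPLSDAResults, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    t = opls.scores
    to = (opls.orthogonal_scores.iloc[:, 0]
          if opls.orthogonal_scores.shape[1] else pd.Series(0.0, index=t.index))
    y = opls.model.y
    for label, cls, marker in (("control", 0, "o"), ("rbst", 1, "s")):
        m = y == cls
        ax.scatter(t[m], to[m], label=label, marker=marker, alpha=0.7)
    ax.set_xlabel("t1 (predictive)")
    ax.set_ylabel("to1 (orthogonal)")
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_s_plot(s_plot: pd.DataFrame, path: str | Path | None = None,
                annotate: bool = True):
    fig, ax = plt.subplots(figsize=(5, 4))
    sp = s_plot[s_plot["defined"]] if "defined" in s_plot else s_plot
    ax.scatter(sp["p1"], sp["pcorr1"], alpha=0.8)
    if annotate:
        for _, r in sp.iterrows():
            ax.annotate(r["gene"], (r["p1"], r["pcorr1"]), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("p1 (covariance with t1)")
    ax.set_ylabel("p(corr)1 (correlation with t1)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_ylim(-1.05, 1.05)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
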