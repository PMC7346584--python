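"""Figures and summary tables for a compared pipeline run.

Produces the cumulative-frequency plots the field uses to present
radial-position data: one figure per metric with the cumulative
histogram (ECDF) of each group, optionally overlaid with the
closed-form projection-model curve (e.g. the surface-placement law
F(x) = 1 - sqrt(1 - x**2) for resting lymphocytes), plus a medians
summary table.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .nullmodel import PlacementModel, closed_form_cdf  # noqa: E402

__all__ = ["render_report", "plot_cumulative"]


def plot_cumulative(ax, values, label: str) -> None:
    """ECDF step curve of one group on ``ax``."""
    xs = np.sort(np.asarray(values, dtype=float))
    ax.step(xs, np.arange(1, xs.size + 1) / xs.size, where="post", label=label)


def render_report(outdir, model_curve: str | None = None) -> int:
    """Render figures + medians summary from compare-stage outputs.

    ``model_curve`` may name a placement law ("surface", "ball") to
    overlay on radius-metric plots.  Returns the number of figures
    written; an empty comparison produces a note instead of failing.
    """
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    comparison = pd.read_csv(outdir / "comparison.csv")
    if comparison.empty:
        (outdir / "medians_summary.csv").write_text("metric,median_a,median_b\n")
        (figdir / "NOTE.txt").write_text("no comparisons to plot\n")
        return 0
    n_figs = 0
    for hist_path in sorted(outdir.glob("hist_*.csv")):
        metric = hist_path.stem[len("hist_"):]
        hist = pd.read_csv(hist_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        for group, sub in hist.groupby("group"):
            ax.step(sub.bin_upper, sub.cumulative_count / sub.n.iloc[0],
                    where="post", label=str(group))
        if model_curve and metric in ("r", "r_agnor"):
            xs = np.linspace(0, 1, 201)
            law = (PlacementModel.surface() if model_curve == "surface"
                   else PlacementModel.ball())
            ax.plot(xs, closed_form_cdf(law, xs), "k:", label=f"{model_curve} model")
        ax.set_xlabel(metric)
        ax.set_ylabel("cumulative frequency")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(figdir / f"cumulative_{metric}.png", dpi=120)
        plt.close(fig)
        n_figs += 1
    med = comparison[~comparison.get("skipped", False)] if "skipped" in comparison else comparison
    cols = [c for c in ("metric", "median_a", "median_b", "D", "ks_sig", "U", "p",
                        "significant") if c in med.columns]
    med[cols].to_csv(outdir / "medians_summary.csv", index=False, float_format="%.6g")
    return n_figs
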