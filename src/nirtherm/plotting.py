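"""Diagnostic plots: score-temperature, score-composition, and correlation plots.

Plots are artifacts for human inspection; all numeric assertions live in the
tabular outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .phantoms import PhantomSpec
from .screening import CONSTITUENTS, PCAResult

__all__ = [
    "score_temperature_plot",
    "score_composition_plot",
    "correlation_plot",
    "lopo_correlation_plots",
]

_CMAP = plt.get_cmap("tab10")


def _phantom_colors(pids: np.ndarray) -> dict:
    return {pid: _CMAP(i % 10) for i, pid in enumerate(np.unique(pids))}


def score_temperature_plot(
    pca: PCAResult,
    temperatures: np.ndarray,
    phantom_ids: np.ndarray,
    n_components: int = 5,
    path: str | Path | None = None,
):
    """Scores of the leading components against assigned temperature."""
    k = min(n_components, pca.n_components)
    fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 3.0), squeeze=False)
    colors = _phantom_colors(np.asarray(phantom_ids))
    for j in range(k):
        ax = axes[0, j]
        for pid, color in colors.items():
            sel = np.asarray(phantom_ids) == pid
            ax.plot(
                np.asarray(temperatures)[sel], pca.scores[sel, j], ".",
                color=color, ms=3, label=f"phantom {pid}" if j == 0 else None,
            )
        ax.set_xlabel("assigned temperature (degC)")
        ax.set_ylabel(f"PC {j + 1} score")
    axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def score_composition_plot(
    pca: PCAResult,
    phantom_ids: np.ndarray,
    phantoms: Sequence[PhantomSpec],
    n_components: int = 5,
    path: str | Path | None = None,
):
    """Scores against gelatin / Intralipid / water weight-percent."""
    k = min(n_components, pca.n_components)
    comp = {p.phantom_id: p for p in phantoms}
    pids = np.asarray(phantom_ids)
    fig, axes = plt.subplots(k, 3, figsize=(9.5, 2.6 * k), squeeze=False)
    colors = _phantom_colors(pids)
    for j in range(k):
        for c, name in enumerate(CONSTITUENTS):
            ax = axes[j, c]
            x = np.array([getattr(comp[int(p)], name) for p in pids])
            for pid, color in colors.items():
                sel = pids == pid
                ax.plot(x[sel], pca.scores[sel, j], ".", color=color, ms=3)
            ax.set_xlabel(name.replace("_pct", " (wt%)"))
            ax.set_ylabel(f"PC {j + 1}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def correlation_plot(
    assigned_cal: np.ndarray,
    predicted_cal: np.ndarray,
    assigned_pred: np.ndarray | None = None,
    predicted_pred: np.ndarray | None = None,
    path: str | Path | None = None,
    title: str = "",
):
    """Predicted vs assigned temperatures with the unity line."""
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    ax.plot(assigned_cal, predicted_cal, "o", ms=3, color="tab:red", label="calibration (CV)")
    if assigned_pred is not None:
        ax.plot(assigned_pred, predicted_pred, "o", ms=3, color="gold", label="prediction")
    lims = [19.0, 25.0]
    ax.plot(lims, lims, "k--", lw=1, label="unity")
    ax.set_xlabel("assigned temperature (degC)")
    ax.set_ylabel("predicted temperature (degC)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def lopo_correlation_plots(lopo_result, out_dir: str | Path) -> list[Path]:
    """One correlation plot per held-out phantom."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for h in lopo_result.holdouts:
        cv = h.results.cv_curve
        p = out_dir / f"lopo_phantom_{h.held_out:02d}.png"
        correlation_plot(
            cv.reference, cv.cv_predictions, h.reference, h.predicted,
            path=p, title=f"held-out phantom {h.held_out}",
        )
        paths.append(p)
    return paths
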