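"""Figure helpers: ROC curves, cross-species heat map, per-species radar chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import MetricSet, ROCCurve
from .experiments import CrossSpeciesMatrix

__all__ = ["plot_roc", "plot_heatmap", "plot_radar"]


def plot_roc(curves: dict[str, tuple[ROCCurve, float]], path: str | Path) -> Path:
    """One or more labelled ROC curves with their AUCs, plus the chance line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, (curve, auc) in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{label} (AUC={auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random (AUC=0.5)")
    ax.set_xlabel("False positive rate (1 - Sp)")
    ax.set_ylabel("True positive rate (Sn)")
    ax.legend(loc="lower right", fontsize=8)
    return _save(fig, path)


def plot_heatmap(matrix: CrossSpeciesMatrix, path: str | Path) -> Path:
    """Cross-species accuracy heat map (train species = row, test = column)."""
    acc = matrix.accuracy
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(acc.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(acc.columns)), acc.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(acc.index)), acc.index)
    ax.set_xlabel("test species")
    ax.set_ylabel("training species")
    for i in range(acc.shape[0]):
        for j in range(acc.shape[1]):
            ax.text(j, i, f"{acc.values[i, j]:.2f}", ha="center", va="center",
                    color="w", fontsize=8)
    fig.colorbar(im, ax=ax, label="Acc")
    return _save(fig, path)


def plot_radar(per_species: dict[str, MetricSet], path: str | Path,
               metrics: tuple[str, ...] = ("Sn", "Sp", "Acc", "MCC", "AUC")) -> Path:
    """Radar chart of leave-one-species-out metrics, one axis per species."""
    species = list(per_species)
    angles = np.linspace(0, 2 * np.pi, len(species), endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    for name in metrics:
        vals = [per_species[sp].to_dict()[name] for sp in species]
        if any(v is None for v in vals):
            continue
        closed = np.concatenate([vals, vals[:1]])
        ax.plot(np.concatenate([angles, angles[:1]]), closed, label=name)
    ax.set_xticks(angles, species, fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.05), fontsize=8)
    return _save(fig, path)


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
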