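"""Plot helpers for ranking scores and ROC / precision-recall curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def ranking_bars(mft: pd.DataFrame, path, max_columns: int = 4) -> None:
    """Grouped bar chart of per-feature scores for the first few
    (classifier, measure) columns of a normalized MFT."""
    cols = list(mft.columns[:max_columns])
    n = len(mft)
    x = np.arange(n)
    width = 0.8 / max(len(cols), 1)
    fig, ax = plt.subplots(figsize=(max(6, n * 0.3), 4))
    for i, c in enumerate(cols):
        ax.bar(x + i * width, mft[c].to_numpy(), width, label=c)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(mft.index, rotation=90, fontsize=7)
    ax.set_ylabel("normalized score")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(points: np.ndarray, auc: float, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(points[:, 0], points[:, 1], lw=1.5)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"ROC (AUC = {auc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pr_plot(points: np.ndarray, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(points[:, 0], points[:, 1], lw=1.5, drawstyle="steps-post")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_title("precision-recall")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
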