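"""Plotting helpers: permutation-null histograms and importance summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .importance import ImportanceTable
from .signal_tests import PermutationTestResult


def plot_null_distribution(result: PermutationTestResult, path: str | Path, title: str = "") -> None:
    """Histogram of null PC scores with the original PC marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.null_pcs, bins=40, color="steelblue", alpha=0.8, label="permuted test sets")
    ax.axvline(result.original_pc, color="crimson", lw=2, label="original test set")
    ax.axvline(result.null_low, color="grey", ls="--", lw=1)
    ax.axvline(result.null_high, color="grey", ls="--", lw=1, label="null 95% interval")
    ax.set_xlabel("Pearson correlation")
    ax.set_ylabel("replicates")
    ax.set_title(title or result.mode)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance(imp: ImportanceTable, path: str | Path, top_n: int = 20) -> None:
    """Per-row attribution strip plot of the top features (most important on top)."""
    top = imp.table.head(top_n)
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(top) + 1.5))
    rng = np.random.default_rng(0)
    for i, row in enumerate(top.itertuples()):
        y = len(top) - 1 - i
        if imp.shap_values is not None and row.feature in imp.shap_values.columns:
            vals = imp.shap_values[row.feature].to_numpy()
            jitter = rng.uniform(-0.25, 0.25, size=len(vals))
            ax.scatter(vals, np.full_like(vals, y) + jitter, s=4, alpha=0.4, color="steelblue")
        else:
            ax.barh(y, row.mean_abs_shap, color="steelblue", height=0.6)
    ax.set_yticks(range(len(top)))
    labels = [f[:45] + ("…" if len(f) > 45 else "") for f in top["feature"][::-1]]
    ax.set_yticklabels(labels, fontsize=7)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("attribution to predicted V_max (h⁻¹); negative = faster acidification")
    ax.set_title(f"{imp.representation} model: top {len(top)} features")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
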