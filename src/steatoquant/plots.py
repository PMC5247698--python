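"""Optional SVG figures: bracket box plots and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .stats import BRACKET_LABELS, RocCurve, categorize_mfpa_series  # noqa: E402

__all__ = ["plot_bracket_boxes", "plot_roc"]


def plot_bracket_boxes(
    records: pd.DataFrame, variable: str, path: str | Path, ylabel: str | None = None
) -> Path:
    """Box plot of one variable across the mFPA brackets, written as SVG."""
    df = records[["mfpa_pct", variable]].dropna()
    brackets = categorize_mfpa_series(df["mfpa_pct"])
    groups = [
        df.loc[(brackets == b).to_numpy(), variable].to_numpy() for b in BRACKET_LABELS
    ]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(
        [g for g in groups if g.size],
        tick_labels=[b for b, g in zip(BRACKET_LABELS, groups) if g.size],
    )
    ax.set_xlabel("mFPA bracket (%)")
    ax.set_ylabel(ylabel or variable)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def plot_roc(curves: dict[str, RocCurve], path: str | Path) -> Path:
    """Overlayed ROC curves (one per labelled score), written as SVG."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, curve in curves.items():
        fpr = 1.0 - curve.specificity
        ax.plot(fpr, curve.sensitivity, label=f"{label} (AUROC {curve.auroc:.2f})")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
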