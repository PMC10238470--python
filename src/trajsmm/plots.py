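"""Trajectory figures: spaghetti plot and fitted class curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def spaghetti(data: pd.DataFrame, frac: float = 0.5, seed: int = 0, path=None):
    """Individual weight trajectories for a random subsample of subjects."""
    rng = np.random.default_rng(seed)
    subjects = data["subject_id"].unique()
    take = rng.choice(subjects, size=max(1, int(frac * len(subjects))), replace=False)
    sub = data[data["subject_id"].isin(take)]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for _, grp in sub.groupby("subject_id"):
        ax.plot(grp["month"], grp["weight_kg"], color="steelblue", alpha=0.15, lw=0.7)
    ax.set_xlabel("month of pregnancy")
    ax.set_ylabel("maternal weight (kg)")
    ax.set_title(f"Weight trajectories ({100 * frac:.0f}% of subjects)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def predicted_trajectories(fit, path=None):
    """Fitted class mean curves of an SMMResults object."""
    curves = fit.predicted_curves()
    sizes = fit.class_sizes()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, col in enumerate(curves.columns, start=1):
        ax.plot(curves.index, curves[col], marker="o", label=f"{col} (n={sizes[i]})")
    ax.set_xlabel("month of pregnancy")
    ax.set_ylabel("predicted weight (kg)")
    ax.set_title(f"Predicted trajectories, K={fit.n_classes}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
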