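"""Optional SVG figures: PCoA scatter, angle protractor, association heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["pcoa_scatter", "protractor_plot", "association_heatmap"]


def pcoa_scatter(coords: pd.DataFrame, cohorts: pd.Series,
                 clusters: pd.Series, path) -> None:
    """First two principal coordinates, colored by cohort, shaped by cluster."""
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = "osD^vP*Xh"
    cohort_levels = sorted(cohorts.unique())
    cmap = plt.get_cmap("tab10")
    for ci, cluster in enumerate(sorted(clusters.unique())):
        for hi, cohort in enumerate(cohort_levels):
            mask = (clusters == cluster) & (cohorts == cohort)
            if not mask.any():
                continue
            ax.scatter(coords.loc[mask.index[mask], coords.columns[0]],
                       coords.loc[mask.index[mask], coords.columns[1]],
                       c=[cmap(hi % 10)], marker=markers[ci % len(markers)],
                       s=25, alpha=0.8,
                       label=f"{cohort}/c{cluster}")
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def protractor_plot(summary: pd.DataFrame, reference: str, path) -> None:
    """Half-circle plot of mean cohort angles relative to the reference."""
    fig = plt.figure(figsize=(6, 4))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    sub = summary[(summary["cohort_a"] == reference)
                  | (summary["cohort_b"] == reference)]
    cmap = plt.get_cmap("tab10")
    for i, (_, row) in enumerate(sub.iterrows()):
        other = row["cohort_b"] if row["cohort_a"] == reference else row["cohort_a"]
        mean, sd = row["mean_angle"], row["sd_angle"]
        ax.plot([0, np.radians(mean)], [0, 1], lw=2, c=cmap(i % 10),
                label=f"{other}: {mean:.1f}° ± {sd:.1f}°")
        span = np.radians(np.linspace(max(0, mean - sd), min(180, mean + sd), 50))
        ax.fill_between(span, 0, 1, alpha=0.12, color=cmap(i % 10))
    ax.plot([0, 0], [0, 1], lw=3, c="black", label=f"{reference} (0°)")
    ax.set_yticks([])
    ax.legend(fontsize=7, loc="lower left", bbox_to_anchor=(0.9, 0.0))
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def association_heatmap(effects: pd.DataFrame, path) -> None:
    """Feature x covariate effect-size heatmap (positive orange, negative blue)."""
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * effects.shape[1], 1 + 0.3 * max(1, effects.shape[0]))
    )
    vals = effects.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(vals)) if vals.size else 1.0
    im = ax.imshow(vals, cmap="coolwarm", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(effects.shape[1]), effects.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(effects.shape[0]), effects.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="effect size")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
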