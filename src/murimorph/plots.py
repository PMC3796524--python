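"""Cosmetic figures: PC1/PC2 scatter with concentration ellipses, distance-vs-age."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .morphospace import concentration_ellipse, ellipse_polygon


def pc_scatter(pc_scores, labels, level, path):
    fig, ax = plt.subplots(figsize=(6, 5))
    xy = np.asarray(pc_scores)[:, :2]
    for g in sorted(set(labels)):
        mask = np.asarray(labels) == g
        pts = xy[mask]
        sc = ax.scatter(pts[:, 0], pts[:, 1], s=12, label=str(g), alpha=0.7)
        if mask.sum() >= 3:
            try:
                ell = concentration_ellipse(pts, level)
                ring = np.asarray(ellipse_polygon(ell, 180).exterior.coords)
                ax.plot(ring[:, 0], ring[:, 1], lw=1, color=sc.get_facecolor()[0])
            except ValueError:
                pass
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def distance_vs_age(basal_distances, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, df in basal_distances.groupby("group"):
        d = df["distance"].to_numpy()
        ax.errorbar(
            df["age_Ma"].to_numpy(),
            d,
            yerr=[d - df["ci_low"].to_numpy(), df["ci_high"].to_numpy() - d],
            fmt="o",
            label=str(g),
            ms=4,
        )
    ax.invert_xaxis()
    ax.set_xlabel("Age (Ma)")
    ax.set_ylabel("Distance from basal mean")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
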