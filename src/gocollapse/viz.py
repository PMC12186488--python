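"""Optional plotting: per-cluster paired l2fc boxplots for two species."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .crossspecies import JointClusterReport  # noqa: E402


def plot_cluster_l2fc(
    reports: Sequence[JointClusterReport],
    names: dict[str, str],
    path: Path,
) -> None:
    """Horizontal paired boxplots of per-cluster l2fc, one row per cluster.

    Mirrors the shared-cluster comparison panel: for every GO cluster the
    two species' fold-change distributions sit side by side, labelled by
    the representative term and annotated with each species' ratio n.
    """
    if not reports:
        return
    labels = sorted(reports[0].per_species)
    fig_h = max(2.0, 0.6 * len(reports) + 1.0)
    fig, ax = plt.subplots(figsize=(7, fig_h))
    yticks, ylabels = [], []
    colors = {labels[0]: "#c23b22", labels[1]: "#1f6fb2"} if len(labels) == 2 else {}
    for i, rep in enumerate(reports):
        base = len(reports) - 1 - i
        for j, label in enumerate(labels):
            view = rep.per_species[label]
            if view.box is None:
                continue
            b = view.box
            y = base + (0.18 if j == 0 else -0.18)
            color = colors.get(label, "black")
            ax.plot([b.whisker_lo, b.whisker_hi], [y, y], color=color, lw=1)
            ax.add_patch(
                plt.Rectangle((b.q1, y - 0.12), b.q3 - b.q1, 0.24,
                              facecolor="white", edgecolor=color, lw=1.2)
            )
            ax.plot([b.median, b.median], [y - 0.12, y + 0.12], color=color, lw=1.5)
            if b.outliers:
                ax.plot(b.outliers, [y] * len(b.outliers), "o",
                        mfc="none", mec=color, ms=4)
            ax.annotate(f"n={view.ratio_n:.2f}", (b.whisker_hi, y),
                        textcoords="offset points", xytext=(6, -3),
                        fontsize=7, color="gray")
        yticks.append(base)
        ylabels.append(names.get(rep.representative, rep.representative))
    ax.axvline(0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels, fontsize=8)
    ax.set_xlabel("log2 fold change (co-culture vs monoculture)")
    handles = [plt.Line2D([], [], color=colors.get(lab, "black"), label=lab)
               for lab in labels]
    ax.legend(handles=handles, fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
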