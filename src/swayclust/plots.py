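"""Box plots of sway parameters by cluster (figure-style outputs)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def parameter_boxplot(
    features: pd.DataFrame,
    parameter: str = "amplitude",
    axis: str = "X",
    side: str = "Left",
    out: str | None = None,
):
    """One box plot per body part: parameter value by cluster, one axis.

    Mirrors the per-part box-plot panels (medial-lateral amplitude or
    frequency by cluster).  COM is always included; sided parts use
    ``side``.
    """
    sub = features[
        (features["axis"] == axis) & (features["side"].isin([side, "None"]))
    ]
    parts = list(dict.fromkeys(sub["part"]))
    fig, axes = plt.subplots(1, len(parts), figsize=(3 * len(parts), 3.2))
    for ax, part in zip(axes, parts):
        block = sub[sub["part"] == part]
        clusters = sorted(block["cluster"].unique())
        ax.boxplot(
            [block.loc[block["cluster"] == c, parameter] for c in clusters],
            tick_labels=[str(c) for c in clusters],
        )
        ax.set_title(part)
        ax.set_xlabel("cluster")
    axes[0].set_ylabel(parameter)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
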