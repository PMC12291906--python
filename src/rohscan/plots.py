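"""Summary figures: length-bin proportions per group and F_ROH violins."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_bin_proportions(per_group: pd.DataFrame, path: str | Path) -> None:
    """Stacked barplot of per-group length-bin proportions.

    Expects the ``(count, proportion)`` multi-column frame returned by
    :func:`rohscan.stats.classify_lengths`.
    """
    props = per_group["proportion"]
    ax = props.plot(kind="bar", stacked=True, figsize=(7, 4), width=0.7)
    ax.set_ylabel("proportion of ROH segments")
    ax.set_xlabel("group")
    ax.legend(title="length bin (Mb)", bbox_to_anchor=(1.02, 1), loc="upper left")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()


def plot_froh_violin(froh: pd.DataFrame, path: str | Path) -> None:
    """Violin plot of per-sample F_ROH by group (needs a ``group`` column)."""
    groups = list(dict.fromkeys(froh["group"]))
    data = [froh.loc[froh["group"] == g, "froh"].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel("F_ROH")
    ax.set_xlabel("group")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
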