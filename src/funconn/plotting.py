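"""Group-mean metric-vs-sparsity curves (regenerable from the persisted
curve CSV alone)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort import GROUPS

_COLORS = {"HC": "#2b6cb0", "MHD_noCI": "#dd6b20", "MHD_CI": "#c53030"}


def plot_metric_curves(curves: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """One PNG per metric: group mean +/- sd across the sparsity sweep."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric, sub in curves.groupby("metric"):
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for grp in GROUPS:
            g = sub[sub["group"] == grp]
            if g.empty:
                continue
            agg = g.groupby("threshold")["value"].agg(["mean", "std"])
            ax.plot(agg.index, agg["mean"], label=grp, color=_COLORS.get(grp))
            ax.fill_between(
                agg.index, agg["mean"] - agg["std"], agg["mean"] + agg["std"],
                alpha=0.15, color=_COLORS.get(grp),
            )
        ax.set_xlabel("sparsity")
        ax.set_ylabel(metric)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out / f"curve_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
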