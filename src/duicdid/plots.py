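"""Optional chart exports: the simulated power curve and the grouped-bar
burden decomposition. Figures are plain matplotlib; callers pass a path to
save, nothing is displayed."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .burden import BurdenTable  # noqa: E402
from .power import MDEResult  # noqa: E402


def plot_power_curve(result: MDEResult, path) -> None:
    """Estimated power against the DiD odds ratio, with the MDE marked."""
    curve = result.curve.sort_values("or")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(curve["or"], curve["power"], yerr=2 * curve["mc_se"],
                fmt="o-", ms=3, lw=1, capsize=2)
    ax.axhline(0.8, color="grey", ls=":", lw=1)
    ax.axvline(result.mde_or, color="firebrick", ls="--", lw=1,
               label=f"MDE OR = {result.mde_or:.2f}")
    ax.set_xlabel("DiD odds ratio")
    ax.set_ylabel("estimated power")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_burden(table: BurdenTable, path) -> None:
    """Grouped bars: user population share and DUIC(-)/(+) episode shares
    by cannabis-use frequency."""
    tab = table.table
    cols = ["pop_share_pct", "minus_share_pct", "plus_share_pct"]
    labels = ["cannabis users", "DUIC(-) episodes", "DUIC(+) episodes"]
    x = np.arange(len(tab.index))
    width = 0.27
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for i, (col, lab) in enumerate(zip(cols, labels)):
        vals = tab[col].to_numpy(dtype=float)
        err = None
        if f"{col}_low" in tab.columns:
            err = np.vstack([vals - tab[f"{col}_low"],
                             tab[f"{col}_high"] - vals])
            err = np.clip(err, 0, None)
        ax.bar(x + (i - 1) * width, vals, width, yerr=err, capsize=2,
               label=lab)
    ax.set_xticks(x, [f.replace("_", " ") for f in tab.index])
    ax.set_ylabel("share (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
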