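"""Panel-grid figures for sweep output (optional; requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_RESPONSES = [
    ("mu_star", "ESS arrival date"),
    ("n_star", "equilibrium density n*"),
    ("f_star", "fraction of young f*"),
    ("gradient_after", "selection gradient after shift"),
    ("density_ratio", "n2*/n1*"),
    ("young_ratio", "f2/f1"),
]


def plot_sweep(df: pd.DataFrame, path) -> None:
    """Six-panel summary of a one-parameter sweep table.

    Baseline panels (top row) show the ESS and its equilibrium against the
    varied parameter; response panels (bottom row) show one line per shift
    scenario.  Rows flagged extinct or nonviable break the lines, mirroring
    how a collapsed population leaves no equilibrium to plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vary = df["vary_param"].iloc[0]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), constrained_layout=True)
    ok = df[df["status"] != "nonviable"]
    baseline = ok.drop_duplicates("vary_value")
    for ax, (col, title) in zip(axes.flat, _RESPONSES):
        if col in ("mu_star", "n_star", "f_star"):
            ax.plot(baseline["vary_value"], baseline[col], color="k")
        else:
            for label, grp in ok.groupby("scenario"):
                shown = grp.where(grp["status"] == "ok")
                ax.plot(grp["vary_value"], shown[col], label=label)
            ax.legend(fontsize=7)
            ax.axhline(0.0 if col == "gradient_after" else 1.0, lw=0.5, ls=":", color="grey")
        ax.set_title(title, fontsize=9)
        ax.set_xlabel(vary)
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
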