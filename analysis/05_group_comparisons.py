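#!/usr/bin/env python
"""Group statistics and summary figure.

Compares per-cell oscillation frequency and mean dF/F0 between tip, stalk
and non-budding DA cells of the wild-type cohort (Student's t test, alpha =
0.05), writes the comparison table, and draws the per-cell dot plots.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from caosc import io_formats, report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    wt = ROOT / "results" / "runs" / "wildtype"
    metrics = io_formats.read_table(wt / "metrics.csv", "metrics")
    ann = io_formats.read_table(wt / "annotations.csv", "annotations").set_index("cell_id")
    metrics["role"] = [ann.loc[c]["role"] for c in metrics["cell_id"]]

    rows = []
    for col, label in (("frequency_per_min", "frequency"),
                       ("mean_dff", "mean_dff")):
        groups = {r: metrics.loc[metrics["role"] == r, col].to_numpy()
                  for r in ("tip", "stalk", "da")}
        for a, b in (("tip", "stalk"), ("tip", "da"), ("stalk", "da")):
            res = report.compare_groups(groups[a], groups[b], labels=(a, b))
            rows.append(dict(
                quantity=label, group_a=a, group_b=b,
                mean_a=res.means[0], mean_b=res.means[1],
                n_a=res.n[0], n_b=res.n[1],
                t=res.t_statistic, p=res.p_value,
                significant=res.significant))
            stars = "***" if res.p_value < 1e-3 else (
                "*" if res.significant else "NS")
            print(f"{label}: {a} ({res.means[0]:.3f}, n={res.n[0]}) vs "
                  f"{b} ({res.means[1]:.3f}, n={res.n[1]}): "
                  f"t={res.t_statistic:.2f}, p={res.p_value:.2g} {stars}")
    out = ROOT / "results" / "group_comparisons.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"comparison table -> {out}")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = ROOT / "results" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    roles = ["tip", "stalk", "da"]
    for ax, col, label in zip(
        axes, ("frequency_per_min", "mean_dff"),
        ("Ca$^{2+}$ oscillation frequency (min$^{-1}$)", "mean $\\Delta F/F_0$"),
    ):
        for i, role in enumerate(roles):
            vals = metrics.loc[metrics["role"] == role, col].to_numpy()
            x = np.full(len(vals), i) + np.linspace(-0.12, 0.12, max(len(vals), 1))
            ax.plot(x, vals, "o", ms=4, alpha=0.7)
            ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k", lw=1.5)
        ax.set_xticks(range(len(roles)))
        ax.set_xticklabels(roles)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(fig_dir / "dotplots_wildtype.png", dpi=150)
    print(f"dot plots -> {fig_dir / 'dotplots_wildtype.png'}")


if __name__ == "__main__":
    main()
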