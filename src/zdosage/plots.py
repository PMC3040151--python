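"""Optional matplotlib figures mirroring the standard dosage-compensation views."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dosage import classify_sex_bias_series, density_log2mf


def density_plot(mf_table, path):
    """Kernel densities of log2(m:f) for autosomal vs Z-linked genes."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, mask, color in (
        ("autosomes", mf_table["chromosome"] != "Z", "black"),
        ("Z", mf_table["chromosome"] == "Z", "red"),
    ):
        vals = mf_table.loc[mask, "log2_mf"].to_numpy()
        if len(vals) >= 2 and np.ptp(vals) > 0:
            grid, dens = density_log2mf(vals)
            ax.plot(grid, dens, color=color, label=label)
            ax.axvline(vals.mean(), color=color, linestyle=":")
    ax.set_xlabel("log2(m:f)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def chromosome_boxplot(mf_table, path, min_genes: int = 5):
    """Per-chromosome boxplots of the m:f ratio."""
    counts = mf_table["chromosome"].value_counts()
    chroms = sorted(counts.index[counts >= min_genes], key=lambda c: (c == "Z", c.zfill(3)))
    data = [mf_table.loc[mf_table["chromosome"] == c, "mf_ratio"].to_numpy() for c in chroms]
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(chroms)), 4))
    ax.boxplot(data, tick_labels=[f"{c}\n({counts[c]})" for c in chroms])
    ax.axhline(1.0, linestyle=":", color="grey")
    ax.set_ylabel("m:f ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bias_class_boxplot(mf_table, path):
    """Expression level by sex-bias class, one panel pair per sex."""
    classes = classify_sex_bias_series(mf_table["mf_ratio"])
    order = ["female_biased", "unbiased", "male_biased"]
    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels = [], []
    for cls in order:
        mask = (classes == cls).to_numpy()
        if mask.sum() == 0:
            continue
        for col, sex in (("mean_m", "m"), ("mean_f", "f")):
            data.append(np.log2(mf_table.loc[mask, col].to_numpy()))
            labels.append(f"{cls}\n{sex}")
    if data:
        ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
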