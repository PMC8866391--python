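"""Plotting helpers for the panel-level summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_sfs(sfs: pd.DataFrame, ax=None, categories=None):
    """Stacked site-frequency-spectrum bars, coloured by germplasm category.

    ``sfs`` is the table from :func:`allelemine.diversity.sfs_table`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cats = categories or [
        c for c in sfs.columns if c not in ("freq_low", "freq_high", "count")
    ]
    x = sfs["freq_low"].to_numpy()
    width = (sfs["freq_high"] - sfs["freq_low"]).to_numpy()
    bottom = np.zeros(len(sfs))
    for cat in cats:
        vals = sfs[cat].to_numpy()
        ax.bar(x, vals, width=width, bottom=bottom, align="edge", label=cat)
        bottom += vals
    ax.set_xlabel("alternative allele frequency")
    ax.set_ylabel("number of SNPs")
    ax.legend(frameon=False)
    return ax


def plot_cn_by_latitude(
    cn_table: pd.DataFrame,
    metadata: pd.DataFrame,
    genes=("HvCBF2a", "HvCBF4b"),
    ax=None,
):
    """Scatter of summed gene copy number against sampling latitude, with
    marker size proportional to the copy-number sum."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = cn_table[cn_table["gene_id"].isin(genes)]
    summed = sub.groupby("sample_id")["cn_ratio"].sum().rename("cn_sum")
    merged = metadata.merge(
        summed, left_on="sample_id", right_index=True, how="inner"
    ).dropna(subset=["latitude"])
    ax.scatter(
        merged["latitude"],
        merged["cn_sum"],
        s=10 * merged["cn_sum"],
        alpha=0.5,
        edgecolors="none",
    )
    ax.set_xlabel("latitude (degrees)")
    ax.set_ylabel(f"summed copy number ({' + '.join(genes)})")
    return ax
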