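"""Report figures rendered from the pipeline's result tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def bundle_vs_sum_figure(wtp: pd.DataFrame, curve: pd.DataFrame,
                         path: Path) -> None:
    """Bundle bid against the summed member bids, with the fitted curve."""
    items = wtp[wtp.trial_type == "item"]
    key = {(r.subject_id, r.day, int(r.item_id)): r.bid
           for r in items.itertuples(index=False)}
    bundles = wtp[wtp.trial_type == "bundle"]
    sums = np.array([
        key[(r.subject_id, r.day, int(r.left_item))]
        + key[(r.subject_id, r.day, int(r.right_item))]
        for r in bundles.itertuples(index=False)])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hexbin(sums, bundles.bid, gridsize=40, cmap="Blues", mincnt=1)
    lim = max(sums.max(), 20.0)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="additive")
    ax.plot(curve.sum_value, curve.predicted_bundle_value, "r-", lw=2,
            label="fitted")
    ax.set_xlabel("sum of item bids ($)")
    ax.set_ylabel("bundle bid ($)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def decoding_split_figure(group: pd.DataFrame, path: Path) -> None:
    """Mean accuracy per split with significance markers."""
    sub = group[~group.split.str.startswith("diff_")]
    agg = sub.groupby("split").agg(acc=("mean_accuracy", "mean"),
                                   sig=("significant", "any"))
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(agg))
    ax.bar(x, agg.acc, color="steelblue")
    for i, (label, row) in enumerate(agg.iterrows()):
        if row.sig:
            ax.text(i, row.acc + 0.01, "*", ha="center", fontsize=14)
    ax.set_xticks(x, [s.replace("train_", "").replace("_test_", "→")
                      for s in agg.index], rotation=20)
    ax.set_ylabel("mean Pearson r")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def rsa_delta_bic_figure(table: pd.DataFrame, path: Path) -> None:
    """Summed delta-BIC per RSA family (more negative = better than null)."""
    summed = table.groupby("family").delta_bic.sum().sort_values()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.barh(summed.index, summed.values, color="indianred")
    ax.set_xlabel("summed $\\Delta$BIC vs null")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def attenuation_figure(fits: pd.DataFrame, path: Path) -> None:
    """Per-subject item and bundle value coefficients with group means."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for _, r in fits.iterrows():
        ax.plot([0, 1], [r.b_item, r.b_bundle], "o-", color="gray", alpha=0.5)
    ax.hlines(fits.b_item.mean(), -0.1, 0.1, color="k", lw=2)
    ax.hlines(fits.b_bundle.mean(), 0.9, 1.1, color="k", lw=2)
    ax.set_xticks([0, 1], ["item (b1)", "bundle (b1+b2)"])
    ax.set_ylabel("value coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
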