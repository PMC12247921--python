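"""Cross-condition value decoding from multivoxel patterns.

A ridge-regression decoder (alpha = 10^3) is trained on the trials of one
trial type (single items or bundles) from all runs but one, and its
predictions on the held-out run are scored separately for each trial type
with a Pearson correlation against the true values — leave-one-run-out
cross-validation yielding four accuracy metrics per subject and ROI:
within-item, within-bundle, and the two cross-condition splits. Decoding
value across conditions indicates a shared (condition-independent) value
code; decoding only within a condition indicates a condition-specific one.

Group inference uses two-sided one-sample Wilcoxon signed-rank tests of the
per-subject accuracies against chance (r = 0), Benjamini-Hochberg FDR
corrected across ROIs at q = 0.05, and paired signed-rank tests for
condition differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from statsmodels.stats.multitest import multipletests

from .synth import VoxelPatternDataset

logger = logging.getLogger(__name__)

SPLITS = (
    "train_item_test_item",
    "train_item_test_bundle",
    "train_bundle_test_bundle",
    "train_bundle_test_item",
)


@dataclass
class DecodingConfig:
    alpha: float = 1e3  # ridge penalty
    q_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def zscore_by_condition(values, trial_types) -> np.ndarray:
    """Z-score values within each trial type (population-sd convention)."""
    values = np.asarray(values, dtype=float)
    trial_types = np.asarray(trial_types)
    out = np.empty_like(values)
    for tt in np.unique(trial_types):
        m = trial_types == tt
        sd = values[m].std()
        if sd == 0 or m.sum() < 2:
            raise ValueError(f"condition {tt!r} has no value variance")
        out[m] = (values[m] - values[m].mean()) / sd
    return out


def cross_decode(
    data: VoxelPatternDataset,
    config: DecodingConfig = DecodingConfig(),
    train_conditions: tuple[str, ...] = ("item", "bundle"),
) -> pd.DataFrame:
    """Leave-one-run-out cross-condition decoding for one subject/ROI.

    Returns one row per (train condition, test condition) with the mean
    Pearson r across folds and the per-fold values. Runs are identified by
    the (day, run) pair; folds with fewer than two test trials of a
    condition are skipped with a warning.
    """
    meta = data.meta
    y = zscore_by_condition(meta.value.to_numpy(), meta.trial_type.to_numpy())
    run_id = list(zip(meta.day, meta.run))
    runs = sorted(set(run_id))
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    run_arr = np.array([runs.index(r) for r in run_id])
    tt = meta.trial_type.to_numpy()

    rows = []
    for train_tt in train_conditions:
        fold_r: dict[str, list[float]] = {"item": [], "bundle": []}
        for k in range(len(runs)):
            train_m = (run_arr != k) & (tt == train_tt)
            model = Ridge(alpha=config.alpha)
            model.fit(data.patterns[train_m], y[train_m])
            for test_tt in ("item", "bundle"):
                test_m = (run_arr == k) & (tt == test_tt)
                if test_m.sum() < 2:
                    logger.warning(
                        "fold %d: <2 %s test trials, skipping", k, test_tt
                    )
                    continue
                pred = model.predict(data.patterns[test_m])
                if np.std(pred) == 0:
                    r = 0.0
                else:
                    r = float(stats.pearsonr(pred, y[test_m])[0])
                fold_r[test_tt].append(r)
        for test_tt in ("item", "bundle"):
            rows.append(
                {
                    "subject_id": meta.subject_id.iloc[0],
                    "roi_label": data.roi_label,
                    "split": f"train_{train_tt}_test_{test_tt}",
                    "accuracy": float(np.mean(fold_r[test_tt])),
                    "n_folds": len(fold_r[test_tt]),
                    "fold_r": fold_r[test_tt],
                }
            )
    return pd.DataFrame(rows)


def group_decoding_tests(
    results: pd.DataFrame, q_fdr: float = 0.05
) -> pd.DataFrame:
    """Group-level significance of decoding accuracies per ROI and split.

    Two-sided one-sample Wilcoxon signed-rank tests of the per-subject mean
    r against 0, BH-FDR corrected across ROIs within each split; paired
    signed-rank tests of within- vs cross-condition differences are
    appended (splits prefixed ``diff_``), likewise corrected. All-zero
    samples get p = 1 by convention.
    """
    if results.groupby(["roi_label", "split"]).subject_id.nunique().min() < 5:
        raise ValueError("need >=5 subjects per ROI/split for group tests")

    def _wilcoxon(x: np.ndarray) -> float:
        x = x[x != 0]
        if x.size == 0:
            return 1.0
        return float(stats.wilcoxon(x, alternative="two-sided").pvalue)

    rows = []
    for split in results.split.unique():
        sub = results[results.split == split]
        for roi, grp in sub.groupby("roi_label"):
            acc = grp.accuracy.to_numpy()
            rows.append(
                {
                    "split": split,
                    "roi_label": roi,
                    "mean_accuracy": float(acc.mean()),
                    "p_raw": _wilcoxon(acc),
                    "n_subjects": len(acc),
                }
            )
    # paired condition-difference tests per train condition
    wide = results.pivot_table(
        index=["subject_id", "roi_label"], columns="split", values="accuracy"
    )
    for train_tt in ("item", "bundle"):
        a = f"train_{train_tt}_test_{train_tt}"
        other = "bundle" if train_tt == "item" else "item"
        b = f"train_{train_tt}_test_{other}"
        if a in wide.columns and b in wide.columns:
            diff = (wide[a] - wide[b]).rename("d").reset_index()
            for roi, grp in diff.groupby("roi_label"):
                d = grp.d.to_numpy()
                rows.append(
                    {
                        "split": f"diff_{a}_vs_{b}",
                        "roi_label": roi,
                        "mean_accuracy": float(d.mean()),
                        "p_raw": _wilcoxon(d),
                        "n_subjects": len(d),
                    }
                )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    table["significant"] = False
    for split in table.split.unique():
        m = table.split == split
        rej, p_adj, *_ = multipletests(
            table.loc[m, "p_raw"], alpha=q_fdr, method="fdr_bh"
        )
        table.loc[m, "p_fdr"] = p_adj
        table.loc[m, "significant"] = rej
    return table


def ridge_normal_equations(X: np.ndarray, y: np.ndarray, alpha: float):
    """Brute-force ridge oracle: centered normal equations with intercept.

    Matches sklearn's Ridge (intercept unpenalized).
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    b = y.mean() - X.mean(axis=0) @ w
    return w, b


def voxelwise_value_regression(
    data: VoxelPatternDataset,
    variants: tuple[str, ...] = ("absolute", "zscore_by_condition", "value_minus_reference"),
) -> pd.DataFrame:
    """Compare value regressors by how well they explain the voxel patterns.

    For each variant, every voxel is regressed on [value regressor,
    trial-type indicator, button-side indicator, intercept]; the table
    reports the summed log-likelihood and mean R^2 across voxels plus the
    ROI-mean-signal fit — a region-level analogue of comparing normalized
    vs absolute value regressors. The nuisance-only model is included as
    ``null``. Collinear variants are flagged.
    """
    meta = data.meta
    raw = meta.value.to_numpy(float)
    tt = (meta.trial_type.to_numpy() == "bundle").astype(float)
    side = (meta.button_side.to_numpy() == "right").astype(float)
    regs: dict[str, np.ndarray | None] = {"null": None}
    for v in variants:
        if v == "absolute":
            regs[v] = raw
        elif v == "zscore_by_condition":
            regs[v] = zscore_by_condition(raw, meta.trial_type.to_numpy())
        elif v == "value_minus_reference":
            if "reference_amount" not in meta:
                raise ValueError("metadata lacks reference amounts")
            regs[v] = raw - meta.reference_amount.to_numpy(float)
        else:
            raise ValueError(f"unknown variant {v!r}")

    Y = data.patterns
    n = len(meta)
    rows = []
    base = np.column_stack([np.ones(n), tt, side])
    for name, reg in regs.items():
        X = base if reg is None else np.column_stack([base, reg])
        collinear = np.linalg.matrix_rank(X) < X.shape[1]
        if collinear:
            warnings.warn(f"variant {name}: collinear design")
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        rss_vox = (resid**2).sum(axis=0)
        s2 = np.maximum(rss_vox / n, 1e-300)
        ll = float((-0.5 * n * (np.log(2 * np.pi * s2) + 1)).sum())
        tss_vox = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        r2 = float(np.mean(1 - rss_vox / np.maximum(tss_vox, 1e-300)))
        # ROI mean signal fit
        ym = Y.mean(axis=1)
        bm, *_ = np.linalg.lstsq(X, ym, rcond=None)
        rm = ym - X @ bm
        r2_mean = 1 - float((rm**2).sum()) / max(float(((ym - ym.mean()) ** 2).sum()), 1e-300)
        rows.append(
            {
                "variant": name,
                "loglik_sum": ll,
                "mean_r2": r2,
                "roi_mean_r2": r2_mean,
                "k_regressors": X.shape[1],
                "collinear": collinear,
            }
        )
    return pd.DataFrame(rows)
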