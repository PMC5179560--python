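"""Relative qPCR quantification (2^-ddCt) with outlier handling and group tests.

Each sample's target-gene Ct is normalized to the mean Ct of stably
expressed reference genes (dCt); ddCt subtracts the control-group mean dCt;
the per-sample fold change is 2^-ddCt, renormalized so the control-group
mean fold is exactly 1.  Outliers are screened per group with a two-sided
Grubbs test (a "2sd" mode removing points beyond two standard deviations is
available).  Stressed vs control folds are compared with an unpaired
two-tailed t-test when an F-test accepts equal variances, otherwise with a
two-tailed Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrMeasurements:
    """Per-sample Ct values for a target gene and reference genes.

    ``table``: one row per sample with columns ``sample_id``, ``group``
    (stress / control), ``ct_target``, and one ``ct_<ref>`` column per
    reference gene.
    """

    table: pd.DataFrame
    target: str
    references: list[str]

    def __post_init__(self) -> None:
        needed = ["sample_id", "group", "ct_target"] + [f"ct_{r}" for r in self.references]
        missing = [c for c in needed if c not in self.table.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        bad_group = set(self.table["group"]) - {"stress", "control"}
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        ct_cols = ["ct_target"] + [f"ct_{r}" for r in self.references]
        for col in ct_cols:
            nan_rows = self.table.loc[self.table[col].isna(), "sample_id"]
            if len(nan_rows):
                raise ValueError(
                    f"missing Ct value in column {col!r} for sample {nan_rows.iloc[0]!r}"
                )

    @classmethod
    def from_long(cls, long: pd.DataFrame, target: str, references: list[str]) -> "QpcrMeasurements":
        """Build from a long table with columns sample, group, gene, ct."""
        wide = long.pivot_table(index=["sample", "group"], columns="gene", values="ct")
        wide = wide.reset_index()
        genes = [target] + references
        missing = [g for g in genes if g not in wide.columns]
        if missing:
            raise ValueError(f"genes absent from Ct table: {missing}")
        tab = pd.DataFrame(
            {
                "sample_id": wide["sample"],
                "group": wide["group"],
                "ct_target": wide[target],
            }
        )
        for r in references:
            tab[f"ct_{r}"] = wide[r]
        return cls(tab, target, references)


@dataclass
class QpcrGroupResult:
    """Stress vs control comparison of per-sample fold changes."""

    target: str
    fold_changes: pd.DataFrame  # sample_id, group, fold
    control_mean: float
    stress_mean: float
    test_used: str  # "t" or "mann-whitney"
    statistic: float
    df: float
    p_value: float
    outliers_removed: list[str] = field(default_factory=list)


def delta_delta_ct(data: QpcrMeasurements) -> pd.DataFrame:
    """Per-sample fold changes by the 2^-ddCt rule.

    dCt = Ct_target - mean(Ct_references); ddCt = dCt - mean(dCt over
    control samples); fold = 2^-ddCt, then rescaled so the control-group
    mean fold is exactly 1.
    """
    tab = data.table
    if not (tab["group"] == "control").any():
        raise ValueError("at least one control sample is required")
    ref_cols = [f"ct_{r}" for r in data.references]
    d_ct = tab["ct_target"] - tab[ref_cols].mean(axis=1)
    control_mean_dct = d_ct[tab["group"] == "control"].mean()
    dd_ct = d_ct - control_mean_dct
    fold = np.power(2.0, -dd_ct)
    fold = fold / fold[tab["group"] == "control"].mean()
    return pd.DataFrame(
        {"sample_id": tab["sample_id"], "group": tab["group"], "fold": fold}
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from Student-t quantiles."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values,
    alpha: float = 0.05,
    mode: str = "grubbs",
    max_removals: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative outlier screen; returns (kept, removed) value arrays.

    ``grubbs`` mode removes the most extreme point while G = max|x - mean|/sd
    exceeds the two-sided critical value, re-testing after each removal up to
    ``max_removals``.  ``2sd`` mode removes points with |x - mean| > 2 sd.
    Fewer than 3 values (or zero spread) are returned unchanged with a warning.
    """
    if mode not in ("grubbs", "2sd"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    x = np.asarray(values, dtype=float)
    removed: list[float] = []
    for _ in range(max_removals):
        n = len(x)
        if n < 3:
            warnings.warn(f"only {n} values; outlier screen skipped")
            break
        s = x.std(ddof=1)
        if s == 0:
            warnings.warn("zero spread; outlier screen skipped")
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        if mode == "grubbs":
            g = dev[i] / s
            if g <= grubbs_critical_value(n, alpha):
                break
        else:
            if dev[i] <= 2 * s:
                break
        removed.append(float(x[i]))
        x = np.delete(x, i)
    return x, np.asarray(removed)


def compare_groups(
    stress_folds,
    control_folds,
    var_alpha: float = 0.05,
) -> tuple[str, float, float, float]:
    """Two-tailed stress vs control comparison with variance-based test choice.

    A two-sided F-test on the group variances at ``var_alpha`` decides:
    equal variances -> pooled-variance unpaired t-test; unequal -> two-tailed
    Mann-Whitney U.  Returns (test_used, statistic, df_or_nan, p).
    """
    a = np.asarray(stress_folds, dtype=float)
    b = np.asarray(control_folds, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples after outlier removal")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal_var = True
    else:
        hi, lo = max(va, vb), min(va, vb)
        n_hi = len(a) if va >= vb else len(b)
        n_lo = len(b) if va >= vb else len(a)
        if lo == 0:
            equal_var = False
        else:
            f = hi / lo
            p_f = 2 * stats.f.sf(f, n_hi - 1, n_lo - 1)
            equal_var = min(p_f, 1.0) >= var_alpha
    if equal_var:
        df = len(a) + len(b) - 2
        if va == 0 and vb == 0:
            # degenerate: no within-group spread at all
            same = a.mean() == b.mean()
            return "t", 0.0 if same else np.inf, float(df), 1.0 if same else 0.0
        res = stats.ttest_ind(a, b, equal_var=True)
        return "t", float(res.statistic), float(df), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann-whitney", float(res.statistic), float("nan"), float(res.pvalue)


def analyze_qpcr(
    data: QpcrMeasurements,
    alpha: float = 0.05,
    outlier_mode: str = "grubbs",
) -> QpcrGroupResult:
    """Full relative-quantification analysis for one target gene."""
    folds = delta_delta_ct(data)
    kept_rows = []
    removed_samples: list[str] = []
    for group in ("control", "stress"):
        sub = folds[folds["group"] == group]
        kept, removed = grubbs_filter(sub["fold"].to_numpy(), alpha=alpha, mode=outlier_mode)
        removed_set = list(removed)
        for _, row in sub.iterrows():
            if removed_set and row["fold"] in removed_set:
                removed_set.remove(row["fold"])
                removed_samples.append(row["sample_id"])
            else:
                kept_rows.append(row)
    kept_df = pd.DataFrame(kept_rows).reset_index(drop=True)
    # renormalize so the post-screen control mean fold is exactly 1
    ctrl_mean = kept_df.loc[kept_df["group"] == "control", "fold"].mean()
    kept_df["fold"] = kept_df["fold"] / ctrl_mean
    stress = kept_df.loc[kept_df["group"] == "stress", "fold"].to_numpy()
    control = kept_df.loc[kept_df["group"] == "control", "fold"].to_numpy()
    test_used, statistic, df, p = compare_groups(stress, control)
    return QpcrGroupResult(
        target=data.target,
        fold_changes=kept_df,
        control_mean=float(control.mean()),
        stress_mean=float(stress.mean()),
        test_used=test_used,
        statistic=statistic,
        df=df,
        p_value=p,
        outliers_removed=removed_samples,
    )
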