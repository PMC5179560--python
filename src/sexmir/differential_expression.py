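"""Precision-weighted differential expression for pooled RNA-seq libraries.

The modelling chain mirrors the voom/limma approach for count data:

1. filter features to those expressed (> ``filter_min_count`` reads) in at
   least ``filter_min_fraction`` of the samples of any one sex x condition
   cell;
2. transform counts to log2 counts-per-million with a 0.5-count offset;
3. estimate a mean-variance trend (LOWESS of sqrt residual SD against average
   log2 count) from unweighted gene-wise fits and convert it into
   per-observation precision weights;
4. fit a weighted gene-wise linear model on the group-means parameterization
   of the 2 x 2 sex x condition factorial, extracting within-sex stress
   contrasts;
5. shrink residual variances toward a common prior by empirical Bayes
   (method-of-moments on the scaled F distribution of sample variances) and
   test each contrast with a moderated t-statistic;
6. call a feature up / down / neutral per contrast using an uncorrected
   p-value cutoff and a linear fold-change threshold.

Normalization is plain library-size CPM; a compositional normalization such
as TMM is deliberately not applied (configurable via the ``lib_size``
argument of :func:`log_cpm` for callers that want to supply adjusted sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from sexmir.io_formats import CountMatrix, SampleDesign

GROUPS = ("male.control", "male.stress", "female.control", "female.stress")


@dataclass
class AnalysisThresholds:
    """Statistical cutoffs used throughout the pipeline.

    ``p_cut`` and ``fc_cut`` define differential expression (uncorrected
    p < 0.05 and linear fold change >= 1.3); ``filter_min_count`` /
    ``filter_min_fraction`` define the expression filter (> 5 reads in >= 80%
    of samples of some condition cell); ``enrich_neglogp`` is the
    overrepresentation significance rule (-log10 p >= 1.3);
    ``network_bh_alpha`` the BH cutoff for per-miR selection; the fixed
    overlap backgrounds are 19,827 candidate mRNAs and 781 candidate miRs.
    """

    p_cut: float = 0.05
    fc_cut: float = 1.3
    filter_min_count: int = 5
    filter_min_fraction: float = 0.8
    enrich_neglogp: float = 1.3
    network_bh_alpha: float = 0.05
    background_mrna: int = 19827
    background_mir: int = 781

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0, 1)")
        if self.fc_cut <= 1:
            raise ValueError("fc_cut must exceed 1")
        if not 0 < self.filter_min_fraction <= 1:
            raise ValueError("filter_min_fraction must lie in (0, 1]")

    @property
    def lfc_cut(self) -> float:
        return float(np.log2(self.fc_cut))


@dataclass
class ContrastSpec:
    """A named contrast over the four group means (must sum to zero)."""

    name: str
    vector: np.ndarray  # length 4 over GROUPS order

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (4,):
            raise ValueError("contrast vector must have length 4")
        if abs(self.vector.sum()) > 1e-12:
            raise ValueError(f"contrast {self.name!r} does not sum to zero")


def default_contrasts() -> list[ContrastSpec]:
    """Within-sex stress effects: stress minus control, per sex."""
    return [
        ContrastSpec("stress_in_males", np.array([-1.0, 1.0, 0.0, 0.0])),
        ContrastSpec("stress_in_females", np.array([0.0, 0.0, -1.0, 1.0])),
    ]


@dataclass
class DEResult:
    """Per-feature differential-expression results across contrasts.

    ``table`` has one row per feature with columns ``feature_id``,
    ``ave_expr`` (mean log2-CPM), and per contrast ``logFC_<name>``,
    ``t_<name>``, ``p_<name>``, ``dir_<name>``; plus the residual and
    moderated SDs and degrees of freedom shared across contrasts.
    """

    table: pd.DataFrame
    contrasts: list[str]
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def directional_list(self, contrast: str, direction: str) -> list[str]:
        col = f"dir_{contrast}"
        return list(self.table.loc[self.table[col] == direction, "feature_id"])

    def directions(self, contrast: str) -> pd.Series:
        return pd.Series(
            self.table[f"dir_{contrast}"].values, index=self.table["feature_id"].values
        )

    def log2fc(self, contrast: str) -> pd.Series:
        return pd.Series(
            self.table[f"logFC_{contrast}"].values, index=self.table["feature_id"].values
        )


# ---------------------------------------------------------------------------
# Filtering and transformation
# ---------------------------------------------------------------------------


def filter_low_counts(
    counts: CountMatrix,
    design: SampleDesign,
    thresholds: AnalysisThresholds | None = None,
) -> CountMatrix:
    """Keep features expressed in at least one experimental condition.

    A feature is retained iff, in some sex x condition cell, the fraction of
    samples with count strictly greater than ``filter_min_count`` is at least
    ``filter_min_fraction``.
    """
    thresholds = thresholds or AnalysisThresholds()
    design.check_matches(counts)
    keep = np.zeros(counts.n_features, dtype=bool)
    sample_pos = {s: j for j, s in enumerate(counts.sample_ids)}
    for sex in ("male", "female"):
        for cond in ("stress", "control"):
            cols = [sample_pos[s] for s in design.samples_in_cell(sex, cond)]
            cell = counts.counts[:, cols]
            frac = (cell > thresholds.filter_min_count).mean(axis=1)
            keep |= frac >= thresholds.filter_min_fraction
    if not keep.any():
        raise ValueError("no features pass filter")
    kept_ids = [f for f, k in zip(counts.feature_ids, keep) if k]
    return counts.subset_features(kept_ids)


def log_cpm(counts: CountMatrix, lib_size: np.ndarray | None = None) -> pd.DataFrame:
    """log2 counts-per-million with the voom offset:
    ``log2((count + 0.5) / (lib_size + 1) * 1e6)``."""
    if lib_size is None:
        lib_size = counts.counts.sum(axis=0).astype(float)
    else:
        lib_size = np.asarray(lib_size, dtype=float)
    if np.any(lib_size <= 0):
        bad = counts.sample_ids[int(np.argmin(lib_size))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    vals = np.log2((counts.counts + 0.5) / (lib_size + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def group_design_matrix(design: SampleDesign) -> pd.DataFrame:
    """Group-means (cell-means) design matrix over the four sex x condition groups."""
    labels = design.group_labels()
    X = pd.DataFrame(0.0, index=labels.index, columns=list(GROUPS))
    for s, g in labels.items():
        X.loc[s, g] = 1.0
    empty = [g for g in GROUPS if X[g].sum() == 0]
    if empty:
        raise ValueError(f"groups with no samples: {empty}")
    return X


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------


def voom_weights(
    logcpm: pd.DataFrame,
    counts: CountMatrix,
    design_matrix: pd.DataFrame,
    span: float = 0.5,
) -> pd.DataFrame:
    """Per-observation precision weights from the mean-variance trend.

    Unweighted gene-wise linear fits give residual SDs; a LOWESS trend of
    sqrt(SD) against average log2 count captures the count-level
    mean-variance relationship; each observation's fitted log2 count is then
    mapped through the trend (monotone interpolation, clamped at the trend
    range) and the weight is the predicted sqrt-SD to the power -4, i.e. the
    reciprocal of the predicted variance of the log-CPM value.
    """
    X = design_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"fewer residual df than required: {n} samples, {p} columns")
    Y = logcpm.to_numpy(dtype=float)

    beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    if rank < p:
        raise ValueError("singular design matrix")
    fitted = (X @ beta).T  # genes x samples, log-CPM scale
    resid = Y - fitted
    df_resid = n - p
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(sigma)

    lib_size = counts.counts.sum(axis=0).astype(float)
    # average log2 count: mean log-CPM shifted back to the count scale
    mean_logcpm = Y.mean(axis=1)
    ave_log_count = mean_logcpm + np.mean(np.log2(lib_size + 1.0)) - np.log2(1e6)

    trend = lowess(sqrt_sd, ave_log_count, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]

    # per-observation fitted log2 count
    fitted_log_count = fitted + np.log2(lib_size + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_log_count, tx, ty)  # clamped at range ends
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    w = pred_sqrt_sd**-4.0
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


# ---------------------------------------------------------------------------
# Weighted fits and contrasts
# ---------------------------------------------------------------------------


def fit_contrasts(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: SampleDesign,
    contrasts: Sequence[ContrastSpec] | None = None,
) -> pd.DataFrame:
    """Gene-wise weighted least squares on the group-means parameterization.

    Returns a frame with one row per feature: ``beta_<name>`` (the contrast
    estimate, a log2 fold change for the default contrasts),
    ``unscaled_sd_<name>`` (sqrt of c'(X'WX)^-1 c), residual SD ``s_g``, and
    residual degrees of freedom ``df``.
    """
    contrasts = list(contrasts) if contrasts is not None else default_contrasts()
    Xdf = group_design_matrix(design)
    Xdf = Xdf.loc[list(logcpm.columns)]
    X = Xdf.to_numpy(dtype=float)
    n, p = X.shape
    Y = logcpm.to_numpy(dtype=float)
    G = Y.shape[0]
    if weights is None:
        W = np.ones_like(Y)
    else:
        W = weights.loc[logcpm.index, logcpm.columns].to_numpy(dtype=float)
    if np.any(W <= 0) or not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite and positive")

    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    C = np.stack([c.vector for c in contrasts])  # k x p
    # batched weighted normal equations, one 4x4 system per gene
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X)
    XtWy = np.einsum("gn,np,gn->gp", W, X, Y)
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        raise ValueError("singular design matrix") from None
    beta = np.einsum("gpq,gq->gp", XtWX_inv, XtWy)
    resid = Y - beta @ X.T
    rss = (W * resid**2).sum(axis=1)
    s_g = np.sqrt(rss / df_resid)
    cb = beta @ C.T  # G x k
    cvar = np.einsum("kp,gpq,kq->gk", C, XtWX_inv, C)

    out: dict[str, np.ndarray] = {}
    for i, c in enumerate(contrasts):
        out[f"beta_{c.name}"] = cb[:, i]
        out[f"unscaled_sd_{c.name}"] = np.sqrt(cvar[:, i])

    res = pd.DataFrame(out, index=logcpm.index)
    res["s_g"] = s_g
    res["df"] = df_resid
    res["ave_expr"] = Y.mean(axis=1)
    return res


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled F prior (d0, s0^2) to sample variances.

    Matches the mean and variance of log(s^2) to the theoretical moments of a
    scaled chi-squared variable: with z = log(s^2),
    E[z] = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2).  An observed variance of
    log-variances at or below trigamma(df/2) yields d0 = inf (no gene-level
    variance heterogeneity beyond sampling noise).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("degenerate variances: all residual SDs are zero")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    if e_var == 0.0:
        # all sample variances identical: the data contradict the chi-squared
        # sampling model, and the common value is the only consistent prior
        return np.inf, float(np.exp(z[0]))
    # subtract the sampling variance of log s^2 under the chi-squared law
    target = e_var - float(polygamma(1, df / 2.0)) if len(e) > 1 else 0.0
    if target <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(target)
    s0sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def moderate_and_test(
    fits: pd.DataFrame,
    contrasts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Moderated t-tests for each contrast via empirical-Bayes shrinkage.

    Posterior variances s~^2 = (d0 s0^2 + df s^2) / (d0 + df); moderated
    t = beta / (s~ * unscaled_sd); two-sided p from t with d0 + df degrees of
    freedom.  d0 = inf collapses every posterior variance to s0^2.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 features to estimate the variance prior")
    if contrasts is None:
        contrasts = [c.removeprefix("beta_") for c in fits.columns if c.startswith("beta_")]
    s2 = fits["s_g"].to_numpy() ** 2
    df = float(fits["df"].iloc[0])
    d0, s0sq = estimate_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df
    out = fits.copy()
    out["s_moderated"] = np.sqrt(s2_post)
    out["df_prior"] = d0
    out["s0_sq"] = s0sq
    for name in contrasts:
        beta = fits[f"beta_{name}"].to_numpy()
        se = np.sqrt(s2_post) * fits[f"unscaled_sd_{name}"].to_numpy()
        t = beta / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        out[f"t_{name}"] = t
        out[f"p_{name}"] = p
    return out


# ---------------------------------------------------------------------------
# Direction calls
# ---------------------------------------------------------------------------


def classify_direction(
    log2fc: float, p: float, thresholds: AnalysisThresholds | None = None
) -> str:
    """``up`` / ``down`` / ``neutral`` from the uncorrected p and fold-change rule."""
    thresholds = thresholds or AnalysisThresholds()
    if p < thresholds.p_cut and log2fc >= thresholds.lfc_cut:
        return "up"
    if p < thresholds.p_cut and log2fc <= -thresholds.lfc_cut:
        return "down"
    return "neutral"


def _classify_vec(log2fc: np.ndarray, p: np.ndarray, thresholds: AnalysisThresholds) -> np.ndarray:
    out = np.full(len(log2fc), "neutral", dtype=object)
    sig = p < thresholds.p_cut
    out[sig & (log2fc >= thresholds.lfc_cut)] = "up"
    out[sig & (log2fc <= -thresholds.lfc_cut)] = "down"
    return out


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------


def run_differential_expression(
    counts: CountMatrix,
    design: SampleDesign,
    thresholds: AnalysisThresholds | None = None,
    contrasts: Sequence[ContrastSpec] | None = None,
) -> DEResult:
    """Filter, transform, weight, fit, moderate, and classify in one call."""
    thresholds = thresholds or AnalysisThresholds()
    contrasts = list(contrasts) if contrasts is not None else default_contrasts()
    filtered = filter_low_counts(counts, design, thresholds)
    lc = log_cpm(filtered)
    X = group_design_matrix(design).loc[list(lc.columns)]
    w = voom_weights(lc, filtered, X)
    fits = fit_contrasts(lc, w, design, contrasts)
    tested = moderate_and_test(fits, [c.name for c in contrasts])

    table = pd.DataFrame({"feature_id": list(tested.index)})
    table["ave_expr"] = tested["ave_expr"].to_numpy()
    table["s_g"] = tested["s_g"].to_numpy()
    table["s_moderated"] = tested["s_moderated"].to_numpy()
    table["df"] = tested["df"].to_numpy()
    table["df_prior"] = tested["df_prior"].to_numpy()
    for c in contrasts:
        lfc = tested[f"beta_{c.name}"].to_numpy()
        p = tested[f"p_{c.name}"].to_numpy()
        table[f"logFC_{c.name}"] = lfc
        table[f"t_{c.name}"] = tested[f"t_{c.name}"].to_numpy()
        table[f"p_{c.name}"] = p
        table[f"dir_{c.name}"] = _classify_vec(lfc, p, thresholds)
    return DEResult(table, [c.name for c in contrasts], thresholds)
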