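"""Dual-method discriminatory-taxon discovery.

Two independent arms are run over a normalized feature table and the same
subgroup labels, and only features flagged by both are reported as
consensus biomarkers:

1. an effect-size arm in the style of LEfSe: a Kruskal-Wallis screen at
   ``kw_alpha`` followed by a bootstrapped one-feature linear-discriminant
   effect size reported as log10(1 + |effect|), so the conventional
   "LDA score > 2" threshold applies;

2. a covariate-adjusted linear model: log-transformed abundance regressed
   on subgroup plus age and gender, with the subgroup term tested by a
   nested-model F comparison.

The same machinery applies unchanged to functional (KO / pathway) tables,
where the linear-model arm runs on log counts-per-million with optional
inverse-variance observation weights estimated from a fitted
mean-variance trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import kruskal
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .features import FeatureTable

__all__ = [
    "LefseConfig",
    "kruskal_screen",
    "lda_effect_size",
    "confounder_lm",
    "consensus",
    "run_consensus",
    "pathway_differential",
]


@dataclass(frozen=True)
class LefseConfig:
    """Settings for the effect-size arm.

    ``lda_min`` is the log10 effect-size threshold (the conventional
    "LDA > 2"); ``boot_fraction`` of each class is subsampled in each of
    ``n_boot`` bootstrap rounds.  By default effect sizes are measured on
    the abundance scale of the input table (CSS-normalized values in the
    pipeline), which keeps null features at realistic abundances below the
    threshold; set ``rescale_total`` (e.g. 1e6) to first rescale every
    sample to a common total, the convention of the published tool.
    """

    kw_alpha: float = 0.05
    lda_min: float = 2.0
    n_boot: int = 30
    boot_fraction: float = 2.0 / 3.0
    seed: int | None = None
    rescale_total: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.kw_alpha < 1:
            raise ValueError("kw_alpha must lie in (0, 1)")
        if self.lda_min <= 0:
            raise ValueError("lda_min must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.boot_fraction <= 1:
            raise ValueError("boot_fraction must lie in (0, 1]")


def _aligned(table: FeatureTable, labels: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    labels = pd.Series(labels).dropna()
    common = [s for s in table.sample_ids if s in set(labels.index)]
    if len(common) < 4:
        raise ValueError("too few labelled samples")
    return table.data[common], labels.reindex(common)


def kruskal_screen(
    table: FeatureTable, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature tie-corrected Kruskal-Wallis test across subgroups.

    Returns a DataFrame (feature -> kw_p, passed, reason).  Features that
    are constant across all samples have no defined rank statistic and
    fail the screen with reason ``constant``.
    """
    data, labels = _aligned(table, labels)
    group_idx = [np.flatnonzero(labels.values == g) for g in sorted(labels.unique())]
    if len(group_idx) < 2 or any(len(ix) < 2 for ix in group_idx):
        raise ValueError("need >=2 groups with >=2 samples each")
    rows = []
    for fid, values in data.iterrows():
        v = values.values
        if np.ptp(v) == 0:
            rows.append((fid, np.nan, False, "constant"))
            continue
        h, p = kruskal(*(v[ix] for ix in group_idx))
        rows.append((fid, p, bool(p < alpha), ""))
    out = pd.DataFrame(rows, columns=["feature_id", "kw_p", "passed", "reason"])
    return out.set_index("feature_id")


def lda_effect_size(
    table: FeatureTable, labels: pd.Series, cfg: LefseConfig = LefseConfig()
) -> pd.DataFrame:
    """Bootstrapped linear-discriminant effect size per feature.

    In each bootstrap round, ``boot_fraction`` of each class is drawn
    without replacement and class means are computed per feature
    (optionally after rescaling each sample to ``rescale_total``).  The
    effect size
    for a class pair is the class-mean difference along the one-feature
    discriminant axis (whose unit-normalised weight is +-1, so the
    combination of raw-mean difference and discriminant projection used by
    the published scheme reduces to the absolute mean difference).  The
    reported score is log10(1 + mean |effect|), maximised over class
    pairs, with the enriched group taken from full-data class means.
    """
    data, labels = _aligned(table, labels)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if cfg.rescale_total is not None:
        totals = data.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("samples with zero total abundance cannot be rescaled")
        x = (data / totals) * cfg.rescale_total  # features x samples
    else:
        x = data
    class_cols = {g: np.flatnonzero(labels.values == g) for g in classes}
    rng = np.random.default_rng(cfg.seed)
    xv = x.values
    n_feat = xv.shape[0]
    pair_list = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1 :]]
    effect_sum = {pair: np.zeros(n_feat) for pair in pair_list}
    for _ in range(cfg.n_boot):
        boot_means = {}
        for g, cols in class_cols.items():
            k = max(1, math.ceil(cfg.boot_fraction * len(cols)))
            pick = rng.choice(cols, size=k, replace=False)
            boot_means[g] = xv[:, pick].mean(axis=1)
        for pair in pair_list:
            a, b = pair
            effect_sum[pair] += np.abs(boot_means[a] - boot_means[b])
    pair_effects = np.column_stack([effect_sum[p] / cfg.n_boot for p in pair_list])
    best = pair_effects.max(axis=1)
    score = np.log10(1.0 + best)
    full_means = pd.DataFrame({g: xv[:, cols].mean(axis=1) for g, cols in class_cols.items()},
                              index=x.index)
    enriched = full_means.idxmax(axis=1)
    return pd.DataFrame(
        {"lda_score": score, "effect": best, "enriched_group": enriched},
        index=x.index,
    )


def _design_matrices(
    labels: pd.Series, covariates: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full and reduced (no-group) design matrices with intercept."""
    parts = [pd.get_dummies(labels.astype(str), prefix="group", drop_first=True, dtype=float)]
    cov_part = None
    if covariates is not None and len(covariates.columns) > 0:
        cov = covariates.copy()
        num_cols = []
        for col in cov.columns:
            if cov[col].dtype == object or str(cov[col].dtype) == "category":
                dummies = pd.get_dummies(cov[col].astype(str), prefix=col, drop_first=True, dtype=float)
                num_cols.append(dummies)
            else:
                num_cols.append(cov[[col]].astype(float))
        cov_part = pd.concat(num_cols, axis=1)
        parts.append(cov_part)
    full = pd.concat(parts, axis=1)
    full.insert(0, "const", 1.0)
    reduced_cols = ["const"] + (list(cov_part.columns) if cov_part is not None else [])
    reduced = full[reduced_cols]
    # collinearity check on non-constant columns, naming the offending pair
    check = full.drop(columns="const")
    if check.shape[1] >= 2:
        corr = check.corr().abs()
        for i, a in enumerate(corr.columns):
            for b in corr.columns[i + 1 :]:
                if corr.loc[a, b] > 0.9999:
                    raise ValueError(f"collinear covariates: {a} and {b}")
    if np.linalg.matrix_rank(full.values) < full.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    return full, reduced


def confounder_lm(
    table: FeatureTable,
    labels: pd.Series,
    covariates: pd.DataFrame,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted linear model per feature.

    Fits ``log(abundance + pseudocount) ~ group + age + gender`` by OLS and
    tests the group term via a nested-model F comparison (equivalent to the
    coefficient t-test when the group has two levels).  The pseudocount
    defaults to half the smallest nonzero abundance in the table.  Returns
    per-feature ``lm_group_p`` with coefficients; constant features are
    rejected with a reason instead of fitted.
    """
    data, labels = _aligned(table, labels)
    cov = covariates.reindex(data.columns)
    if cov.isna().any().any():
        bad = cov.index[cov.isna().any(axis=1)].tolist()
        raise ValueError(f"covariates incomplete for samples {bad}")
    full, reduced = _design_matrices(labels, cov)
    full = full.set_index(data.columns)
    reduced = reduced.set_index(data.columns)
    if pseudocount is None:
        nonzero = data.values[data.values > 0]
        if nonzero.size == 0:
            raise ValueError("table is all zero")
        pseudocount = float(nonzero.min()) / 2.0
    logged = np.log(data + pseudocount)
    group_cols = [c for c in full.columns if c.startswith("group_")]
    rows = []
    for fid, y in logged.iterrows():
        if np.ptp(y.values) == 0:
            rows.append({"feature_id": fid, "lm_group_p": np.nan, "reason": "constant"})
            continue
        fit_full = sm.OLS(y.values, full.values).fit()
        fit_red = sm.OLS(y.values, reduced.values).fit()
        f, p, _ = fit_full.compare_f_test(fit_red)
        row = {"feature_id": fid, "lm_group_p": float(p), "reason": ""}
        for name, coef in zip(full.columns, fit_full.params):
            row[f"coef_{name}"] = float(coef)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    out.attrs["pseudocount"] = pseudocount
    out.attrs["covariates"] = list(covariates.columns)
    return out


def consensus(
    kw: pd.DataFrame,
    lda: pd.DataFrame,
    lm: pd.DataFrame,
    cfg: LefseConfig = LefseConfig(),
    lm_alpha: float = 0.05,
) -> pd.DataFrame:
    """Intersect the effect-size and linear-model arms into one report.

    A feature is a consensus biomarker iff its Kruskal-Wallis p is below
    ``kw_alpha``, its LDA score exceeds ``lda_min`` and its adjusted-model
    group p is below ``lm_alpha``.  Features significant in only one arm
    are kept with ``evidence='single-method'`` for transparency;
    Benjamini-Hochberg q-values are emitted alongside the raw thresholds.
    """
    features = kw.index
    report = pd.DataFrame(index=features)
    report["kw_p"] = kw["kw_p"]
    report["lda_score"] = lda["lda_score"].reindex(features)
    report["enriched_group"] = lda["enriched_group"].reindex(features)
    report["lm_group_p"] = lm["lm_group_p"].reindex(features)
    lefse_pass = (report["kw_p"] < cfg.kw_alpha) & (report["lda_score"] > cfg.lda_min)
    lm_pass = report["lm_group_p"] < lm_alpha
    report["lefse_pass"] = lefse_pass.fillna(False)
    report["lm_pass"] = lm_pass.fillna(False)
    report["consensus"] = report["lefse_pass"] & report["lm_pass"]
    evidence = np.where(
        report["consensus"], "consensus",
        np.where(report["lefse_pass"] | report["lm_pass"], "single-method", ""),
    )
    report["evidence"] = evidence
    for col, qcol in (("kw_p", "bh_q_kw"), ("lm_group_p", "bh_q_lm")):
        p = report[col].values.astype(float)
        q = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        report[qcol] = q
    report.index.name = "feature_id"
    return report


def run_consensus(
    table: FeatureTable,
    labels: pd.Series,
    covariates: pd.DataFrame,
    cfg: LefseConfig = LefseConfig(),
) -> pd.DataFrame:
    """Convenience wrapper: screen, effect size, adjusted model, intersect."""
    kw = kruskal_screen(table, labels, alpha=cfg.kw_alpha)
    lda = lda_effect_size(table, labels, cfg)
    lm = confounder_lm(table, labels, covariates)
    return consensus(kw, lda, lm, cfg)


def _voom_weights(logged: pd.DataFrame, fitted_means: np.ndarray) -> np.ndarray:
    """Inverse-variance weights from a lowess mean-variance trend.

    Mirrors the idea of precision weighting for log-count data: regress
    per-feature residual scale on mean log abundance, interpolate the
    trend at each fitted value and weight by the inverse fourth power of
    the predicted square-root standard deviation.
    """
    mean_log = logged.mean(axis=1).values
    sqrt_sd = np.sqrt(logged.std(axis=1, ddof=1).values.clip(min=1e-8))
    trend = lowess(sqrt_sd, mean_log, frac=0.5, return_sorted=True)
    pred = np.interp(fitted_means, trend[:, 0], trend[:, 1]).clip(min=1e-4)
    return 1.0 / pred**4


def pathway_differential(
    ko_table: FeatureTable,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    cfg: LefseConfig = LefseConfig(),
    voom_weights: bool = False,
) -> pd.DataFrame:
    """Consensus differential analysis of a functional (KO/pathway) table.

    All-zero rows are dropped (logged in ``attrs``).  The linear-model arm
    runs on log2 counts-per-million; with ``voom_weights`` it uses WLS with
    inverse-variance observation weights from a fitted mean-variance
    trend, otherwise the unweighted log-linear model is the reference arm.
    """
    keep = ko_table.data.sum(axis=1) > 0
    dropped = ko_table.feature_ids[~keep].tolist()
    data = ko_table.data.loc[keep]
    table = FeatureTable(data, mode=ko_table.mode)
    aligned, labels = _aligned(table, labels)
    table = FeatureTable(aligned, mode=ko_table.mode)

    kw = kruskal_screen(table, labels, alpha=cfg.kw_alpha)
    lda = lda_effect_size(table, labels, cfg)

    totals = aligned.sum(axis=0)
    cpm = (aligned + 0.5).div(totals + 1.0, axis=1) * 1e6
    logged = np.log2(cpm)
    cov = covariates.reindex(aligned.columns) if covariates is not None else None
    full, reduced = _design_matrices(labels, cov)
    full = full.set_index(aligned.columns)
    reduced = reduced.set_index(aligned.columns)
    weights_by_feature = None
    if voom_weights:
        weights_by_feature = _voom_weights(logged, logged.mean(axis=1).values)
    rows = []
    for i, (fid, y) in enumerate(logged.iterrows()):
        if np.ptp(y.values) == 0:
            rows.append({"feature_id": fid, "lm_group_p": np.nan, "reason": "constant"})
            continue
        w = None if weights_by_feature is None else np.full(len(y), weights_by_feature[i])
        if w is None:
            fit_full = sm.OLS(y.values, full.values).fit()
            fit_red = sm.OLS(y.values, reduced.values).fit()
        else:
            fit_full = sm.WLS(y.values, full.values, weights=w).fit()
            fit_red = sm.WLS(y.values, reduced.values, weights=w).fit()
        _, p, _ = fit_full.compare_f_test(fit_red)
        rows.append({"feature_id": fid, "lm_group_p": float(p), "reason": ""})
    lm = pd.DataFrame(rows).set_index("feature_id")
    report = consensus(kw, lda, lm, cfg)
    report.attrs["dropped_all_zero"] = dropped
    report.attrs["voom_weights"] = voom_weights
    return report
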