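"""Prognosis: cross-validated random-forest outcome prediction with
permutation (mean-decrease-accuracy) importances, Mann-Whitney AUC,
covariate-adjusted logistic odds ratios for a microbial marker, and relapse
survival analysis stratified by alpha diversity.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .containers import ClassifierReport, SurvivalReport

__all__ = [
    "auc",
    "rf_outcome_model",
    "combined_marker_model",
    "logistic_adjusted_or",
    "relapse_survival",
]


def auc(scores_pos, scores_neg) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 0.5.

    Identical to the trapezoidal area under the empirical ROC curve.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="mergesort")
    s, yl = scores[order], labels[order]
    p, n = yl.sum(), len(yl) - yl.sum()
    tps = np.cumsum(yl)
    fps = np.cumsum(1 - yl)
    # keep the last point of each tied-score run
    keep = np.r_[s[1:] != s[:-1], True]
    fpr = np.r_[0.0, fps[keep] / n]
    tpr = np.r_[0.0, tps[keep] / p]
    thr = np.r_[np.inf, s[keep]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _bootstrap_auc_ci(scores, labels, n_boot, rng) -> tuple:
    vals = []
    idx_all = np.arange(len(labels))
    for _ in range(n_boot):
        idx = rng.choice(idx_all, size=len(idx_all), replace=True)
        yl = labels[idx]
        if yl.sum() == 0 or yl.sum() == len(yl):
            continue
        vals.append(auc(scores[idx][yl == 1], scores[idx][yl == 0]))
    return tuple(np.percentile(vals, [2.5, 97.5]))


def _cv_rf(
    x: np.ndarray,
    ybin: np.ndarray,
    n_trees: int,
    n_splits: int,
    n_repeats: int,
    seed: int,
    importance: bool,
    top_k: int | None,
):
    """Repeated stratified CV: pooled held-out scores and, optionally,
    permutation (mean-decrease-accuracy) importances on held-out blocks.

    When ``top_k`` is set and smaller than the feature count, each training
    fold first ranks features with a full-feature forest and refits on the
    top ``top_k`` (selection strictly inside the fold, so the pooled scores
    stay honest)."""
    rkf = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=seed
    )
    rng = np.random.default_rng(seed)
    n, p = x.shape
    select = top_k is not None and top_k < p
    scores = np.zeros(n)
    counts = np.zeros(n)
    drops = np.zeros(p)
    n_folds_done = 0
    for train, test in rkf.split(x, ybin):
        fold_seed = int(rng.integers(2 ** 31))
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=fold_seed, n_jobs=1
        )
        clf.fit(x[train], ybin[train])
        if select:
            cols = np.argsort(-clf.feature_importances_)[:top_k]
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=fold_seed, n_jobs=1
            )
            clf.fit(x[train][:, cols], ybin[train])
        else:
            cols = np.arange(p)
        xt = x[test][:, cols]
        prob = clf.predict_proba(xt)[:, list(clf.classes_).index(1)]
        scores[test] += prob
        counts[test] += 1
        if importance:
            base_acc = (clf.predict(xt) == ybin[test]).mean()
            # stack one permuted copy of the test block per feature and
            # predict in a single call
            m = len(test)
            k = len(cols)
            stacked = np.repeat(xt[None, :, :], k, axis=0)
            for j in range(k):
                stacked[j, :, j] = rng.permutation(stacked[j, :, j])
            preds = clf.predict(stacked.reshape(k * m, k)).reshape(k, m)
            drops[cols] += base_acc - (preds == ybin[test]).mean(axis=1)
        n_folds_done += 1
    return scores / counts, drops / n_folds_done


def rf_outcome_model(
    features: pd.DataFrame,
    outcome: pd.Series,
    n_trees: int = 1000,
    n_splits: int = 5,
    n_repeats: int = 5,
    n_boot: int = 2000,
    seed: int = 0,
    compute_importance: bool = True,
    top_k: int | None = 10,
) -> ClassifierReport:
    """Random-forest outcome classifier under repeated stratified k-fold CV.

    Each training fold ranks taxa with a full-feature forest and refits on
    the ``top_k`` most predictive ones (set ``top_k=None`` to disable);
    selection happens strictly inside the fold so pooled held-out scores
    remain honest. Feature importance is the mean decrease in held-out
    accuracy when the feature is permuted in the held-out block, averaged
    over folds and repeats (never computed on training data). The ROC/AUC
    pool the held-out scores across repeats; the AUC CI is a sample
    bootstrap.
    """
    outcome = outcome.loc[features.index].astype(int)
    if outcome.nunique() < 2:
        raise ValueError("outcome has a single class")
    if (outcome.value_counts() < 10).any():
        import warnings

        warnings.warn("fewer than 10 samples in a class; estimates are unstable")
    x = features.to_numpy(dtype=float)
    ybin = outcome.to_numpy()
    scores, drops = _cv_rf(
        x, ybin, n_trees, n_splits, n_repeats, seed, compute_importance, top_k
    )
    a = auc(scores[ybin == 1], scores[ybin == 0])
    rng = np.random.default_rng(seed + 1)
    ci = _bootstrap_auc_ci(scores, ybin, n_boot, rng)
    roc = _roc_points(scores, ybin)
    youden = (roc["tpr"] - roc["fpr"]).idxmax()
    imp = (
        pd.Series(drops, index=features.columns, name="mean_decrease_accuracy")
        .sort_values(ascending=False)
        if compute_importance
        else None
    )
    return ClassifierReport(
        auc=a,
        auc_ci=ci,
        roc_points=roc,
        importances=imp,
        sensitivity=float(roc.loc[youden, "tpr"]),
        specificity=float(1 - roc.loc[youden, "fpr"]),
        scheme=(
            f"repeated stratified {n_splits}x{n_repeats} CV, {n_trees} trees"
            + (f", in-fold top-{top_k} refit" if top_k and top_k < x.shape[1] else "")
        ),
        seed=seed,
        scores=pd.Series(scores, index=features.index, name="score"),
        labels=outcome,
    )


def combined_marker_model(
    neos: pd.Series,
    otu_marker: pd.Series,
    serum_mets: pd.DataFrame,
    fecal_mets: pd.DataFrame,
    outcome: pd.Series,
    reference_auc: Optional[float] = None,
    **rf_kwargs,
) -> ClassifierReport:
    """Classifier on the combined panel (NEOS + microbial marker + 2 serum +
    2 fecal metabolite markers) using the same CV machinery.

    ``report.scheme`` records the AUC delta against ``reference_auc`` (e.g.
    the taxa-only model) when provided.
    """
    if serum_mets.shape[1] != 2 or fecal_mets.shape[1] != 2:
        raise ValueError("expect exactly 2 serum and 2 fecal metabolite markers")
    panel = pd.concat(
        [neos.rename("neos"), otu_marker.rename("otu_marker"), serum_mets, fecal_mets],
        axis=1,
    ).dropna()
    if panel.apply(lambda c: c.nunique() <= 1).all():
        raise ValueError("all panel features are constant")
    report = rf_outcome_model(panel, outcome.loc[panel.index], **rf_kwargs)
    if reference_auc is not None:
        report.scheme += f"; delta AUC vs reference = {report.auc - reference_auc:+.3f}"
    return report


def logistic_adjusted_or(
    marker: pd.Series,
    outcome: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    dichotomize: bool = True,
):
    """Covariate-adjusted odds ratio of a microbial marker for poor outcome.

    The marker enters as an above-median indicator by default (continuous by
    flag). Returns ``(OR, (lo, hi), p)`` from a maximum-likelihood logistic
    fit with Wald intervals. Perfect separation raises a ValueError.
    """
    df = pd.concat([marker.rename("marker"), outcome.rename("y")], axis=1)
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    x = df.drop(columns="y").astype(float)
    if dichotomize:
        x["marker"] = (x["marker"] > x["marker"].median()).astype(float)
    xmat = sm.add_constant(x)
    yv = df["y"].astype(int)
    try:
        res = sm.Logit(yv, xmat).fit(disp=0)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(
            f"logistic fit failed ({exc}); possible separation - consider a "
            "penalized fit"
        )
    if not np.isfinite(res.bse["marker"]) or res.bse["marker"] > 50:
        raise ValueError("quasi-separation detected (unbounded marker estimate)")
    beta = res.params["marker"]
    lo, hi = res.conf_int().loc["marker"]
    return float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi))), float(res.pvalues["marker"])


def relapse_survival(
    relapse_time: pd.Series,
    relapse_event: pd.Series,
    strata: pd.Series,
    followup_months: float = 6.0,
) -> SurvivalReport:
    """Kaplan-Meier + log-rank + Cox HR for a two-stratum relapse analysis.

    ``strata`` is a binary indicator (1 = at-risk stratum, e.g. below-median
    diversity); the HR is for stratum 1 vs 0 with Efron tie handling. With
    zero events the KM curves are returned and the tests flagged undefined
    (NaN).
    """
    df = pd.DataFrame(
        {"time": relapse_time, "event": relapse_event.astype(int), "stratum": strata}
    ).dropna()
    levels = sorted(df["stratum"].unique())
    if len(levels) != 2:
        raise ValueError("need exactly 2 strata")
    km_curves = {}
    ticks = np.arange(0, np.floor(followup_months) + 1)
    at_risk = {}
    for lev in levels:
        sub = df[df["stratum"] == lev]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(lev))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        km_curves[lev] = curve
        at_risk[lev] = [(sub["time"] >= t).sum() for t in ticks]
    at_risk_df = pd.DataFrame(at_risk, index=ticks).T
    at_risk_df.index.name = "stratum"

    n_events = int(df["event"].sum())
    if n_events == 0:
        return SurvivalReport(
            km_curves=km_curves, logrank_stat=np.nan, logrank_p=np.nan,
            log_hr=np.nan, hr=np.nan, hr_ci=(np.nan, np.nan),
            at_risk=at_risk_df, n_events=0,
        )
    a, b = levels
    lr = logrank_test(
        df.loc[df["stratum"] == b, "time"], df.loc[df["stratum"] == a, "time"],
        df.loc[df["stratum"] == b, "event"], df.loc[df["stratum"] == a, "event"],
    )
    cox_df = df.copy()
    cox_df["stratum"] = (cox_df["stratum"] == b).astype(float)
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col="time", event_col="event")
    log_hr = float(cph.params_["stratum"])
    ci = cph.confidence_intervals_.loc["stratum"]
    return SurvivalReport(
        km_curves=km_curves,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        log_hr=log_hr,
        hr=float(np.exp(log_hr)),
        hr_ci=(float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))),
        at_risk=at_risk_df,
        n_events=n_events,
    )
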