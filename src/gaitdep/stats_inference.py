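"""Inferential stage: group comparisons, PCA reduction, stepwise logistic fits.

The diagnostic question is how much of the case/control variance each gait
feature bank explains.  The analysis mirrors standard clinical biostatistics
practice:

* pooled two-sample t-tests compare each spatiotemporal feature between
  groups;
* the high-dimensional time- and frequency-domain banks are reduced with
  PCA on z-scored features, keeping the leading components that reach 95%
  cumulative explained variance;
* a binary logistic model is built by stepwise forward selection
  (likelihood-ratio entry at alpha = 0.05), reporting per-term coefficients,
  Wald statistics, odds ratios exp(beta), raw and Holm-corrected p-values,
  and Nagelkerke's pseudo-R-squared;
* Pearson correlations between retained components and original features
  make the components interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

__all__ = [
    "GroupSummary",
    "PCAResult",
    "LogisticFit",
    "two_sample_t",
    "group_summary",
    "pca_reduce",
    "nagelkerke_r2",
    "stepwise_logistic",
    "pc_feature_correlations",
]


@dataclass
class GroupSummary:
    """Per-feature case/control means, SDs and pooled t-tests."""

    table: pd.DataFrame  # columns: mean_case, sd_case, mean_control, sd_control, t, df, p
    n_case: int
    n_control: int


@dataclass
class PCAResult:
    """PCA of z-scored features truncated at 95% cumulative variance."""

    loadings: pd.DataFrame            # feature x component
    scores: pd.DataFrame              # participant x component
    explained_variance_ratio: np.ndarray
    n_retained: int
    feature_means: pd.Series = field(repr=False, default=None)
    feature_sds: pd.Series = field(repr=False, default=None)
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class LogisticFit:
    """A stepwise-selected binary logistic model.

    ``terms`` has one row per selected predictor (selection order) with
    columns beta, se, wald, odds_ratio, p_raw, p_corrected.
    """

    terms: pd.DataFrame
    intercept: float
    loglik_null: float
    loglik_model: float
    n: int
    nagelkerke_r2: float
    warnings: list[str] = field(default_factory=list)


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> tuple[float, int, float]:
    """Pooled-variance Student t-test from group summary statistics.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2 and a two-sided p.  If both
    SDs are zero the statistic is defined as 0 for equal means (and is
    infinite otherwise).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    denom = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    if denom == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / denom
    p = float(2 * sstats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), int(df), p


def group_summary(features: pd.DataFrame, y: np.ndarray) -> GroupSummary:
    """Case/control means, SDs and pooled t-tests for each feature column."""
    y = np.asarray(y)
    case, ctrl = features[y == 1], features[y == 0]
    rows = {}
    for col in features.columns:
        m1, s1 = float(case[col].mean()), float(case[col].std(ddof=1))
        m0, s0 = float(ctrl[col].mean()), float(ctrl[col].std(ddof=1))
        t, df, p = two_sample_t(m1, s1, len(case), m0, s0, len(ctrl))
        rows[col] = dict(mean_case=m1, sd_case=s1, mean_control=m0,
                         sd_control=s0, t=t, df=df, p=p)
    return GroupSummary(pd.DataFrame(rows).T, int((y == 1).sum()), int((y == 0).sum()))


def pca_reduce(feature_matrix: pd.DataFrame,
               cum_var_threshold: float = 0.95) -> PCAResult:
    """PCA on z-scored features, retaining the minimal component count that
    reaches ``cum_var_threshold`` cumulative explained variance.

    Zero-variance features are dropped (with a warning) before
    standardization.  Component signs follow the convention that each
    component's largest-magnitude loading is positive.
    """
    X = feature_matrix.copy()
    sds = X.std(ddof=1)
    dropped = list(X.columns[(sds == 0) | sds.isna()])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features before PCA")
        X = X.drop(columns=dropped)
        sds = sds.drop(index=dropped)
    means = X.mean()
    Z = (X - means) / sds
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    n_retained = int(np.searchsorted(cum, cum_var_threshold - 1e-12) + 1)
    n_retained = min(n_retained, len(ratio))

    components = pca.components_[:n_retained]          # component x feature
    # deterministic sign: largest-|loading| positive per component
    flip = np.sign(components[np.arange(n_retained),
                              np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    scores = scores[:, :n_retained] * flip[None, :]

    pc_names = [f"PC{i + 1}" for i in range(n_retained)]
    return PCAResult(
        loadings=pd.DataFrame(components.T, index=X.columns, columns=pc_names),
        scores=pd.DataFrame(scores, index=X.index, columns=pc_names),
        explained_variance_ratio=ratio,
        n_retained=n_retained,
        feature_means=means,
        feature_sds=sds,
        dropped_features=dropped,
    )


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke's pseudo-R-squared.

    Rescales the Cox-Snell R^2 = 1 - exp(2 (ll_null - ll_model) / n) by its
    attainable maximum 1 - exp(2 ll_null / n), giving a statistic in [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below null log-likelihood")
    if loglik_null == 0:
        raise ValueError("degenerate null model with zero log-likelihood")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    r2_max = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(min(1.0, max(0.0, r2_cs / r2_max)))


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-fit logistic with intercept; fall back to ridge on separation.

    Returns (params, standard errors, log-likelihood, separation_flag);
    params[0] is the intercept.
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> raise
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=100, tol=1e-8,
                                      disp=False)
        if np.all(np.isfinite(res.bse)) and np.all(np.abs(res.params) < 1e3):
            return np.asarray(res.params), np.asarray(res.bse), float(res.llf), False
    except Exception:
        pass
    # penalized fallback: light L2 ridge keeps estimates finite
    clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=1000)
    clf.fit(X, y)
    params = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
    eta = Xc @ params
    p = 1.0 / (1.0 + np.exp(-eta))
    llf = float(np.sum(y * np.log(np.clip(p, 1e-12, 1)) +
                       (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))))
    W = p * (1 - p)
    info = Xc.T @ (Xc * W[:, None]) + np.eye(Xc.shape[1]) / 1e3
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return params, se, llf, True


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def stepwise_logistic(X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05,
                      entry_test: str = "lr",
                      correction: str = "holm") -> LogisticFit:
    """Forward stepwise binary logistic regression.

    At each step the candidate with the smallest entry p-value
    (likelihood-ratio test by default, Wald optionally) joins the model if
    that p-value is below ``alpha``; the model is refit after every entry and
    selection stops when no candidate qualifies.  The final model reports
    per-term beta, SE, Wald = (beta/SE)^2, odds ratio exp(beta), raw Wald
    p-values and multiplicity-corrected p-values (Holm by default,
    Bonferroni optionally), plus Nagelkerke's R^2.
    """
    if entry_test not in ("lr", "wald"):
        raise ValueError("entry_test must be 'lr' or 'wald'")
    if correction not in ("holm", "bonferroni"):
        raise ValueError("correction must be 'holm' or 'bonferroni'")
    y = np.asarray(y, dtype=float)
    if X.isna().any().any():
        raise ValueError("predictor matrix contains missing values")
    ll_null = _null_loglik(y)
    selected: list[str] = []
    remaining = list(X.columns)
    ll_current = ll_null
    notes: list[str] = []

    while remaining:
        best: tuple[float, str, float] | None = None
        for cand in remaining:
            cols = selected + [cand]
            params, se, llf, sep = _fit_logit(X[cols].to_numpy(), y)
            if entry_test == "lr":
                stat = max(0.0, 2.0 * (llf - ll_current))
                p = float(sstats.chi2.sf(stat, 1))
            else:
                w = (params[-1] / se[-1]) ** 2 if se[-1] > 0 else 0.0
                p = float(sstats.chi2.sf(w, 1))
            if best is None or p < best[0]:
                best = (p, cand, llf)
        assert best is not None
        p_best, cand_best, llf_best = best
        if p_best >= alpha:
            break
        selected.append(cand_best)
        remaining.remove(cand_best)
        ll_current = llf_best

    if selected:
        params, se, llf, sep = _fit_logit(X[selected].to_numpy(), y)
        if sep:
            notes.append("perfect separation detected; penalized fallback fit used")
    else:
        params = np.array([sm.Logit(y, np.ones((len(y), 1))).fit(disp=False).params[0]])
        se = np.array([np.nan])
        llf = ll_null

    betas = params[1:]
    ses = se[1:]
    wald = np.where(ses > 0, (betas / ses) ** 2, np.inf)
    p_raw = sstats.chi2.sf(wald, 1)
    if correction == "holm":
        order = np.argsort(p_raw)
        m = len(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
        p_corr = adj
    else:
        p_corr = np.minimum(1.0, p_raw * len(p_raw)) if len(p_raw) else p_raw

    terms = pd.DataFrame(
        {
            "beta": betas,
            "se": ses,
            "wald": wald,
            "odds_ratio": np.exp(betas),
            "p_raw": p_raw,
            "p_corrected": p_corr,
        },
        index=selected,
    )
    return LogisticFit(
        terms=terms,
        intercept=float(params[0]),
        loglik_null=ll_null,
        loglik_model=float(llf),
        n=len(y),
        nagelkerke_r2=nagelkerke_r2(ll_null, float(llf), len(y)),
        warnings=notes,
    )


def pc_feature_correlations(pca: PCAResult,
                            original_features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each retained component score and each feature.

    Zero-variance features get NaN (undefined correlation).
    """
    feats = original_features.loc[pca.scores.index]
    S = pca.scores.to_numpy()
    F = feats.to_numpy(dtype=float)
    S = S - S.mean(axis=0)
    F = F - F.mean(axis=0)
    s_sd = S.std(axis=0, ddof=1)
    f_sd = F.std(axis=0, ddof=1)
    n = len(feats)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (F.T @ S) / ((n - 1) * np.outer(f_sd, s_sd))
    corr[f_sd == 0, :] = np.nan
    return pd.DataFrame(corr, index=feats.columns, columns=pca.scores.columns)
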