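"""Dimensionality-reduction chain for radiomic feature tables.

Four stages, each nested inside the previous survivors:

1. two-sample Student's t-test per feature, keep ``p < alpha``
   (constant / all-missing features are dropped with a logged reason);
2. per-feature AUROC under stratified bootstrap resampling, keep
   ``mean AUROC >= floor``; the AUROC is the rank-sum (Mann-Whitney)
   statistic with half credit for ties and is *not* orientation-flipped;
3. Pearson-correlation pruning: on the graph with edges ``|r| >= r_threshold``
   keep, per connected component, the feature with the largest mean
   bootstrap AUROC (ties broken toward the lower column index);
4. backward-stepwise logistic elimination: iteratively drop the covariate
   with the largest Wald p-value above ``p_remove``, allowing an excluded
   covariate back in when it would enter with ``p < p_enter``.

The public surface is :class:`GrowthFeatureSelector`, a scikit-learn
transformer (``fit`` / ``transform`` / ``get_support``); the module-level
functions expose the individual stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SelectionReport",
    "GrowthFeatureSelector",
    "ttest_filter",
    "bootstrap_auroc_filter",
    "correlation_prune",
    "backward_eliminate",
    "rank_auroc",
]


# ---------------------------------------------------------------------------
# primitives


def rank_auroc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise AUROC of features ``x`` for binary labels ``y``.

    Rank-sum (Mann-Whitney) formulation with 0.5 credit for ties; the
    positive class is ``y == 1``.  NaNs are ignored per column.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y).astype(bool)
    n1 = y.sum()
    n0 = (~y).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUROC")
    out = np.empty(x.shape[1])
    nan_cols = np.isnan(x).any(axis=0)
    clean = ~nan_cols
    if clean.any():
        ranks = sps.rankdata(x[:, clean], axis=0)
        out[clean] = (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    for j in np.flatnonzero(nan_cols):
        ok = ~np.isnan(x[:, j])
        yk = y[ok]
        if yk.all() or not yk.any():
            out[j] = np.nan
            continue
        r = sps.rankdata(x[ok, j])
        m1, m0 = yk.sum(), (~yk).sum()
        out[j] = (r[yk].sum() - m1 * (m1 + 1) / 2.0) / (m1 * m0)
    return out


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


# ---------------------------------------------------------------------------
# stages


def ttest_filter(X, y, alpha: float = 0.05, welch: bool = False
                 ) -> tuple[list[str], pd.Series, list[str]]:
    """Stage 1: keep features whose two-sample t-test p-value is < alpha.

    Returns (survivors, p-values for all testable features, dropped-reason
    log).  Uses the pooled-variance Student's t by default; Welch optional.
    """
    df = _as_frame(X)
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    dropped: list[str] = []
    pvals = {}
    a = df.loc[y]
    b = df.loc[~y]
    for col in df.columns:
        xa = a[col].dropna().to_numpy()
        xb = b[col].dropna().to_numpy()
        if xa.size < 2 or xb.size < 2:
            dropped.append(f"{col}: insufficient non-missing observations")
            continue
        if np.var(xa) == 0 and np.var(xb) == 0:
            dropped.append(f"{col}: zero pooled variance (constant feature)")
            continue
        t = sps.ttest_ind(xa, xb, equal_var=not welch)
        pvals[col] = float(t.pvalue)
    pser = pd.Series(pvals)
    survivors = [c for c in df.columns if c in pvals and pvals[c] < alpha]
    return survivors, pser, dropped


def bootstrap_auroc_filter(X, y, n_boot: int = 200, floor: float = 0.5,
                           seed: int | np.random.Generator = 0,
                           features: list[str] | None = None
                           ) -> tuple[list[str], pd.Series]:
    """Stage 2: keep features whose mean bootstrap AUROC is >= floor.

    Stratified resampling (class counts preserved) so every resample
    contains both classes.  AUROC is not orientation-flipped.
    """
    df = _as_frame(X)
    if features is not None:
        df = df[features]
    y = np.asarray(y).astype(bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    x = df.to_numpy(dtype=np.float64)
    total = np.zeros(x.shape[1])
    for _ in range(int(n_boot)):
        bi = np.concatenate([rng.choice(pos, pos.size, replace=True),
                             rng.choice(neg, neg.size, replace=True)])
        yb = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        total += rank_auroc(x[bi], yb)
    mean_auc = pd.Series(total / n_boot, index=df.columns)
    survivors = [c for c in df.columns if mean_auc[c] >= floor]
    return survivors, mean_auc


def correlation_prune(X, survivors: list[str], mean_auroc: pd.Series,
                      r_threshold: float = 0.8) -> list[str]:
    """Stage 3: within each connected component of the ``|r| >= threshold``
    graph keep only the feature with the largest mean AUROC (tie -> lower
    column position).  Output preserves the input column order."""
    df = _as_frame(X)[survivors]
    if len(survivors) <= 1:
        return list(survivors)
    # pairwise-complete Pearson correlations
    r = df.corr(method="pearson").to_numpy()
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        warnings.warn(f"correlation pruning used pairwise-complete cases "
                      f"({n_missing} missing values)", stacklevel=2)
    adj = (np.abs(r) >= r_threshold) & ~np.eye(len(survivors), dtype=bool)
    np.nan_to_num(adj, copy=False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    keep = []
    order = {c: k for k, c in enumerate(survivors)}
    for c in range(n_comp):
        members = [survivors[k] for k in np.flatnonzero(comp == c)]
        best = max(members, key=lambda f: (mean_auroc[f], -order[f]))
        keep.append(best)
    return [c for c in survivors if c in set(keep)]


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """Logistic fit with separation handling: capped iterations, flagged."""
    exog = sm.add_constant(X.astype(float), has_constant="add")
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(np.asarray(y, float), exog).fit(disp=0, maxiter=100)
        except Exception:
            res = sm.Logit(np.asarray(y, float), exog).fit(
                disp=0, method="bfgs", maxiter=200)
            flagged = True
    params = res.params
    bse = res.bse
    if (np.abs(params.drop("const", errors="ignore")) > 50).any() or \
            (~np.isfinite(bse)).any() or (bse > 1e3).any():
        flagged = True
    return res, flagged


def backward_eliminate(X, y, features: list[str] | None = None,
                       p_enter: float = 0.05, p_remove: float = 0.10
                       ) -> tuple[list[str], object, list[dict]]:
    """Stage 4: backward-stepwise logistic elimination with re-entry.

    Starting from the full model, repeatedly remove the covariate with the
    largest Wald p-value above ``p_remove``; after each removal any
    excluded covariate whose addition p-value is below ``p_enter`` may
    re-enter.  Returns (final features, fitted results, trace).
    """
    df = _as_frame(X)
    features = list(df.columns if features is None else features)
    y = np.asarray(y).astype(float)
    cc = df[features].notna().all(axis=1)
    if not cc.all():
        warnings.warn(f"backward elimination on {int(cc.sum())} complete cases "
                      f"of {len(cc)}", stacklevel=2)
    dfc = df.loc[cc, features]
    yc = y[cc.to_numpy()] if isinstance(cc, pd.Series) else y[cc]
    if len(dfc) < len(features) + 2:
        raise ValueError("need at least n_features + 2 complete observations")

    current = list(features)
    excluded: list[str] = []
    trace: list[dict] = []
    seen_states: set[frozenset] = set()
    res, flagged = (None, False)
    while True:
        state = frozenset(current)
        if state in seen_states:
            break
        seen_states.add(state)
        if current:
            res, flagged = _fit_logit(dfc[current], yc)
            if flagged:
                # Wald statistics are meaningless under (quasi-)separation;
                # fall back to likelihood-ratio p-values so a perfectly
                # separating covariate is retained, not discarded
                pv = _lrt_pvalues(dfc, yc, current, res)
            else:
                pv = res.pvalues.drop("const", errors="ignore").fillna(1.0)
            worst = pv.idxmax()
            if pv[worst] > p_remove:
                current.remove(worst)
                excluded.append(worst)
                trace.append({"action": "remove", "feature": worst,
                              "p": float(pv[worst]), "separation": flagged})
                # re-entry pass
                entered = _try_reenter(dfc, yc, current, excluded, p_enter, trace)
                continue
        else:
            res, flagged = _fit_logit(dfc[[]], yc)
        break
    final_res, flagged = _fit_logit(dfc[current], yc)
    if flagged:
        trace.append({"action": "flag", "feature": None,
                      "p": None, "separation": True})
    return current, final_res, trace


def _lrt_pvalues(dfc, yc, current, full_res) -> pd.Series:
    """Per-covariate likelihood-ratio p-values against the full model."""
    out = {}
    llf_full = float(full_res.llf)
    for c in current:
        reduced = [f for f in current if f != c]
        res_r, _ = _fit_logit(dfc[reduced], yc)
        stat = max(0.0, 2.0 * (llf_full - float(res_r.llf)))
        out[c] = float(sps.chi2.sf(stat, 1))
    return pd.Series(out).fillna(1.0)


def _try_reenter(dfc, yc, current, excluded, p_enter, trace) -> bool:
    best, best_p = None, p_enter
    for cand in list(excluded):
        try:
            res, _ = _fit_logit(dfc[current + [cand]], yc)
        except Exception:
            continue
        p = float(res.pvalues.get(cand, 1.0))
        if np.isfinite(p) and p < best_p:
            best, best_p = cand, p
    if best is not None:
        current.append(best)
        excluded.remove(best)
        trace.append({"action": "enter", "feature": best, "p": best_p,
                      "separation": False})
        return True
    return False


# ---------------------------------------------------------------------------
# report + estimator


@dataclass
class SelectionReport:
    """Per-stage survivors and diagnostics; survivors are nested."""

    stage_survivors: dict[str, list[str]]
    pvalues: pd.Series
    mean_auroc: pd.Series
    dropped: list[str]
    elimination_trace: list[dict]
    separation_flagged: bool = False
    n_missing_logged: int = 0

    def to_dict(self) -> dict:
        return {
            "stage_survivors": self.stage_survivors,
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "mean_auroc": {k: float(v) for k, v in self.mean_auroc.items()},
            "dropped": self.dropped,
            "elimination_trace": self.elimination_trace,
            "separation_flagged": self.separation_flagged,
        }


class GrowthFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer running the full four-stage chain.

    Parameters mirror the published procedure: ``alpha=0.05`` t-test
    filter, 200 stratified bootstrap resamples with mean-AUROC floor 0.5,
    Pearson ``|r| >= 0.8`` pruning, and backward-stepwise logistic
    elimination at 0.05 entry / 0.10 removal.

    Attributes (after ``fit``)
    --------------------------
    support_ : boolean mask over input columns of the final survivors.
    selected_features_ : final feature names in input order.
    report_ : :class:`SelectionReport` with the full per-stage record.
    model_ : the final statsmodels logistic fit on the survivors.
    """

    def __init__(self, alpha: float = 0.05, n_boot: int = 200,
                 auroc_floor: float = 0.5, r_threshold: float = 0.8,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 welch: bool = False, random_state: int | None = 0):
        self.alpha = alpha
        self.n_boot = n_boot
        self.auroc_floor = auroc_floor
        self.r_threshold = r_threshold
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.welch = welch
        self.random_state = random_state

    def fit(self, X, y):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [0, 1]")
        df = _as_frame(X)
        y = np.asarray(y).astype(int)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]

        s1, pvals, dropped = ttest_filter(df, y, self.alpha, self.welch)
        rng = np.random.default_rng(self.random_state)
        if s1:
            s2, mean_auc = bootstrap_auroc_filter(
                df, y, self.n_boot, self.auroc_floor, rng, features=s1)
        else:
            s2, mean_auc = [], pd.Series(dtype=float)
        s3 = correlation_prune(df, s2, mean_auc, self.r_threshold) if s2 else []
        if s3:
            s4, model, trace = backward_eliminate(
                df, y, s3, self.p_enter, self.p_remove)
        else:
            s4, model, trace = [], None, []

        self.pvalues_ = pvals
        self.mean_auroc_ = mean_auc
        self.selected_features_ = list(s4)
        self.support_ = np.isin(self.feature_names_in_, s4)
        self.model_ = model
        self.report_ = SelectionReport(
            stage_survivors={"ttest": s1, "bootstrap_auroc": s2,
                             "correlation_prune": s3, "backward_elimination": s4},
            pvalues=pvals, mean_auroc=mean_auc, dropped=dropped,
            elimination_trace=trace,
            separation_flagged=any(t.get("separation") for t in trace),
        )
        # survivor nesting is an invariant of the chain
        assert set(s2) <= set(s1) and set(s3) <= set(s2) and set(s4) <= set(s3)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.target_tags.required = True
        return tags
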