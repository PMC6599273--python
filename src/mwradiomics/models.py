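"""Logistic growth-pattern models, radiomics scores, bootstrap validation
and nomograms.

The modelling chain fits logistic regressions of the aggressive-vs-indolent
label on (a) selected lung-window features, (b) selected difference-region
features, (c) their combination; each fit defines a *radiomics score* (the
linear predictor), which then enters a clinical augmentation model together
with sex and COPD.  Performance is summarized by the rank-sum AUROC with a
stratified-bootstrap confidence interval and accuracy / sensitivity /
specificity at the Youden-optimal threshold (positive class: aggressive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .selection import _fit_logit, rank_auroc

__all__ = [
    "FittedModel",
    "PerformanceSummary",
    "NomogramSpec",
    "BootstrapLogisticModel",
    "fit_logistic",
    "radiomics_score",
    "combine_clinical",
    "evaluate",
    "youden_threshold",
    "build_nomogram",
]


@dataclass
class FittedModel:
    """A fitted logistic model: coefficients, odds ratios, diagnostics."""

    covariates: list[str]
    intercept: float
    coefficients: pd.Series
    odds_ratios: pd.Series
    pvalues: pd.Series
    family: str = "custom"
    separation_flagged: bool = False
    bootstrap_or_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    _result: object = None

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        lp = self.intercept + X[self.covariates].to_numpy(float) @ \
            self.coefficients[self.covariates].to_numpy(float)
        return np.asarray(lp, dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "covariates": self.covariates,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "odds_ratios": {k: float(v) for k, v in self.odds_ratios.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "separation_flagged": self.separation_flagged,
            "bootstrap_or_ci": {k: list(map(float, v))
                                for k, v in self.bootstrap_or_ci.items()},
        }


@dataclass
class PerformanceSummary:
    """Apparent and bootstrap-validated discrimination statistics."""

    auroc: float
    auroc_ci: tuple[float, float]
    mean_bootstrap_auroc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_boot: int

    def __post_init__(self) -> None:
        lo, hi = self.auroc_ci
        if lo > hi:
            raise ValueError("CI bounds out of order")

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "mean_bootstrap_auroc": self.mean_bootstrap_auroc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n_boot": self.n_boot,
        }


def fit_logistic(X, y, covariates: list[str] | None = None,
                 family: str = "custom") -> FittedModel:
    """Maximum-likelihood logistic fit of binary ``y`` on the covariates.

    Separation (diverging coefficients or standard errors) is detected and
    flagged; the capped-iteration fit is still reported.
    """
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
        np.asarray(X), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    covariates = list(df.columns if covariates is None else covariates)
    y = np.asarray(y).astype(float)
    if len(df) < len(covariates) + 2:
        raise ValueError("need at least n_covariates + 2 observations")
    res, flagged = _fit_logit(df[covariates], y)
    params = res.params
    coefs = params.drop("const", errors="ignore")
    return FittedModel(
        covariates=covariates,
        intercept=float(params.get("const", 0.0)),
        coefficients=coefs,
        odds_ratios=np.exp(coefs),
        pvalues=res.pvalues.drop("const", errors="ignore"),
        family=family,
        separation_flagged=flagged,
        _result=res,
    )


def radiomics_score(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """The radiomics score: the model's linear predictor per observation.

    Refitting a one-covariate logistic model on this score reproduces the
    original predicted probabilities exactly (slope 1, intercept 0).
    """
    return model.linear_predictor(X)


def combine_clinical(score: np.ndarray, clinical: pd.DataFrame, y,
                     clinical_covariates: tuple[str, ...] = ("sex_female", "copd"),
                     family: str = "nomogram") -> FittedModel:
    """Logistic fit on {radiomics score, sex, COPD}."""
    df = clinical[list(clinical_covariates)].reset_index(drop=True).copy()
    df.insert(0, "radiomics_score", np.asarray(score, dtype=float))
    return fit_logistic(df, y, family=family)


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    cand = np.unique(scores)
    best_t, best_j = cand[0], -np.inf
    n1, n0 = y.sum(), (~y).sum()
    for t in cand:
        pred = scores >= t
        sens = (pred & y).sum() / n1
        spec = (~pred & ~y).sum() / n0
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def evaluate(scores: np.ndarray, y, n_boot: int = 5000,
             seed: int | np.random.Generator = 0) -> PerformanceSummary:
    """Apparent AUROC, stratified-bootstrap CI, and threshold statistics.

    The AUROC is the rank-sum (Mann-Whitney) statistic; the CI is the
    percentile interval over ``n_boot`` stratified resamples and the mean
    bootstrap AUROC is reported alongside.  Accuracy / sensitivity /
    specificity are computed at the Youden-optimal threshold of the
    apparent ROC.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    auroc = float(rank_auroc(scores, y)[0])
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    boots = np.empty(int(n_boot))
    for b in range(int(n_boot)):
        bi = np.concatenate([rng.choice(pos, pos.size, replace=True),
                             rng.choice(neg, neg.size, replace=True)])
        yb = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        boots[b] = rank_auroc(scores[bi], yb)[0]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    t = youden_threshold(scores, y)
    pred = scores >= t
    sens = float((pred & y).sum() / y.sum())
    spec = float((~pred & ~y).sum() / (~y).sum())
    acc = float((pred == y).mean())
    return PerformanceSummary(auroc=auroc, auroc_ci=ci,
                              mean_bootstrap_auroc=float(boots.mean()),
                              accuracy=acc, sensitivity=sens,
                              specificity=spec, threshold=t,
                              n_boot=int(n_boot))


def roc_curve_table(scores: np.ndarray, y) -> pd.DataFrame:
    """ROC as a (threshold, TPR, FPR) table for export."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    rows = []
    for t in np.concatenate(([np.inf], np.unique(scores)[::-1])):
        pred = scores >= t
        rows.append({"threshold": float(t),
                     "tpr": float((pred & y).sum() / y.sum()),
                     "fpr": float((pred & ~y).sum() / (~y).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nomogram


@dataclass
class NomogramSpec:
    """Piecewise-linear point mapping of a logistic model to a 0-100 scale.

    ``points_i(x) = 100 * beta_i * (x - x_ref,i) / K`` with ``x_ref,i`` the
    end of the observed range minimizing the linear predictor and
    ``K = max_j |beta_j| * range_j``; the covariate with the largest
    ``|beta| * range`` spans exactly 0-100.  Total points map back to
    predicted probability through the inverse logit.
    """

    covariates: list[str]
    coefficients: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    reference: dict[str, float]
    scale: float  # K
    base_lp: float  # intercept + sum beta_i * x_ref,i
    excluded: list[str] = field(default_factory=list)

    def points(self, covariate: str, x) -> np.ndarray:
        b = self.coefficients[covariate]
        ref = self.reference[covariate]
        return 100.0 * b * (np.asarray(x, dtype=float) - ref) / self.scale

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        return sum(self.points(c, X[c].to_numpy()) for c in self.covariates)

    def probability(self, total_points) -> np.ndarray:
        lp = self.base_lp + self.scale * np.asarray(total_points, dtype=float) / 100.0
        return expit(lp)

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "coefficients": self.coefficients,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "reference": self.reference,
            "scale": self.scale,
            "base_lp": self.base_lp,
            "excluded": self.excluded,
        }


def build_nomogram(model: FittedModel, X: pd.DataFrame) -> NomogramSpec:
    """Nomogram point mapping from a fitted model and observed covariates.

    Zero-range covariates are excluded with a warning.  The probability
    reconstructed from total points equals the model's predicted
    probability on every observation (up to floating-point error).
    """
    coefs, ranges, refs = {}, {}, {}
    excluded = []
    for c in model.covariates:
        lo = float(X[c].min())
        hi = float(X[c].max())
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise ValueError(f"non-finite range for covariate {c}")
        if hi == lo:
            warnings.warn(f"covariate {c} has zero observed range; "
                          f"excluded from the nomogram", stacklevel=2)
            excluded.append(c)
            continue
        b = float(model.coefficients[c])
        coefs[c] = b
        ranges[c] = (lo, hi)
        refs[c] = lo if b >= 0 else hi
    if not coefs:
        raise ValueError("no covariates with positive range")
    scale = max(abs(b) * (ranges[c][1] - ranges[c][0]) for c, b in coefs.items())
    base_lp = model.intercept + sum(
        b * refs[c] for c, b in coefs.items())
    # excluded zero-range covariates still contribute their constant term
    for c in excluded:
        base_lp += float(model.coefficients[c]) * float(X[c].iloc[0])
    return NomogramSpec(covariates=list(coefs), coefficients=coefs,
                        ranges=ranges, reference=refs, scale=float(scale),
                        base_lp=float(base_lp), excluded=excluded)


def plot_nomogram(spec: NomogramSpec, path: str) -> None:
    """Static nomogram rendering (horizontal point scales per covariate)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(spec.covariates)
    fig, ax = plt.subplots(figsize=(7, 1.2 * (n + 2)))
    ax.set_xlim(-5, 105)
    ax.set_ylim(-1.5, n + 0.5)
    ax.axis("off")
    ax.annotate("Points", (-4, n), fontsize=9, ha="left")
    ax.plot([0, 100], [n, n], color="k")
    for p in range(0, 101, 10):
        ax.plot([p, p], [n - 0.08, n + 0.08], color="k")
        ax.annotate(str(p), (p, n + 0.15), fontsize=7, ha="center")
    for k, c in enumerate(spec.covariates):
        yline = n - 1 - k
        lo, hi = spec.ranges[c]
        p_lo = float(spec.points(c, lo))
        p_hi = float(spec.points(c, hi))
        ax.annotate(c, (-4, yline), fontsize=8, ha="left")
        ax.plot(sorted((p_lo, p_hi)), [yline, yline], color="tab:blue")
        ax.annotate(f"{lo:.3g}", (p_lo, yline - 0.25), fontsize=7, ha="center")
        ax.annotate(f"{hi:.3g}", (p_hi, yline - 0.25), fontsize=7, ha="center")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# sklearn estimator


class BootstrapLogisticModel(ClassifierMixin, BaseEstimator):
    """scikit-learn classifier wrapping the logistic fit + bootstrap
    validation used throughout the modelling stage.

    After ``fit``: ``model_`` (the :class:`FittedModel`), ``coef_``,
    ``intercept_``, ``classes_``; :meth:`performance` runs the stratified
    bootstrap evaluation on given data.
    """

    def __init__(self, n_boot: int = 5000, random_state: int | None = 0,
                 family: str = "custom"):
        self.n_boot = n_boot
        self.random_state = random_state
        self.family = family

    def fit(self, X, y):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float))
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        self.model_ = fit_logistic(df, (y == self.classes_[1]).astype(int),
                                   family=self.family)
        self.coef_ = self.model_.coefficients.to_numpy()[None, :]
        self.intercept_ = np.array([self.model_.intercept])
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float), columns=self.feature_names_in_)
        return self.model_.linear_predictor(df)

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]

    def performance(self, X, y) -> PerformanceSummary:
        y = np.asarray(y).astype(int)
        return evaluate(self.decision_function(X), (y == self.classes_[1]),
                        n_boot=self.n_boot, seed=self.random_state)
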