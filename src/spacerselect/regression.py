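"""Linear-model building pipeline: screening, selection, validation.

The pipeline mirrors standard small-cohort dosimetric modelling practice:

1. Pearson screening of candidate geometric predictors against the endpoint.
2. Ordinary least squares (y = b0 + b1 x1 + b2 x2 + ...), all metrics
   initially included, then reduced by backward stepwise AIC.
3. Variance-inflation-factor pruning (VIF < 5) against multicollinearity,
   and a cap on the number of predictors (3 by default for n = 21).
4. Structure coefficients rs = r_pears / sqrt(R^2) apportioning the
   explained variance among the retained predictors.
5. Leave-one-out cross-validation reporting predicted R^2 (1 - PRESS/SST),
   MAE and %MAE (MAE normalized by the observed endpoint range).

Mutually dependent predictors (e.g. rectum vs rectal-wall volume, which are
near-duplicates by construction) are declared in exclusive groups of which
at most one may enter any model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Term",
    "LinearModel",
    "FitReport",
    "LoocvResult",
    "StepwiseConfig",
    "MODEL1_CANDIDATES",
    "MODEL2_CANDIDATES",
    "pearson",
    "ols_fit",
    "gaussian_aic",
    "aic",
    "vif",
    "stepwise_select",
    "structure_coefficients",
    "squared_structure_coefficient",
    "loocv",
]

#: full candidate set (geometry plus distance transforms)
MODEL1_CANDIDATES = [
    "rectum_vol_cc",
    "rw_vol_cc",
    "ctv_vol_cc",
    "norm_ctv_pct",
    "rinptv_cc",
    "norm_rinptv_pct",
    "rw_to_ctv_cm",
    "rw_to_ctv_inv_cubed",
]

#: TPS-derivable candidates only (volumes and their normalizations; no
#: slice-wise Hausdorff metrics, which need extra computation)
MODEL2_CANDIDATES = [
    "rectum_vol_cc",
    "rw_vol_cc",
    "ctv_vol_cc",
    "norm_ctv_pct",
    "rinptv_cc",
    "norm_rinptv_pct",
]

#: rectum and rectal-wall volume are interchangeable but never joint
DEFAULT_EXCLUSIVE_GROUPS = [frozenset({"rectum_vol_cc", "rw_vol_cc"})]


@dataclass(frozen=True)
class Term:
    name: str
    beta: float
    se: float


@dataclass(frozen=True)
class LinearModel:
    """Fitted (or published) linear model y = intercept + sum(beta_i x_i)."""

    dependent: str
    intercept: Term
    terms: tuple
    r_squared: float
    p_value: float
    n: int

    @property
    def term_names(self) -> list:
        return [t.name for t in self.terms]

    def predict(self, features: Mapping[str, float]) -> float:
        missing = [t.name for t in self.terms if t.name not in features]
        if missing:
            raise KeyError(f"feature(s) missing for prediction: {missing}")
        return self.intercept.beta + sum(
            t.beta * float(features[t.name]) for t in self.terms
        )

    def predict_frame(self, t: pd.DataFrame) -> np.ndarray:
        x = t[self.term_names].to_numpy(dtype=float)
        betas = np.array([tm.beta for tm in self.terms])
        return self.intercept.beta + x @ betas

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "intercept": {"est": self.intercept.beta, "se": self.intercept.se},
            "terms": [{"name": t.name, "beta": t.beta, "se": t.se} for t in self.terms],
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass(frozen=True)
class FitReport:
    """Audit trail of a stepwise selection run."""

    pearson_table: pd.DataFrame          # per-candidate (r_pears, p)
    aic_trace: tuple                     # ((removed term or None, AIC), ...)
    vif_table: pd.DataFrame              # per-final-term VIF
    structure_coeffs: pd.DataFrame       # per-final-term rs, rs2
    alpha: float = 0.01


@dataclass(frozen=True)
class LoocvResult:
    predicted_r_squared: float
    mae: float
    pct_mae: float


@dataclass(frozen=True)
class StepwiseConfig:
    """Knobs of the selection pipeline (defaults match the standard recipe)."""

    candidates: tuple = tuple(MODEL1_CANDIDATES)
    vif_limit: float = 5.0
    max_predictors: int = 3
    exclusive_groups: tuple = tuple(DEFAULT_EXCLUSIVE_GROUPS)
    alpha: float = 0.01

    def __post_init__(self):
        if self.vif_limit <= 1:
            raise ValueError("vif_limit must be > 1")
        if self.max_predictors < 1:
            raise ValueError("max_predictors must be >= 1")


# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple:
    """Pearson correlation and two-sided p-value (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs equal-length columns with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _design(X: pd.DataFrame) -> np.ndarray:
    return sm.add_constant(X.to_numpy(dtype=float), has_constant="add")


def ols_fit(X: pd.DataFrame, y, dependent: str = "y") -> LinearModel:
    """Ordinary least squares with intercept.

    A constant response yields zero slopes, intercept = mean(y) and a
    reported R^2 of 0 (with a warning) rather than an error.
    """
    y = np.asarray(y, dtype=float)
    n, k = len(y), X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    design = _design(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if np.ptp(y) == 0:
        warnings.warn("constant response: R^2 reported as 0", stacklevel=2)
        terms = tuple(Term(c, 0.0, 0.0) for c in X.columns)
        return LinearModel(dependent, Term("const", float(y[0]), 0.0), terms, 0.0, 1.0, n)
    res = sm.OLS(y, design).fit()
    terms = tuple(
        Term(c, float(res.params[i + 1]), float(res.bse[i + 1]))
        for i, c in enumerate(X.columns)
    )
    return LinearModel(
        dependent=dependent,
        intercept=Term("const", float(res.params[0]), float(res.bse[0])),
        terms=terms,
        r_squared=float(res.rsquared),
        p_value=float(res.f_pvalue) if k > 0 else 1.0,
        n=n,
    )


def gaussian_aic(rss: float, n: int, n_slopes: int) -> float:
    """Gaussian-profile AIC: n ln(RSS/n) + 2 (k + 2).

    k slopes plus intercept plus the error variance are counted as
    parameters. A perfect fit (RSS = 0) returns -inf with a warning.
    """
    if rss <= 0:
        warnings.warn("zero residual sum of squares: AIC is -inf", stacklevel=2)
        return -math.inf
    return n * math.log(rss / n) + 2 * (n_slopes + 2)


def aic(model: LinearModel, X: pd.DataFrame, y) -> float:
    """AIC of a fitted model on its training data."""
    y = np.asarray(y, dtype=float)
    resid = y - model.predict_frame(X)
    return gaussian_aic(float(resid @ resid), len(y), len(model.terms))


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j on the remaining columns (with
    intercept). Exact collinearity yields an inf sentinel.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        design = _design(others)
        yj = X[col].to_numpy(dtype=float)
        beta, rss, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        rss = float(resid @ resid)
        sst = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - rss / sst if sst > 0 else 1.0
        out[col] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _fit_and_aic(t: pd.DataFrame, dependent: str, cols: Sequence[str]):
    X = t[list(cols)]
    y = t[dependent].to_numpy(dtype=float)
    model = ols_fit(X, y, dependent)
    return model, aic(model, X, y)


def _pvalues(t: pd.DataFrame, dependent: str, cols: Sequence[str]) -> pd.Series:
    design = _design(t[list(cols)])
    res = sm.OLS(t[dependent].to_numpy(dtype=float), design).fit()
    return pd.Series(res.pvalues[1:], index=list(cols))


def stepwise_select(
    t: pd.DataFrame, dependent: str, cfg: StepwiseConfig | None = None
) -> tuple:
    """Backward stepwise-AIC model selection with VIF and size constraints.

    All candidates (after exclusive-group resolution: the group member most
    correlated with the endpoint is kept) enter the initial model; the
    single term whose removal lowers AIC the most is dropped repeatedly
    until no removal lowers it. Then the highest-VIF term is dropped while
    any VIF >= vif_limit, and finally the predictor cap is enforced by
    further AIC-ordered removal. Equal-AIC removals (within 1e-9) are broken
    toward the term with the larger p-value.

    Returns (LinearModel, FitReport).
    """
    cfg = StepwiseConfig() if cfg is None else cfg
    candidates = [c for c in cfg.candidates if c in t.columns]
    if not candidates:
        raise ValueError("no candidate predictors present in the table")
    y = t[dependent].to_numpy(dtype=float)

    pearson_rows = {}
    for c in candidates:
        r, p = pearson(t[c], y)
        pearson_rows[c] = {"r_pears": r, "p": p}
    pearson_table = pd.DataFrame.from_dict(pearson_rows, orient="index")

    # exclusive groups: keep the member best correlated with the endpoint
    current = list(candidates)
    for group in cfg.exclusive_groups:
        members = [c for c in current if c in group]
        if len(members) > 1:
            keep = max(members, key=lambda c: abs(pearson_rows[c]["r_pears"]))
            current = [c for c in current if c not in group or c == keep]

    if len(t) <= len(current) + 1:
        raise ValueError(
            f"n = {len(t)} too small for {len(current)} candidates after "
            "group exclusion"
        )

    def best_removal(cols):
        """(term, aic_without) whose removal gives the lowest AIC."""
        pvals = _pvalues(t, dependent, cols)
        options = []
        for c in cols:
            remaining = [x for x in cols if x != c]
            if not remaining:
                # intercept-only model
                rss = float(((y - y.mean()) ** 2).sum())
                a = gaussian_aic(rss, len(y), 0)
            else:
                _, a = _fit_and_aic(t, dependent, remaining)
            options.append((c, a))
        best_aic = min(a for _, a in options)
        tied = [c for c, a in options if a <= best_aic + 1e-9]
        drop = max(tied, key=lambda c: pvals[c])  # larger p goes first
        return drop, best_aic

    # phase 0: exact collinearity makes the full model singular; drop the
    # infinite-VIF duplicate least correlated with the endpoint first
    trace = []
    while len(current) >= 2 and np.linalg.matrix_rank(_design(t[current])) < len(current) + 1:
        v = vif(t[current])
        dups = [c for c in current if not math.isfinite(v[c])]
        drop = min(dups, key=lambda c: abs(pearson_rows[c]["r_pears"]))
        current.remove(drop)
        trace.append((drop, math.nan))

    _, current_aic = _fit_and_aic(t, dependent, current)
    trace.append((None, current_aic))
    # phase 1: backward AIC
    while len(current) > 1:
        drop, a = best_removal(current)
        if a < current_aic - 1e-9:
            current.remove(drop)
            current_aic = a
            trace.append((drop, a))
        else:
            break
    # phase 2: VIF pruning
    while len(current) >= 2:
        v = vif(t[current])
        if (v < cfg.vif_limit).all():
            break
        drop = v.idxmax()
        current.remove(drop)
        _, current_aic = _fit_and_aic(t, dependent, current)
        trace.append((drop, current_aic))
    # phase 3: predictor cap
    while len(current) > cfg.max_predictors:
        drop, a = best_removal(current)
        current.remove(drop)
        current_aic = a
        trace.append((drop, a))

    model, _ = _fit_and_aic(t, dependent, current)
    sc = structure_coefficients(model, t)
    vif_table = (
        vif(t[current]).to_frame("vif")
        if len(current) >= 2
        else pd.DataFrame({"vif": [1.0]}, index=current)
    )
    report = FitReport(
        pearson_table=pearson_table,
        aic_trace=tuple(trace),
        vif_table=vif_table,
        structure_coeffs=sc,
        alpha=cfg.alpha,
    )
    return model, report


def squared_structure_coefficient(r_pears: float, r_squared: float) -> float:
    """rs^2 = r_pears^2 / R^2: share of the model-explained variance."""
    if r_squared <= 0:
        raise ValueError("structure coefficients undefined for R^2 <= 0")
    return r_pears**2 / r_squared


def structure_coefficients(m: LinearModel, t: pd.DataFrame) -> pd.DataFrame:
    """Per-term structure coefficients rs = r_pears / sqrt(R^2) and rs^2."""
    if m.r_squared <= 0:
        raise ValueError("structure coefficients undefined for R^2 <= 0")
    y = t[m.dependent].to_numpy(dtype=float)
    rows = {}
    for term in m.terms:
        r, _ = pearson(t[term.name], y)
        rs = r / math.sqrt(m.r_squared)
        rows[term.name] = {"rs": rs, "rs2": rs**2}
    return pd.DataFrame.from_dict(rows, orient="index")


def loocv(t: pd.DataFrame, terms: Sequence[str], dependent: str) -> LoocvResult:
    """Leave-one-out cross-validation of a fixed term set.

    Each row is predicted from an OLS refit on the other n-1 rows; the term
    set is never re-selected inside the folds. Predicted R^2 = 1 - PRESS/SST,
    MAE is the mean absolute held-out error and %MAE normalizes it by the
    observed range of the endpoint.
    """
    terms = list(terms)
    n = len(t)
    if n < len(terms) + 3:
        raise ValueError("too few rows for LOOCV with this term count")
    X = _design(t[terms])
    y = t[dependent].to_numpy(dtype=float)
    errors = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError(f"singular refit leaving out row {i}")
        errors[i] = y[i] - X[i] @ beta
    press = float(errors @ errors)
    sst = float(((y - y.mean()) ** 2).sum())
    mae = float(np.abs(errors).mean())
    rng = float(np.ptp(y))
    return LoocvResult(
        predicted_r_squared=1.0 - press / sst,
        mae=mae,
        pct_mae=100.0 * mae / rng,
    )
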