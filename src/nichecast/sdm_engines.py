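"""Eight suitability-model families behind one interface.

Every family fits on a weighted :class:`~nichecast.weighting_selection.TrainingTable`
(presence-only families use its presence rows and ignore weights) and
predicts a per-cell suitability in ``[0, 1]`` on any grid carrying the
same variables:

=============  =====================================================
GAM            weighted binomial additive model, per-variable B-spline
               basis of dimension 3 (curvature-limited smooth)
GLM            weighted binomial regression with linear + quadratic terms
CART           single weighted classification tree, cost-complexity
               pruned by internal cross-validation (1-SE rule)
BRT            stagewise gradient boosting of shallow trees on Bernoulli
               deviance; tree count chosen on a held-out split
BIOCLIM        percentile-position climatic envelope, min over variables
DOMAIN         Gower similarity to the most similar presence
MAHAL          1 − squared Mahalanobis distance to the presence centroid,
               linearly rescaled to [0, 1] over the prediction region
MAXENT_LIKE    regularized presence/background exponential model with
               linear+quadratic features and an entropy-based logistic
               output (an approximation in spirit, not a port, of the
               well-known maximum-entropy program)
=============  =====================================================

The shared ``[0, 1]`` scale is what makes consensus and variance maps
across families meaningful.
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .geo_io import EnvGrid
from .weighting_selection import TrainingTable

__all__ = [
    "SuitabilityModel", "ConstantModel",
    "fit_gam_k3", "fit_glm_quadratic", "fit_cart", "fit_brt",
    "fit_bioclim", "fit_domain", "fit_mahalanobis", "fit_maxent_like",
    "rescale_unit", "predict_map", "FAMILY_FITTERS",
    "save_model", "load_model",
]

_CLIP = 1e-9


# ---------------------------------------------------------------------------
# Shared interface
# ---------------------------------------------------------------------------

class SuitabilityModel(abc.ABC):
    """A fitted model mapping predictor vectors to suitability in [0, 1]."""

    family: str = ""
    variables: tuple[str, ...] = ()
    supports_weights: bool = False

    @abc.abstractmethod
    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        """Suitability for each row of ``X`` (columns ⊇ self.variables)."""

    def predict_map(self, grid: EnvGrid) -> np.ndarray:
        return predict_map(self, grid)


class ConstantModel(SuitabilityModel):
    """Degenerate model predicting one value everywhere (null fits)."""

    def __init__(self, value: float, family: str = "CONST",
                 variables: Sequence[str] = ()):
        self.value = float(value)
        self.family = family
        self.variables = tuple(variables)

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        return np.full(len(X), self.value)


def rescale_unit(values: np.ndarray) -> np.ndarray:
    """Linearly rescale so the (nan-ignoring) min maps to 0 and max to 1."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = np.nanmin(values), np.nanmax(values)
    if not vmax > vmin:
        raise ValueError("rescale_unit is undefined for constant input")
    return (values - vmin) / (vmax - vmin)


def predict_map(model: SuitabilityModel, grid: EnvGrid) -> np.ndarray:
    """Per-cell suitability map: values in [0, 1] on valid cells, NaN off-mask.

    For the Mahalanobis family the raw ``1 − D²`` scores are rescaled to
    [0, 1] over the *target grid's* valid cells, so current and future
    maps each span the unit interval.
    """
    X = grid.table(list(model.variables)) if model.variables else grid.table()
    if isinstance(model, MahalanobisModel):
        vals = rescale_unit(model.raw_scores(X))
    else:
        vals = model.predict_rows(X)
    out = np.full(grid.mask.shape, np.nan)
    out[grid.mask] = vals
    return out


# ---------------------------------------------------------------------------
# Weighted binomial regression backbones (GAM / GLM / forward selection)
# ---------------------------------------------------------------------------

def _spline_knots(x: np.ndarray) -> tuple[float, float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise ValueError("degenerate (constant) variable for spline basis")
    mid = float(np.median(x))
    if not lo < mid < hi:
        mid = 0.5 * (lo + hi)
    return lo, mid, hi


def _spline_columns(x: np.ndarray, knots: tuple[float, float, float]) -> np.ndarray:
    """Degree-2 B-spline basis with one interior knot; first column dropped
    (it is redundant with the intercept), leaving 3 columns."""
    lo, mid, hi = knots
    t = np.array([lo, lo, lo, mid, hi, hi, hi])
    xc = np.clip(x, lo, hi)  # predictions outside the fit range are clamped
    dm = BSpline.design_matrix(xc, t, 2).toarray()
    return dm[:, 1:]


def _design(X: pd.DataFrame, variables: Sequence[str], kind: str,
            knots: Mapping[str, tuple] | None = None) -> np.ndarray:
    cols = [np.ones(len(X))]
    for v in variables:
        x = X[v].to_numpy(dtype=float)
        if kind == "glm_quadratic":
            cols += [x, x**2]
        elif kind == "gam_k3":
            cols.append(_spline_columns(x, knots[v]))
        else:
            raise ValueError(f"unknown design kind {kind!r}")
    return np.column_stack(cols)


def _fit_binomial(design: np.ndarray, y: np.ndarray, w: np.ndarray,
                  variables: Sequence[str]):
    try:
        with warnings.catch_warnings():
            # extreme fitted logits overflow expit inside IRLS; harmless
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.GLM(y, design, family=sm.families.Binomial(),
                         var_weights=w).fit(maxiter=200)
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(
            f"binomial fit failed for variables {list(variables)}: {exc}"
        ) from exc
    if np.isnan(res.params).any():
        raise RuntimeError(f"binomial fit diverged for variables {list(variables)}")
    return res


def _forward_fit_stats(table: TrainingTable, variables: Sequence[str],
                       fit_family: str) -> tuple[float, float, int]:
    """(deviance, AIC, n_params) for one step of forward selection.

    Weights are normalized to sum to the row count before fitting; AIC is
    scale-dependent in the weights, and this convention keeps it
    comparable across steps. For 0/1 responses the saturated
    log-likelihood is zero, so AIC is computed as deviance + 2k — this
    stays finite even when fitted probabilities saturate at 0 or 1
    (where the textbook log-likelihood formula overflows).
    """
    wn = table.normalized_weights()
    knots = None
    if fit_family == "gam_k3":
        knots = {v: _spline_knots(table.X[v].to_numpy()) for v in variables}
    design = _design(table.X, variables, fit_family if variables else "glm_quadratic",
                     knots)
    res = _fit_binomial(design, table.y, wn, variables)
    k = design.shape[1]
    return float(res.deviance), float(res.deviance) + 2.0 * k, k


class _RegressionModel(SuitabilityModel):
    supports_weights = True

    def __init__(self, family: str, kind: str, variables: Sequence[str],
                 params: np.ndarray, knots: Mapping[str, tuple] | None = None):
        self.family = family
        self.kind = kind
        self.variables = tuple(variables)
        self.params = np.asarray(params, dtype=float)
        self.knots = dict(knots or {})

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        design = _design(X, self.variables, self.kind, self.knots) \
            if self.variables else np.ones((len(X), 1))
        return expit(design @ self.params)


def _fit_regression(table: TrainingTable, variables, family: str, kind: str):
    variables = tuple(variables if variables is not None else table.variables)
    wn = table.normalized_weights()
    if not variables:
        res = _fit_binomial(np.ones((len(table.y), 1)), table.y, wn, [])
        return _RegressionModel(family, kind, (), res.params)
    knots = None
    if kind == "gam_k3":
        knots = {v: _spline_knots(table.X[v].to_numpy()) for v in variables}
    design = _design(table.X, variables, kind, knots)
    res = _fit_binomial(design, table.y, wn, variables)
    return _RegressionModel(family, kind, variables, res.params, knots)


def fit_gam_k3(table: TrainingTable, variables: Sequence[str] | None = None
               ) -> SuitabilityModel:
    """Weighted binomial additive model with basis dimension 3 per variable.

    Realized as a degree-2 B-spline basis with a single interior knot at
    the training median (3 free columns per variable after dropping the
    intercept-redundant one) — the same quadratic-like capacity as an
    ``mgcv`` smooth with ``k = 3``. Predictions clamp each variable to its
    training range rather than extrapolating the spline.
    """
    return _fit_regression(table, variables, "GAM", "gam_k3")


def fit_glm_quadratic(table: TrainingTable, variables: Sequence[str] | None = None
                      ) -> SuitabilityModel:
    """Weighted binomial regression on {x, x²} for every predictor."""
    return _fit_regression(table, variables, "GLM", "glm_quadratic")


# ---------------------------------------------------------------------------
# Tree-based families
# ---------------------------------------------------------------------------

def _weighted_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, _CLIP, 1 - _CLIP)
    return float(-2.0 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


class CARTModel(SuitabilityModel):
    family = "CART"
    supports_weights = True

    def __init__(self, tree: DecisionTreeClassifier, variables: Sequence[str]):
        self.tree = tree
        self.variables = tuple(variables)

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.tree.predict_proba(X[list(self.variables)].to_numpy())
        if proba.shape[1] == 1:  # single-class training data
            return np.full(len(X), float(self.tree.classes_[0]))
        return proba[:, list(self.tree.classes_).index(1)]


def fit_cart(table: TrainingTable, variables: Sequence[str] | None = None,
             seed: int = 0, n_folds: int = 5, min_samples_leaf: int = 5
             ) -> SuitabilityModel:
    """Single weighted classification tree with cost-complexity pruning.

    The pruning strength (``ccp_alpha``) is chosen by internal stratified
    cross-validation on weighted Bernoulli deviance with the 1-SE rule
    (largest alpha within one standard error of the minimum), so pure
    noise collapses to the root and the leaf predictions are weighted
    presence proportions. Weights are normalized to mean 1, making the fit
    invariant to rescaling all weights.
    """
    variables = tuple(variables if variables is not None else table.variables)
    X = table.X[list(variables)].to_numpy()
    y, w = table.y, table.w / table.w.mean()

    path = DecisionTreeClassifier(
        random_state=seed, min_samples_leaf=min_samples_leaf
    ).cost_complexity_pruning_path(X, y, sample_weight=w)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > 25:  # thin a long pruning sequence
        alphas = alphas[np.linspace(0, len(alphas) - 1, 25).round().astype(int)]

    if len(alphas) > 1:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        dev = np.zeros((len(alphas), n_folds))
        for f, (tr, va) in enumerate(skf.split(X, y)):
            for i, a in enumerate(alphas):
                t = DecisionTreeClassifier(
                    random_state=seed, ccp_alpha=a,
                    min_samples_leaf=min_samples_leaf,
                ).fit(X[tr], y[tr], sample_weight=w[tr])
                proba = t.predict_proba(X[va])
                p = proba[:, 1] if proba.shape[1] == 2 else np.full(len(va), float(t.classes_[0]))
                dev[i, f] = _weighted_deviance(y[va], p, w[va]) / w[va].sum()
        mean, se = dev.mean(axis=1), dev.std(axis=1, ddof=1) / np.sqrt(n_folds)
        i_min = int(np.argmin(mean))
        cutoff = mean[i_min] + se[i_min]
        best_alpha = float(alphas[np.nonzero(mean <= cutoff)[0].max()])
    else:
        best_alpha = float(alphas[0]) if len(alphas) else 0.0

    tree = DecisionTreeClassifier(
        random_state=seed, ccp_alpha=best_alpha, min_samples_leaf=min_samples_leaf
    ).fit(X, y, sample_weight=w)
    return CARTModel(tree, variables)


class BRTModel(SuitabilityModel):
    family = "BRT"
    supports_weights = True

    def __init__(self, booster: GradientBoostingClassifier,
                 variables: Sequence[str], train_deviance: np.ndarray):
        self.booster = booster
        self.variables = tuple(variables)
        #: training-set loss after each boosting stage (non-increasing)
        self.train_deviance = train_deviance

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        return self.booster.predict_proba(X[list(self.variables)].to_numpy())[:, 1]


def fit_brt(table: TrainingTable, variables: Sequence[str] | None = None,
            learning_rate: float = 0.01, max_depth: int = 3,
            n_estimators: int = 500, val_fraction: float = 0.2,
            seed: int = 0) -> SuitabilityModel:
    """Boosted regression trees on Bernoulli deviance with case weights.

    The number of trees is chosen by held-out deviance: an internal
    stratified 80/20 split is boosted to ``n_estimators`` stages and the
    stage minimizing held-out weighted deviance is kept; the model is then
    refitted on all rows with that stage count. ``n_estimators = 0``
    returns the constant weighted-prevalence model.
    """
    variables = tuple(variables if variables is not None else table.variables)
    w = table.w / table.w.mean()
    if n_estimators == 0:
        prev = float(np.sum(table.w * table.y) / table.w.sum())
        return ConstantModel(prev, family="BRT", variables=variables)
    X = table.X[list(variables)].to_numpy()
    y = table.y

    idx = np.arange(len(y))
    tr, va = train_test_split(idx, test_size=val_fraction, stratify=y,
                              random_state=seed)
    booster = GradientBoostingClassifier(
        n_estimators=n_estimators, learning_rate=learning_rate,
        max_depth=max_depth, random_state=seed,
    ).fit(X[tr], y[tr], sample_weight=w[tr])
    val_dev = [
        _weighted_deviance(y[va], expit(s.ravel()), w[va])
        for s in booster.staged_decision_function(X[va])
    ]
    best_n = int(np.argmin(val_dev)) + 1

    final = GradientBoostingClassifier(
        n_estimators=best_n, learning_rate=learning_rate,
        max_depth=max_depth, random_state=seed,
    ).fit(X, y, sample_weight=w)
    return BRTModel(final, variables, np.asarray(final.train_score_))


# ---------------------------------------------------------------------------
# Presence-only families (weights are ignored by construction)
# ---------------------------------------------------------------------------

def _presence_frame(table_or_X, variables=None) -> pd.DataFrame:
    if isinstance(table_or_X, TrainingTable):
        X = table_or_X.X[table_or_X.y == 1]
    else:
        X = table_or_X
    if variables is not None:
        X = X[list(variables)]
    return X.reset_index(drop=True)


class BioclimModel(SuitabilityModel):
    family = "BIOCLIM"

    def __init__(self, presence_values: Mapping[str, np.ndarray]):
        self.presence_values = {k: np.sort(v) for k, v in presence_values.items()}
        self.variables = tuple(self.presence_values)

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        score = np.ones(len(X))
        for v, sorted_vals in self.presence_values.items():
            x = X[v].to_numpy(dtype=float)
            n = len(sorted_vals)
            less = np.searchsorted(sorted_vals, x, side="left")
            leq = np.searchsorted(sorted_vals, x, side="right")
            F = (less + leq) / (2.0 * n)  # mid-rank empirical CDF
            s = 1.0 - 2.0 * np.abs(F - 0.5)
            s[(x < sorted_vals[0]) | (x > sorted_vals[-1])] = 0.0
            score = np.minimum(score, s)
        return score


def fit_bioclim(table_presences_only, variables: Sequence[str] | None = None
                ) -> SuitabilityModel:
    """Percentile-position climatic envelope.

    Per variable the score is ``1 − 2·|F(x) − 0.5|`` with ``F`` the
    mid-rank empirical CDF of the presence sample (1 at the presence
    median, 0 outside the presence range); the cell score is the minimum
    over variables.
    """
    P = _presence_frame(table_presences_only, variables)
    if P.empty:
        raise ValueError("BIOCLIM needs at least one presence row")
    return BioclimModel({v: P[v].to_numpy(dtype=float) for v in P.columns})


class DomainModel(SuitabilityModel):
    family = "DOMAIN"

    def __init__(self, presences: np.ndarray, ranges: np.ndarray,
                 variables: Sequence[str]):
        self.presences = presences  # (n_presence, V)
        self.ranges = ranges        # (V,)
        self.variables = tuple(variables)

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[list(self.variables)].to_numpy(dtype=float)
        out = np.empty(len(Xv))
        for start in range(0, len(Xv), 2048):  # chunked: cells × presences × V
            chunk = Xv[start:start + 2048]
            d = np.abs(chunk[:, None, :] - self.presences[None, :, :]) / self.ranges
            sim = 1.0 - d.mean(axis=2)
            out[start:start + 2048] = sim.max(axis=1)
        return np.clip(out, 0.0, 1.0)


def fit_domain(table_presences_only, variables: Sequence[str] | None = None
               ) -> SuitabilityModel:
    """Gower similarity to the most similar presence record.

    ``sim(c, p) = 1 − (1/V) Σ_v |x_cv − x_pv| / range_v`` with ranges taken
    over the presence rows; the cell score is the max over presences,
    clamped to [0, 1].
    """
    P = _presence_frame(table_presences_only, variables)
    if P.empty:
        raise ValueError("DOMAIN needs at least one presence row")
    vals = P.to_numpy(dtype=float)
    ranges = vals.max(axis=0) - vals.min(axis=0)
    if (ranges <= 0).any():
        bad = [c for c, r in zip(P.columns, ranges) if r <= 0]
        raise ValueError(f"zero range in variables {bad}; remove degenerate variables")
    return DomainModel(vals, ranges, P.columns)


class MahalanobisModel(SuitabilityModel):
    """``1 − D²`` to the presence centroid; rescaled to [0, 1] at prediction.

    ``raw_scores`` returns the unbounded ``1 − D²`` values (1 at the
    centroid, large negative far away); ``predict_rows`` rescales within
    the supplied batch, while :func:`predict_map` rescales over the target
    grid's valid cells.
    """

    family = "MAHAL"

    def __init__(self, mean: np.ndarray, cov: np.ndarray, variables: Sequence[str]):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self.variables = tuple(variables)
        try:
            self._cov_inv = np.linalg.inv(self.cov)
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular presence covariance; remove degenerate variables"
            ) from exc

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        d = X[list(self.variables)].to_numpy(dtype=float) - self.mean
        d2 = np.einsum("ij,jk,ik->i", d, self._cov_inv, d)
        return 1.0 - d2

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        return rescale_unit(self.raw_scores(X))


def fit_mahalanobis(table_presences_only, variables: Sequence[str] | None = None
                    ) -> SuitabilityModel:
    P = _presence_frame(table_presences_only, variables)
    if len(P) <= len(P.columns):
        raise ValueError("too few presences to estimate a covariance")
    vals = P.to_numpy(dtype=float)
    return MahalanobisModel(vals.mean(axis=0), np.cov(vals, rowvar=False), P.columns)


# ---------------------------------------------------------------------------
# Maximum-entropy-style presence/background model
# ---------------------------------------------------------------------------

class MaxentLikeModel(SuitabilityModel):
    family = "MAXENT_LIKE"

    def __init__(self, variables, beta, feat_mean, feat_sd, log_z, entropy):
        self.variables = tuple(variables)
        self.beta = np.asarray(beta, dtype=float)
        self.feat_mean = feat_mean
        self.feat_sd = feat_sd
        self.log_z = float(log_z)       # log Σ_bg exp(η) over training background
        self.entropy = float(entropy)   # entropy of the fitted background density

    def _features(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for v in self.variables:
            x = X[v].to_numpy(dtype=float)
            cols += [x, x**2]
        F = np.column_stack(cols)
        return (F - self.feat_mean) / self.feat_sd

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        eta = self._features(X) @ self.beta
        # logistic output at tau = 0.5: exp(H)·q(x) / (1 + exp(H)·q(x))
        return expit(self.entropy + eta - self.log_z)


def fit_maxent_like(table: TrainingTable, variables: Sequence[str] | None = None,
                    l1: float = 0.01) -> SuitabilityModel:
    """Regularized presence/background exponential (Gibbs) model.

    Maximizes the presence log-likelihood of the density
    ``q(x) ∝ exp(β·f(x))`` over the background cells, with linear and
    quadratic features (standardized against the background) and an exact
    L1 penalty via the positive/negative-part split. The logistic output
    uses the entropy transform at its default ``τ = 0.5``: a model
    indistinguishable from the background maps to 0.5 everywhere. This is
    a documented approximation of the classic maximum-entropy SDM, not a
    port of it.
    """
    variables = tuple(variables if variables is not None else table.variables)
    pres = table.X.loc[table.y == 1, list(variables)]
    bg = table.X.loc[table.y == 0, list(variables)]
    if pres.empty or bg.empty:
        raise ValueError("need presence and background rows")

    def raw_features(df):
        cols = []
        for v in variables:
            x = df[v].to_numpy(dtype=float)
            cols += [x, x**2]
        return np.column_stack(cols)

    Fb_raw = raw_features(bg)
    mean, sd = Fb_raw.mean(axis=0), Fb_raw.std(axis=0)
    sd[sd == 0] = 1.0
    Fb = (Fb_raw - mean) / sd
    Fp = (raw_features(pres) - mean) / sd
    k = Fb.shape[1]
    fp_mean = Fp.mean(axis=0)

    def objective(uv):
        beta = uv[:k] - uv[k:]
        eta = Fb @ beta
        lse = logsumexp(eta)
        q = np.exp(eta - lse)
        f = lse - np.log(len(Fb)) - fp_mean @ beta + l1 * uv.sum()
        g = q @ Fb - fp_mean
        return f, np.concatenate([g + l1, -g + l1])

    res = minimize(objective, np.zeros(2 * k), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * k),
                   options={"maxiter": 500, "ftol": 1e-12})
    beta = res.x[:k] - res.x[k:]
    eta_b = Fb @ beta
    log_z = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_z)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    return MaxentLikeModel(variables, beta, mean, sd, log_z, entropy)


_SERIAL_FORMAT = 1


def save_model(model: SuitabilityModel, path: str | Path) -> None:
    """Persist a fitted model (versioned joblib payload)."""
    joblib.dump({"format": _SERIAL_FORMAT, "family": model.family,
                 "model": model}, path)


def load_model(path: str | Path) -> SuitabilityModel:
    payload = joblib.load(path)
    if payload.get("format") != _SERIAL_FORMAT:
        raise ValueError(f"unsupported model format {payload.get('format')!r}")
    return payload["model"]


#: Family name → fitting function over a TrainingTable.
FAMILY_FITTERS = {
    "GAM": fit_gam_k3,
    "GLM": fit_glm_quadratic,
    "CART": fit_cart,
    "BRT": fit_brt,
    "BIOCLIM": fit_bioclim,
    "DOMAIN": fit_domain,
    "MAHAL": fit_mahalanobis,
    "MAXENT_LIKE": fit_maxent_like,
}
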