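"""Penalized-spline regression with AR1 pre-whitening and ML smoothing
parameter selection."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin, clone

from ..errors import ConfigError, FitError
from .design import DesignBuilder, SmoothTerm

_LOGLAM_CLIP = 30.0
_BIG = 1e10


@dataclass
class ModelSpec:
    """Declarative model description (thin wrapper over the estimator)."""
    response: str
    terms: Sequence[SmoothTerm]
    factors: Sequence[str] = ()
    ar1_rho: float = 0.8
    series_cols: Tuple[str, ...] = ("token_id", "dimension")
    time_col: str = "time"

    def validate(self) -> "ModelSpec":
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigError(f"ar1_rho must lie in [0, 1), got {self.ar1_rho!r}")
        seen = set()
        for t in self.terms:
            key = (t.kind, t.covariates, t.by, t.group)
            if key in seen:
                raise ConfigError(f"duplicate smooth term {key}")
            seen.add(key)
        return self


class PenalizedSplineGAM(BaseEstimator, RegressorMixin):
    """Gaussian penalized-spline additive model.

    Within each series (default: token x dimension) rows are AR1
    pre-whitened with the fixed autocorrelation ``ar1_rho`` (first sample
    weighted by sqrt(1 - rho^2)). Smoothing parameters maximize the exact
    Gaussian log marginal likelihood with the residual variance profiled
    out, searched by Nelder-Mead over log(lambda) with optional random
    restarts; coefficients come from penalized least squares at the optimum.

    Fitted attributes
    -----------------
    coef_, lambda_ (per penalty), ml_score_ (negative log marginal
    likelihood; lower is better), edf_ (per term), edf_total_, sigma2_,
    residuals_ (response scale, original row order), n_used_.
    """

    def __init__(self, terms: Sequence[SmoothTerm] = (),
                 factors: Sequence[str] = (),
                 ar1_rho: float = 0.8,
                 series_cols: Sequence[str] = ("token_id", "dimension"),
                 time_col: str = "time",
                 n_restarts: int = 1,
                 maxfev: Optional[int] = None,
                 optimizer: str = "Powell",
                 lambdas: Optional[Sequence[float]] = None,
                 init_loglam: Optional[Sequence[float]] = None,
                 random_state: int = 0):
        self.terms = terms
        self.factors = factors
        self.ar1_rho = ar1_rho
        self.series_cols = series_cols
        self.time_col = time_col
        self.n_restarts = n_restarts
        self.maxfev = maxfev
        self.optimizer = optimizer
        self.lambdas = lambdas
        self.init_loglam = init_loglam
        self.random_state = random_state

    # -- AR1 whitening -----------------------------------------------------

    def _whiten(self, df: pd.DataFrame, X: np.ndarray, y: np.ndarray):
        rho = self.ar1_rho
        if not (0.0 <= rho < 1.0):
            raise ConfigError(f"ar1_rho must lie in [0, 1), got {rho!r}")
        cols = [df[c].to_numpy() for c in self.series_cols]
        order = np.lexsort(tuple([df[self.time_col].to_numpy()] + cols[::-1]))
        if rho == 0.0:
            return X, y
        Xs, ys = X[order], y[order]
        series = list(zip(*[c[order] for c in cols]))
        first = np.ones(len(df), dtype=bool)
        for i in range(1, len(series)):
            first[i] = series[i] != series[i - 1]
        Xw = Xs.copy()
        yw = ys.copy()
        Xw[1:] -= rho * Xs[:-1]
        yw[1:] -= rho * ys[:-1]
        w0 = math.sqrt(1.0 - rho ** 2)
        Xw[first] = Xs[first] * w0
        yw[first] = ys[first] * w0
        return Xw, yw

    # -- ML criterion ------------------------------------------------------

    def _assemble_S(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self._p, self._p))
        for sl, Sj, j, _ in self._penalties:
            S[sl, sl] += lam[j] * Sj
        return S

    def _score(self, loglam: np.ndarray) -> float:
        lam = np.exp(np.clip(loglam, -_LOGLAM_CLIP, _LOGLAM_CLIP))
        S = self._assemble_S(lam)
        A = self._XtX + S
        try:
            cA = cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return _BIG
        beta = cho_solve(cA, self._Xty, check_finite=False)
        rss = float(self._yty - 2.0 * beta @ self._Xty
                    + beta @ (self._XtX @ beta))
        pen = float(beta @ (S @ beta))
        dev = max(rss + pen, 1e-300)
        nmp = self._n - self._Mp
        sig2 = dev / nmp
        logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
        St = self._U.T @ S @ self._U
        try:
            cS = cho_factor(St, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return _BIG
        logdetS = 2.0 * np.sum(np.log(np.diag(cS[0])))
        score = 0.5 * (nmp * (math.log(2.0 * math.pi * sig2) + 1.0)
                       + logdetA - logdetS)
        if not math.isfinite(score):
            return _BIG
        return score

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "PenalizedSplineGAM":
        df = X.reset_index(drop=True)
        if y is None:
            raise ConfigError("y (the response) is required")
        yv = np.asarray(y, dtype=float)
        if len(yv) != len(df):
            raise ConfigError("X and y lengths differ")

        builder = DesignBuilder(list(self.terms), list(self.factors)).fit(df)
        Xmat = builder.X_
        self.builder_ = builder
        self._p = builder.p_
        self._penalties = builder.penalties_
        n_lam = builder.n_lambda_

        Xw, yw = self._whiten(df, Xmat, yv)
        self._XtX = Xw.T @ Xw
        self._Xty = Xw.T @ yw
        self._yty = float(yw @ yw)
        self._n = len(yv)

        if n_lam > 0:
            S_sum = self._assemble_S(np.ones(n_lam))
            evals, evecs = np.linalg.eigh(S_sum)
            tol = evals.max() * 1e-10 if evals.size else 0.0
            keep = evals > tol
            self._U = evecs[:, keep]
            self._Mp = self._p - int(keep.sum())
        else:
            self._U = np.zeros((self._p, 0))
            self._Mp = self._p

        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            if lam.shape != (n_lam,):
                raise ConfigError(f"lambdas must have length {n_lam}")
            best_loglam = None
        elif n_lam == 0:
            lam = np.zeros(0)
            best_loglam = np.zeros(0)
        else:
            x0 = (np.zeros(n_lam) if self.init_loglam is None
                  else np.asarray(self.init_loglam, dtype=float))
            if x0.shape != (n_lam,):
                raise ConfigError(f"init_loglam must have length {n_lam}")
            rng = np.random.default_rng(self.random_state)
            maxfev = self.maxfev or max(2000, 400 * n_lam)
            if self.optimizer == "Powell":
                options = {"maxfev": maxfev, "xtol": 1e-4, "ftol": 1e-6}
            elif self.optimizer == "Nelder-Mead":
                options = {"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-4}
            else:
                raise ConfigError(f"unknown optimizer {self.optimizer!r}")
            best_loglam, best_val = None, np.inf
            for r in range(max(1, self.n_restarts)):
                start = x0 if r == 0 else x0 + rng.normal(0.0, 2.0, n_lam)
                res = minimize(self._score, start, method=self.optimizer,
                               options=options)
                if res.fun < best_val:
                    best_val, best_loglam = res.fun, res.x
            lam = np.exp(np.clip(best_loglam, -_LOGLAM_CLIP, _LOGLAM_CLIP))

        S = self._assemble_S(lam)
        A = self._XtX + S
        try:
            cA = cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular penalized system; reduce basis sizes "
                           "or add data") from exc
        beta = cho_solve(cA, self._Xty, check_finite=False)

        rss = float(self._yty - 2.0 * beta @ self._Xty + beta @ (self._XtX @ beta))
        pen = float(beta @ (S @ beta))
        F = cho_solve(cA, self._XtX, check_finite=False)
        diagF = np.diag(F)

        self.coef_ = beta
        self.lambda_ = lam
        self.loglam_ = (np.log(lam) if np.all(lam > 0)
                        else np.full_like(lam, -np.inf))
        self.penalty_names_ = [name for *_, name in self._penalties]
        self.edf_ = {ft.term.name: float(diagF[ft.sl].sum())
                     for ft in builder.fitted_terms_}
        self.edf_total_ = float(diagF.sum())
        nmp = self._n - self._Mp
        self.sigma2_ = (rss + pen) / nmp if nmp > 0 else np.nan
        if n_lam > 0 and np.all(lam > 0):
            self.ml_score_ = self._score(np.log(lam))
        elif n_lam == 0:
            sig2 = rss / self._n
            self.ml_score_ = 0.5 * self._n * (math.log(2 * math.pi * sig2) + 1)
        else:
            self.ml_score_ = np.nan  # improper prior at lambda = 0
        fitted = Xmat @ beta
        self.residuals_ = yv - fitted
        self.fitted_values_ = fitted
        self.n_used_ = self._n
        self.train_quantile_source_ = df
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, X: pd.DataFrame,
                exclude_kinds: Sequence[str] = ()) -> np.ndarray:
        Xmat = self.builder_.transform(X.reset_index(drop=True))
        if exclude_kinds:
            Xmat = Xmat.copy()
            for ft in self.builder_.fitted_terms_:
                if ft.term.kind in exclude_kinds:
                    Xmat[:, ft.sl] = 0.0
        return Xmat @ self.coef_

    def term_effect(self, X: pd.DataFrame, term_name: str) -> np.ndarray:
        """Contribution of a single smooth term at the given rows."""
        Xmat = self.builder_.transform(X.reset_index(drop=True))
        for ft in self.builder_.fitted_terms_:
            if ft.term.name == term_name:
                return Xmat[:, ft.sl] @ self.coef_[ft.sl]
        raise ConfigError(f"no term named {term_name!r}; have "
                          f"{[f.term.name for f in self.builder_.fitted_terms_]}")


def fit_model(table: pd.DataFrame, spec: ModelSpec,
              **estimator_kwargs) -> PenalizedSplineGAM:
    """Fit a :class:`ModelSpec` on a long modelling table."""
    spec.validate()
    est = PenalizedSplineGAM(
        terms=list(spec.terms), factors=list(spec.factors),
        ar1_rho=spec.ar1_rho, series_cols=tuple(spec.series_cols),
        time_col=spec.time_col, **estimator_kwargs)
    return est.fit(table, table[spec.response].to_numpy(float))


def trim_and_refit(fit: PenalizedSplineGAM, table: pd.DataFrame,
                   y: np.ndarray | None = None, k: float = 2.5,
                   response: str = "response"
                   ) -> Tuple[PenalizedSplineGAM, np.ndarray]:
    """Drop rows with |standardized residual| > k once, refit, return
    (refit, kept mask). Warns when more than 20% of rows are trimmed."""
    if y is None:
        y = table[response].to_numpy(float)
    resid = fit.residuals_
    sd = resid.std()
    keep = np.abs(resid - resid.mean()) <= k * sd if sd > 0 else np.ones(len(resid), bool)
    frac = 1.0 - keep.mean()
    if frac > 0.2:
        warnings.warn(f"residual trimming removed {frac:.1%} of rows")
    sub = table.reset_index(drop=True).loc[keep]
    refit = clone(fit).fit(sub, np.asarray(y)[keep])
    refit.n_used_ = int(keep.sum())
    return refit, keep


def predict_percentile_trajectories(fit: PenalizedSplineGAM,
                                    variable: str,
                                    percentiles: Sequence[float] = (10, 30, 50, 70, 90),
                                    n_time: int = 100,
                                    word_class: Optional[str] = None
                                    ) -> pd.DataFrame:
    """Predicted F1/F2 trajectories over a [0, 1] time grid at percentiles
    of ``variable``, other covariates held at medians / modal levels.

    Group smooths are excluded (population-level trajectories). Returns a
    long table (percentile, variable value, dimension, time, predicted).
    """
    for p in percentiles:
        if not (0 < p < 100):
            raise ConfigError(f"percentile must lie in (0, 100), got {p}")
    df = fit.train_quantile_source_
    grid_t = np.linspace(0.0, 1.0, n_time)
    num_cols = df.select_dtypes(include=[np.number]).columns
    medians = {c: float(df[c].median()) for c in num_cols}
    if word_class is None and "word_class" in df.columns:
        word_class = df["word_class"].mode().iloc[0]

    rows = []
    for p in percentiles:
        v = float(np.percentile(df[variable].to_numpy(float), p))
        for dim in sorted(df["dimension"].unique()) if "dimension" in df.columns else [""]:
            new = pd.DataFrame({"time": grid_t})
            for c, m in medians.items():
                if c != "time":
                    new[c] = m
            new[variable] = v
            if "dimension" in df.columns:
                new["dimension"] = dim
            if "word_class" in df.columns:
                new["word_class"] = word_class
            if "dbc" in df.columns:
                new["dbc"] = f"{dim}.{word_class}"
            for c in df.columns:
                if c not in new.columns:
                    new[c] = df[c].mode().iloc[0]
            pred = fit.predict(new, exclude_kinds=("group_smooth",))
            for t, val in zip(grid_t, pred):
                rows.append((p, v, dim, float(t), float(val)))
    return pd.DataFrame(rows, columns=["percentile", "variable_value",
                                       "dimension", "time", "predicted"])
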