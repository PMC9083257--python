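"""Vowel-duration analysis: crossed-random-intercept LMM and rank
correlations.

Log vowel duration is regressed on network activation with local speaking
rate and segment count as controls and crossed random intercepts for
speaker and word, fitted by maximum likelihood (Gaussian). The model is
estimated through a variance-components parameterization; forcing both
variance components to zero reduces it exactly to OLS.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataError, FitError


@dataclass
class DurationFit:
    coefficients: Dict[str, float]
    std_errors: Dict[str, float]
    t_values: Dict[str, float]
    variance_components: Dict[str, float]  # speaker, word, residual (variances)
    sd_components: Dict[str, float] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    n_obs: int = 0
    method: str = "ML"

    def __post_init__(self):
        if any(v < -1e-10 for v in self.variance_components.values()):
            raise FitError("negative variance component at optimum")
        if not self.sd_components:
            self.sd_components = {k: float(np.sqrt(max(v, 0.0)))
                                  for k, v in self.variance_components.items()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class CrossedRandomInterceptLMM(BaseEstimator):
    """Gaussian LMM with two crossed random intercepts (sklearn-style).

    ``fit(X, y, group1=, group2=)`` takes a fixed-effects design (DataFrame;
    an intercept is added) and two grouping label arrays. ``reml=False``
    (maximum likelihood) by default so that log-likelihoods are comparable
    across fixed-effect structures. With ``force_zero_variance=True`` both
    variance components are pinned at zero and the fit is exactly OLS.
    """

    def __init__(self, reml: bool = False, force_zero_variance: bool = False):
        self.reml = reml
        self.force_zero_variance = force_zero_variance

    def fit(self, X: pd.DataFrame, y, *, group1, group2
            ) -> "CrossedRandomInterceptLMM":
        y = np.asarray(y, float)
        X = pd.DataFrame(X).reset_index(drop=True)
        g1 = np.asarray(group1).astype(str)
        g2 = np.asarray(group2).astype(str)
        if not (len(X) == len(y) == len(g1) == len(g2)):
            raise ConfigError("X, y and groups must have equal lengths")
        for name, g in (("group1", g1), ("group2", g2)):
            if len(np.unique(g)) < 2:
                raise DataError(f"{name} needs >= 2 levels")

        design = sm.add_constant(X, has_constant="add")
        names = list(design.columns)

        if self.force_zero_variance:
            res = sm.OLS(y, design).fit()
            self.result_ = res
            self.fit_ = DurationFit(
                coefficients=dict(zip(names, map(float, res.params))),
                std_errors=dict(zip(names, map(float, res.bse))),
                t_values=dict(zip(names, map(float, res.tvalues))),
                variance_components={"group1": 0.0, "group2": 0.0,
                                     "residual": float(res.scale)},
                log_likelihood=float(res.llf), n_obs=len(y), method="OLS",
            )
            return self

        df = design.copy()
        df["_y"] = y
        df["_g1"] = g1
        df["_g2"] = g2
        df["_all"] = 1
        vc = {"group1": "0 + C(_g1)", "group2": "0 + C(_g2)"}
        model = sm.MixedLM.from_formula(
            "_y ~ 0 + " + " + ".join(f"Q('{c}')" for c in names),
            groups="_all", vc_formula=vc, data=df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=self.reml, method="lbfgs", maxiter=200)
            if not res.converged:
                res = model.fit(reml=self.reml, method="powell", maxiter=500)
        params = {n: float(res.fe_params.iloc[i]) for i, n in enumerate(names)}
        bse = {n: float(res.bse_fe.iloc[i]) for i, n in enumerate(names)}
        tvals = {n: (params[n] / bse[n] if bse[n] > 0 else np.nan)
                 for n in names}
        vcomp = {"group1": float(res.vcomp[0]), "group2": float(res.vcomp[1]),
                 "residual": float(res.scale)}
        self.result_ = res
        self.fit_ = DurationFit(
            coefficients=params, std_errors=bse, t_values=tvals,
            variance_components=vcomp, log_likelihood=float(res.llf),
            n_obs=len(y), method="REML" if self.reml else "ML",
        )
        return self


def fit_random_intercept_lmm(y, fixed: pd.DataFrame, group1, group2,
                             reml: bool = False,
                             force_zero_variance: bool = False) -> DurationFit:
    """Spec-level wrapper; see :class:`CrossedRandomInterceptLMM`."""
    est = CrossedRandomInterceptLMM(reml=reml,
                                    force_zero_variance=force_zero_variance)
    return est.fit(fixed, y, group1=group1, group2=group2).fit_


def rank_correlation(x: Sequence[float], y: Sequence[float]
                     ) -> Tuple[float, float]:
    """(Spearman rho with midrank ties, Pearson r)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero variance input to correlation")
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    return rho, r


def duration_analysis(token_table: pd.DataFrame,
                      activation_column: str) -> dict:
    """The token-level duration analysis for one activation measure.

    ``token_table`` needs one row per schwa token with columns
    vowel_duration_s, speaking_rate, n_segments, speaker, form and the
    activation column. Returns the LMM fit plus rank correlations of raw
    duration with activation.
    """
    needed = {"vowel_duration_s", "speaking_rate", "n_segments",
              "speaker", "form", activation_column}
    missing = needed - set(token_table.columns)
    if missing:
        raise ConfigError(f"token table lacks columns {sorted(missing)}")
    y = np.log(token_table["vowel_duration_s"].astype(float).to_numpy())
    fixed = token_table[[activation_column, "speaking_rate", "n_segments"]].astype(float)
    fit = fit_random_intercept_lmm(y, fixed,
                                   group1=token_table["speaker"],
                                   group2=token_table["form"])
    rho, r = rank_correlation(token_table[activation_column],
                              token_table["vowel_duration_s"])
    return {
        "lmm": dataclasses.asdict(fit),
        "spearman_rho": rho,
        "pearson_r": r,
        "activation": activation_column,
    }
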