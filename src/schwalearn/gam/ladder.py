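"""The bottom-up model-comparison ladder for activation predictors.

Baseline m0 models formant trajectories with a dimension-by-class factor, a
time x log-duration tensor smooth per dbc level, and per-speaker grouped
factor smooths of time (separately per dimension). Models m1-m4 add the
activation predictor with increasing structure:

* m1: + s(activation) by dimension
* m2: + s(activation) by dbc
* m3: m2 + ti(time, activation) by dimension
* m4: m2 + ti(time, activation) by dbc

Each model is scored by negative log marginal likelihood; the ladder reports
delta ML = ml(m0) - ml(mk), so positive values mean the activation model
fits better than the baseline. Later models warm-start their smoothing
parameter search at the previous optimum.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .design import SmoothTerm
from .model import ModelSpec, PenalizedSplineGAM, fit_model

LADDER_MODELS = ("m0", "m1", "m2", "m3", "m4")


def baseline_terms(te_k: Tuple[int, int] = (4, 4), fs_k: int = 5):
    return [
        SmoothTerm("tensor", ("time", "log_duration"), by="dbc", k=te_k),
        SmoothTerm("group_smooth", ("time",), group="speaker",
                   by="dimension", k=(fs_k,), penalty_order=1),
    ]


def _activation_terms(model: str, activation_column: str,
                      act_k: int, ti_k: Tuple[int, int]):
    s_dim = SmoothTerm("univariate", (activation_column,), by="dimension",
                       k=(act_k,))
    s_dbc = SmoothTerm("univariate", (activation_column,), by="dbc",
                       k=(act_k,))
    ti_dim = SmoothTerm("partial_tensor", ("time", activation_column),
                        by="dimension", k=ti_k)
    ti_dbc = SmoothTerm("partial_tensor", ("time", activation_column),
                        by="dbc", k=ti_k)
    return {
        "m1": [s_dim],
        "m2": [s_dbc],
        "m3": [s_dbc, ti_dim],
        "m4": [s_dbc, ti_dbc],
    }[model]


def ml_ladder(table: pd.DataFrame, activation_column: str,
              response: str = "response", ar1_rho: float = 0.8,
              te_k: Tuple[int, int] = (4, 4), act_k: int = 6,
              ti_k: Tuple[int, int] = (4, 4), fs_k: int = 5,
              models: Sequence[str] = LADDER_MODELS,
              m0_fit: Optional[PenalizedSplineGAM] = None,
              n_restarts: int = 1, random_state: int = 0,
              collapse_check: bool = False
              ) -> Tuple[Dict, Dict[str, PenalizedSplineGAM]]:
    """Fit the ladder; returns (report, fits).

    The report maps each model name to ml_score, total and per-term edf and,
    for m1-m4, delta_ml = ml(m0) - ml(mk) and delta_edf (positive delta_ml
    means the activation model fits better). ``m0_fit`` lets callers share
    one baseline fit across several activation columns.
    """
    if activation_column not in table.columns:
        raise ConfigError(f"activation column {activation_column!r} missing")
    base = baseline_terms(te_k, fs_k)

    def spec_for(terms):
        return ModelSpec(response=response, terms=terms, factors=("dbc",),
                         ar1_rho=ar1_rho)

    fits: Dict[str, PenalizedSplineGAM] = {}
    if m0_fit is None:
        m0_fit = fit_model(table, spec_for(base), n_restarts=n_restarts,
                           random_state=random_state)
    fits["m0"] = m0_fit
    base_loglam = m0_fit.loglam_

    report: Dict[str, Dict] = {
        "m0": {"ml_score": float(m0_fit.ml_score_),
               "edf_total": m0_fit.edf_total_,
               "edf_by_term": dict(m0_fit.edf_)},
    }
    for name in models:
        if name == "m0":
            continue
        extra = _activation_terms(name, activation_column, act_k, ti_k)
        terms = base + extra
        n_new = sum(2 if t.kind in ("tensor", "partial_tensor", "group_smooth")
                    else 1 for t in extra)
        init = np.concatenate([base_loglam, np.zeros(n_new)])
        fit = fit_model(table, spec_for(terms), n_restarts=n_restarts,
                        random_state=random_state, init_loglam=init)
        fits[name] = fit
        report[name] = {
            "ml_score": float(fit.ml_score_),
            "edf_total": fit.edf_total_,
            "edf_by_term": dict(fit.edf_),
            "delta_ml": float(m0_fit.ml_score_ - fit.ml_score_),
            "delta_edf": float(fit.edf_total_ - m0_fit.edf_total_),
        }

    if collapse_check:
        report["collapse"] = _collapse_check(table, response, ar1_rho, te_k,
                                             fs_k, m0_fit, n_restarts,
                                             random_state)
    return report, fits


def _collapse_check(table, response, ar1_rho, te_k, fs_k, m0_fit,
                    n_restarts, random_state) -> Dict[str, float]:
    """Refit the baseline with two word-class levels merged; reports
    ml(collapsed) - ml(m0) per merge (positive: the 3-class model is
    better)."""
    classes = sorted(table["word_class"].unique())
    out = {}
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            merged = table.copy()
            merged["word_class"] = merged["word_class"].replace({b: a})
            merged["dbc"] = merged["dimension"] + "." + merged["word_class"]
            fit = fit_model(
                merged,
                ModelSpec(response=response, terms=baseline_terms(te_k, fs_k),
                          factors=("dbc",), ar1_rho=ar1_rho),
                n_restarts=n_restarts, random_state=random_state)
            out[f"{a}+{b}"] = float(fit.ml_score_ - m0_fit.ml_score_)
    return out
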