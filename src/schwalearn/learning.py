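"""Rescorla-Wagner delta-rule learning over event streams.

The learner maintains a cue x outcome weight matrix. For every event, the
prediction for each outcome o is V(o) = sum of the weights from the event's
present cues (summed in lexicographic cue order, before any update of the
event). Present outcomes are pushed toward the asymptote ``lambda_max`` at
rate ``eta_present``; absent outcomes decay toward 0 at rate ``eta_absent``;
absent cues are untouched. A closed-form equilibrium (the least-squares
fixed point of the expected update, solving the cue co-occurrence normal
equations) is provided as an analytic oracle.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, NumericError
from .events import (GESTURE_OUTCOME, LearningEvent, NetworkSpec,
                     stream_events)


@dataclass
class LearningParams:
    lambda_max: float = 1.0
    eta_present: float = 0.01
    eta_absent: float = 0.01
    outcome_universe: str = "declared"  # or "seen_so_far"
    n_passes: int = 1

    def validate(self) -> "LearningParams":
        if not self.lambda_max > 0:
            raise ConfigError(f"lambda_max must be > 0, got {self.lambda_max!r}")
        for name in ("eta_present", "eta_absent"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v!r}")
        if self.outcome_universe not in ("declared", "seen_so_far"):
            raise ConfigError(
                f"outcome_universe must be 'declared' or 'seen_so_far', "
                f"got {self.outcome_universe!r}")
        return self


class WeightMatrix:
    """Dense cue x outcome weight store with label registries.

    Unknown (cue, outcome) pairs read as 0. Registries keep labels in sorted
    (lexicographic) order so that summation order is reproducible.
    """

    def __init__(self, cues: Sequence[str] = (), outcomes: Sequence[str] = ()):
        self.cues: List[str] = sorted(set(cues))
        self.outcomes: List[str] = sorted(set(outcomes))
        self.cue_index: Dict[str, int] = {c: i for i, c in enumerate(self.cues)}
        self.outcome_index: Dict[str, int] = {o: i for i, o in enumerate(self.outcomes)}
        self.W = np.zeros((len(self.cues), len(self.outcomes)))

    def get(self, cue: str, outcome: str) -> float:
        i = self.cue_index.get(cue)
        j = self.outcome_index.get(outcome)
        if i is None or j is None:
            return 0.0
        return float(self.W[i, j])

    def set(self, cue: str, outcome: str, value: float) -> None:
        self.ensure_labels([cue], [outcome])
        self.W[self.cue_index[cue], self.outcome_index[outcome]] = value

    def ensure_labels(self, cues: Iterable[str], outcomes: Iterable[str]) -> None:
        new_c = sorted(set(cues) - set(self.cue_index))
        new_o = sorted(set(outcomes) - set(self.outcome_index))
        if not new_c and not new_o:
            return
        old = self
        merged = WeightMatrix(self.cues + new_c, self.outcomes + new_o)
        for ci, c in enumerate(old.cues):
            for oi, o in enumerate(old.outcomes):
                merged.W[merged.cue_index[c], merged.outcome_index[o]] = old.W[ci, oi]
        self.cues, self.outcomes = merged.cues, merged.outcomes
        self.cue_index, self.outcome_index = merged.cue_index, merged.outcome_index
        self.W = merged.W

    def cue_rows(self, cue_set: Iterable[str]) -> np.ndarray:
        """Row indices of known cues, ordered lexicographically by label."""
        return np.array([self.cue_index[c] for c in sorted(cue_set)
                         if c in self.cue_index], dtype=np.intp)

    def activation(self, cue_set: Iterable[str], outcome_set: Iterable[str]) -> float:
        """Sum of weights from the cue set to the outcome set.

        Unknown labels contribute 0; summation runs in lexicographic label
        order (outer loop over outcomes is irrelevant to the total since each
        outcome column is reduced in row order)."""
        rows = self.cue_rows(cue_set)
        cols = np.array([self.outcome_index[o] for o in sorted(outcome_set)
                         if o in self.outcome_index], dtype=np.intp)
        if rows.size == 0 or cols.size == 0:
            return 0.0
        sub = self.W[np.ix_(rows, cols)]
        per_outcome = np.add.reduce(sub, axis=0)
        return float(np.add.reduce(per_outcome))

    # --- serialization: sparse triplet TSV with a JSON header line ---------

    def to_tsv(self, path, params: LearningParams | None = None) -> None:
        header = {
            "n_cues": len(self.cues), "n_outcomes": len(self.outcomes),
            "cues": self.cues, "outcomes": self.outcomes,
        }
        if params is not None:
            header["params"] = {
                "lambda_max": params.lambda_max,
                "eta_present": params.eta_present,
                "eta_absent": params.eta_absent,
                "outcome_universe": params.outcome_universe,
                "n_passes": params.n_passes,
            }
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
            fh.write("cue\toutcome\tweight\n")
            nz = np.argwhere(self.W != 0.0)
            for i, j in nz:
                fh.write(f"{self.cues[i]}\t{self.outcomes[j]}\t"
                         f"{float(self.W[i, j])!r}\n")

    @classmethod
    def from_tsv(cls, path) -> Tuple["WeightMatrix", dict]:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise NumericError("missing JSON header in weight TSV")
            header = json.loads(first[2:])
            body = fh.read()
        wm = cls(header["cues"], header["outcomes"])
        # weights kept as strings so Python's exact repr round-trip applies
        df = pd.read_csv(io.StringIO(body), sep="\t",
                         dtype={"cue": str, "outcome": str, "weight": str})
        for _, r in df.iterrows():
            wm.W[wm.cue_index[r["cue"]], wm.outcome_index[r["outcome"]]] = float(r["weight"])
        return wm, header


class RescorlaWagnerLearner(BaseEstimator):
    """Delta-rule learner over an ordered event stream (sklearn-style).

    Parameters mirror :class:`LearningParams`. ``fit`` performs
    ``n_passes`` deterministic passes in event order and exposes the trained
    weights as ``weights_``.
    """

    def __init__(self, lambda_max: float = 1.0, eta_present: float = 0.01,
                 eta_absent: float = 0.01, outcome_universe: str = "declared",
                 n_passes: int = 1):
        self.lambda_max = lambda_max
        self.eta_present = eta_present
        self.eta_absent = eta_absent
        self.outcome_universe = outcome_universe
        self.n_passes = n_passes

    def _params(self) -> LearningParams:
        return LearningParams(self.lambda_max, self.eta_present,
                              self.eta_absent, self.outcome_universe,
                              self.n_passes).validate()

    def fit(self, X: Sequence[LearningEvent], y=None) -> "RescorlaWagnerLearner":
        params = self._params()
        events = list(X)
        cues = set()
        outcomes = set()
        for ev in events:
            if not ev.cues or not ev.outcomes:
                raise ConfigError("events must have nonempty cues and outcomes")
            cues |= ev.cues
            outcomes |= ev.outcomes
        wm = WeightMatrix(cues, outcomes)
        seen = np.zeros(len(wm.outcomes), dtype=bool)
        incremental = params.outcome_universe == "seen_so_far"
        lam, eta_p, eta_a = params.lambda_max, params.eta_present, params.eta_absent
        W = wm.W
        for _ in range(params.n_passes):
            for k, ev in enumerate(events):
                rows = wm.cue_rows(ev.cues)
                present = np.zeros(len(wm.outcomes), dtype=bool)
                for o in ev.outcomes:
                    present[wm.outcome_index[o]] = True
                if incremental:
                    seen |= present
                # V(o): lexicographic, pre-update sum over present cues
                V = np.add.reduce(W[rows], axis=0)
                delta = np.where(present, eta_p * (lam - V), eta_a * (0.0 - V))
                if incremental:
                    delta = np.where(seen, delta, 0.0)
                if not np.all(np.isfinite(delta)):
                    raise NumericError(f"non-finite weight update at event {k}")
                W[rows] += delta
        self.weights_ = wm
        self.n_events_ = len(events)
        return self

    def transform(self, windows: Sequence[Tuple[Iterable[str], Iterable[str]]]) -> np.ndarray:
        """Total activation for each (cue_set, outcome_set) pair."""
        wm = self.weights_
        return np.array([wm.activation(c, o) for c, o in windows])


# ---------------------------------------------------------------------------
# spec-level operation wrappers


def apply_update(weights: WeightMatrix, event: LearningEvent,
                 params: LearningParams) -> WeightMatrix:
    """Apply one delta-rule update in place (registering new labels).

    The outcome universe for absent-outcome updates is the weight matrix's
    registered outcome set plus the event's own outcomes.
    """
    params.validate()
    if not event.cues or not event.outcomes:
        raise ConfigError("event must have nonempty cues and outcomes")
    weights.ensure_labels(event.cues, event.outcomes)
    rows = weights.cue_rows(event.cues)
    present = np.zeros(len(weights.outcomes), dtype=bool)
    for o in event.outcomes:
        present[weights.outcome_index[o]] = True
    V = np.add.reduce(weights.W[rows], axis=0)
    delta = np.where(present,
                     params.eta_present * (params.lambda_max - V),
                     params.eta_absent * (0.0 - V))
    if not np.all(np.isfinite(delta)):
        raise NumericError("non-finite weight update")
    weights.W[rows] += delta
    return weights


def train(events: Sequence[LearningEvent],
          params: LearningParams | None = None) -> WeightMatrix:
    """Single-pass (by default) delta-rule training; see the learner class."""
    params = (params or LearningParams()).validate()
    events = list(events)
    if not events:
        return WeightMatrix()
    learner = RescorlaWagnerLearner(
        params.lambda_max, params.eta_present, params.eta_absent,
        params.outcome_universe, params.n_passes)
    return learner.fit(events).weights_


def total_activation(weights: WeightMatrix, cue_set: Iterable[str],
                     outcome_set: Iterable[str]) -> float:
    return weights.activation(cue_set, outcome_set)


def danks_equilibrium(events: Sequence[LearningEvent],
                      lambda_max: float = 1.0) -> WeightMatrix:
    """Closed-form expected fixed point of the delta rule.

    For each outcome o, solves the normal equations C w = lambda_max * b,
    where C is the cue co-occurrence frequency matrix over the event multiset
    and b the cue-with-outcome frequency vector (least-squares pseudo-inverse
    for singular C). Matches the trained weights in expectation when
    eta_present == eta_absent and the event distribution is stationary.
    """
    events = list(events)
    wm = WeightMatrix(
        {c for ev in events for c in ev.cues},
        {o for ev in events for o in ev.outcomes},
    )
    n_c, n_o = len(wm.cues), len(wm.outcomes)
    if n_c == 0:
        return wm
    C = np.zeros((n_c, n_c))
    B = np.zeros((n_c, n_o))
    for ev in events:
        rows = wm.cue_rows(ev.cues)
        C[np.ix_(rows, rows)] += 1.0
        for o in ev.outcomes:
            B[rows, wm.outcome_index[o]] += 1.0
    n = float(len(events))
    sol, *_ = np.linalg.lstsq(C / n, lambda_max * B / n, rcond=None)
    wm.W = sol
    return wm


def activations_for_corpus(weights: WeightMatrix, corpus,
                           spec: NetworkSpec) -> pd.DataFrame:
    """Window activation for every schwa-final token.

    For the functional_output structure the outcome set is the token's own
    function labels; for functional_input it is the gesture outcome only.
    Returns a table (token_id, network, activation).
    """
    spec.validate()
    rows = []
    token_by_id = {t.token_id: t for t in corpus}
    for ev in stream_events(corpus, spec):
        tok = token_by_id[ev.center_token_id]
        if not tok.entry.schwa_final:
            continue
        if spec.structure == "functional_output":
            outcome_set = {f"fn:{f}" for f in tok.entry.functions}
        else:
            outcome_set = {GESTURE_OUTCOME}
        rows.append((tok.token_id, spec.structure,
                     weights.activation(ev.cues, outcome_set)))
    return pd.DataFrame(rows, columns=["token_id", "network", "activation"])
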