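"""Exclusion and normalization rules for raw formant tracks.

Filtering precedence: (1) tokens shorter than ``min_duration`` are dropped;
(2) individual samples with F1 or F2 outside the plausible ranges are
dropped; (3) tokens left with fewer than ``min_samples_per_token`` samples
are dropped (attributed to the range rule when range violations caused the
shortfall, otherwise to the sample-count rule).

Normalization: F1 is negated (so that higher tongue positions map to higher
values), then each of (-F1, F2) is centred and scaled to unit SD within
speaker and dimension (population SD); per-token time is mapped affinely to
[0, 1]; duration enters downstream models on a natural-log scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, JoinError


@dataclass
class FilterThresholds:
    min_duration: float = 0.018  # seconds
    f1_range: Tuple[float, float] = (250.0, 1000.0)  # Hz
    f2_range: Tuple[float, float] = (1000.0, 2000.0)  # Hz
    min_samples_per_token: int = 3

    def validate(self) -> "FilterThresholds":
        if not self.min_duration > 0:
            raise ConfigError(f"min_duration must be > 0, got {self.min_duration!r}")
        for name in ("f1_range", "f2_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be ordered, got {(lo, hi)!r}")
        if self.min_samples_per_token < 1:
            raise ConfigError("min_samples_per_token must be >= 1")
        return self


@dataclass
class FilterReport:
    n_tokens_in: int = 0
    n_tokens_kept: int = 0
    tokens_dropped_duration: int = 0
    tokens_dropped_range: int = 0
    tokens_dropped_min_samples: int = 0
    samples_dropped_range: int = 0

    @property
    def counts(self) -> dict:
        return {
            "duration": self.tokens_dropped_duration,
            "range": self.tokens_dropped_range,
            "min_samples": self.tokens_dropped_min_samples,
        }

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def filter_tracks(tracks: pd.DataFrame, durations: pd.Series | dict,
                  thresholds: FilterThresholds | None = None
                  ) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion rules; returns (kept samples, report).

    ``tracks`` is a long table (token_id, speaker, t_s, F1_Hz, F2_Hz);
    ``durations`` maps token_id to vowel duration in seconds.
    """
    thresholds = (thresholds or FilterThresholds()).validate()
    durations = pd.Series(durations)
    if (durations < 0).any():
        bad = durations.index[durations < 0].tolist()
        raise DataError(f"negative vowel duration for tokens {bad[:5]}")

    tokens_in = tracks["token_id"].unique()
    report = FilterReport(n_tokens_in=len(tokens_in))

    dur = tracks["token_id"].map(durations)
    if dur.isna().any():
        missing = sorted(tracks.loc[dur.isna(), "token_id"].unique())
        raise JoinError(f"tracks without a duration: {missing[:5]}")

    short = dur < thresholds.min_duration
    short_tokens = set(tracks.loc[short, "token_id"])
    report.tokens_dropped_duration = len(short_tokens)
    kept = tracks.loc[~tracks["token_id"].isin(short_tokens)].copy()

    in_range = (kept["F1_Hz"].between(*thresholds.f1_range)
                & kept["F2_Hz"].between(*thresholds.f2_range))
    report.samples_dropped_range = int((~in_range).sum())
    lost_samples = set(kept.loc[~in_range, "token_id"])
    kept = kept.loc[in_range]

    sizes = kept.groupby("token_id").size()
    too_few = set(sizes.index[sizes < thresholds.min_samples_per_token])
    # tokens whose every sample was out of range vanish from `sizes`
    vanished = (set(tracks.loc[~tracks["token_id"].isin(short_tokens), "token_id"])
                - set(sizes.index))
    too_few |= vanished
    report.tokens_dropped_range = len(too_few & lost_samples)
    report.tokens_dropped_min_samples = len(too_few - lost_samples)
    kept = kept.loc[~kept["token_id"].isin(too_few)].reset_index(drop=True)
    report.n_tokens_kept = kept["token_id"].nunique()
    return kept, report


def normalize_tracks(tracks: pd.DataFrame,
                     token_info: pd.DataFrame) -> pd.DataFrame:
    """Per-speaker z-scoring and per-token time normalization.

    ``token_info`` must carry token_id, word_class and vowel_duration_s.
    Returns one row per sample with columns token_id, speaker, word_class,
    time (in [0, 1]), f1_z (z-score of -F1), f2_z, log_duration.
    """
    df = tracks.copy()
    info = token_info.set_index("token_id")
    missing = set(df["token_id"]) - set(info.index)
    if missing:
        raise JoinError(f"tokens missing from token_info: {sorted(missing)[:5]}")

    df["neg_f1"] = -df["F1_Hz"]
    out = []
    for (spk,), grp in df.groupby(["speaker"], sort=True):
        for col in ("neg_f1", "F2_Hz"):
            vals = grp[col].to_numpy(float)
            if len(vals) < 2:
                raise DataError(f"speaker {spk}: fewer than 2 samples")
            sd = vals.std()
            if sd == 0:
                raise DataError(f"speaker {spk}: zero variance in {col}")
        g = grp.copy()
        g["f1_z"] = (g["neg_f1"] - g["neg_f1"].mean()) / g["neg_f1"].std(ddof=0)
        g["f2_z"] = (g["F2_Hz"] - g["F2_Hz"].mean()) / g["F2_Hz"].std(ddof=0)
        out.append(g)
    df = pd.concat(out).sort_index()

    t0 = df.groupby("token_id")["t_s"].transform("min")
    t1 = df.groupby("token_id")["t_s"].transform("max")
    span = t1 - t0
    if (span <= 0).any():
        bad = sorted(df.loc[span <= 0, "token_id"].unique())
        raise DataError(f"tokens with zero time span: {bad[:5]}")
    df["time"] = (df["t_s"] - t0) / span

    df["word_class"] = df["token_id"].map(info["word_class"])
    df["log_duration"] = np.log(df["token_id"].map(info["vowel_duration_s"]).astype(float))
    cols = ["token_id", "speaker", "word_class", "time", "f1_z", "f2_z",
            "log_duration"]
    return df[cols].reset_index(drop=True)


def assemble_model_table(prepped: pd.DataFrame,
                         activations: pd.DataFrame,
                         extra_token_columns: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Long modelling table: one row per (token, time sample, dimension).

    ``activations`` is a long table (token_id, network, activation); each
    network becomes one predictor column. The dimension-by-class factor
    ``dbc`` crosses F1/F2 with the three word classes (six levels). The
    response column holds the speaker-normalized formant value of that row's
    dimension.
    """
    act_wide = activations.pivot_table(index="token_id", columns="network",
                                       values="activation", aggfunc="first")
    missing = sorted(set(prepped["token_id"]) - set(act_wide.index))
    if missing:
        raise JoinError(f"tokens without activation records: {missing[:10]}")

    frames = []
    for dim, col in (("F1", "f1_z"), ("F2", "f2_z")):
        part = prepped.drop(columns=["f1_z", "f2_z"]).copy()
        part["dimension"] = dim
        part["response"] = prepped[col]
        frames.append(part)
    table = pd.concat(frames, ignore_index=True)
    table["dbc"] = table["dimension"] + "." + table["word_class"]
    for net in act_wide.columns:
        table[net] = table["token_id"].map(act_wide[net])
    if extra_token_columns is not None:
        extra = extra_token_columns.set_index("token_id")
        for col in extra.columns:
            table[col] = table["token_id"].map(extra[col])
    table = table.sort_values(["token_id", "dimension", "time"],
                              kind="mergesort").reset_index(drop=True)
    return table
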