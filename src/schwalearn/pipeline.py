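"""End-to-end experiment orchestration.

simulate -> events -> train both networks (+ ablation) -> activations ->
formant prep -> model ladder per activation -> duration models ->
network-comparison summary. Every stage seed derives deterministically from
the master seed, artifacts are written in documented text formats, and a
MANIFEST records content hashes so any report number can be traced to its
inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import formants, synthetic
from .duration import duration_analysis
from .errors import ConfigError, SchwalearnError
from .events import NetworkSpec, stream_events
from .gam import ml_ladder, predict_percentile_trajectories
from .learning import (LearningParams, WeightMatrix, activations_for_corpus,
                       train)

ABLATION_COLUMN = "functional_input_ablation"


@dataclass
class LadderSettings:
    ar1_rho: float = 0.8
    te_k: tuple = (4, 4)
    act_k: int = 6
    ti_k: tuple = (4, 4)
    fs_k: int = 5
    n_restarts: int = 1
    models: tuple = ("m0", "m1", "m2", "m3", "m4")
    collapse_check: bool = False


@dataclass
class ExperimentConfig:
    language: synthetic.LanguageConfig = field(
        default_factory=synthetic.LanguageConfig)
    learning: LearningParams = field(default_factory=LearningParams)
    thresholds: formants.FilterThresholds = field(
        default_factory=formants.FilterThresholds)
    ladder: LadderSettings = field(default_factory=LadderSettings)
    truth_overrides: Dict[str, float] = field(default_factory=dict)
    window_size: int = 5
    networks: tuple = ("functional_output", "functional_input")
    run_ablation: bool = True
    run_duration_model: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("master seed must be set")
        # stage seeds derive from the master seed; the language config's own
        # seed is overridden for reproducibility from a single number
        ss = np.random.SeedSequence(self.seed)
        self._stage_seeds = [int(s) % (2 ** 31) for s in ss.generate_state(4)]
        self.language = dataclasses.replace(
            self.language, seed=self._stage_seeds[0])
        self.language.validate()
        self.learning.validate()
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "language" in raw:
            kwargs["language"] = synthetic.LanguageConfig(**raw["language"])
        if "learning" in raw:
            kwargs["learning"] = LearningParams(**raw["learning"])
        if "thresholds" in raw:
            th = dict(raw["thresholds"])
            for k in ("f1_range", "f2_range"):
                if k in th:
                    th[k] = tuple(th[k])
            kwargs["thresholds"] = formants.FilterThresholds(**th)
        if "ladder" in raw:
            ld = dict(raw["ladder"])
            for k in ("te_k", "ti_k", "models"):
                if k in ld:
                    ld[k] = tuple(ld[k])
            kwargs["ladder"] = LadderSettings(**ld)
        for k in ("truth_overrides", "window_size", "run_ablation",
                  "run_duration_model", "seed"):
            if k in raw:
                kwargs[k] = raw[k]
        if "networks" in raw:
            kwargs["networks"] = tuple(raw["networks"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = {
            "language": dataclasses.asdict(self.language),
            "learning": dataclasses.asdict(self.learning),
            "thresholds": dataclasses.asdict(self.thresholds),
            "ladder": dataclasses.asdict(self.ladder),
            "truth_overrides": dict(self.truth_overrides),
            "window_size": self.window_size,
            "networks": list(self.networks),
            "run_ablation": self.run_ablation,
            "run_duration_model": self.run_duration_model,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _network_specs(config: ExperimentConfig) -> Dict[str, NetworkSpec]:
    specs = {}
    for name in config.networks:
        specs[name] = NetworkSpec(name, window_size=config.window_size)
    if config.run_ablation:
        specs[ABLATION_COLUMN] = NetworkSpec(
            "functional_input", include_function_cues=False,
            window_size=config.window_size)
    return specs


def run_experiment(config: ExperimentConfig,
                   outdir: Optional[str] = None,
                   keep_internals: bool = False) -> dict:
    """Run the full experiment; returns the in-memory report bundle and, if
    ``outdir`` is given, writes all artifacts there.

    With ``keep_internals=True`` the bundle additionally carries the
    in-memory corpus, modelling table, fitted ladder models and the latent
    predictability axis under ``_internals`` (never serialized); recovery
    analyses use these to compare fitted effects against the generator's
    ground truth."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: List[dict] = []
    bundle: dict = {"config_seed": config.seed}

    def stage(name):
        log.append({"stage": name, "t": time.time()})

    try:
        stage("simulate")
        lexicon = synthetic.build_lexicon(config.language)
        corpus = synthetic.sample_corpus(lexicon, config.language)
        schwa = [t for t in corpus if t.entry.schwa_final]
        truth = synthetic.default_ground_truth(config.language,
                                               **config.truth_overrides)
        tracks = synthetic.generate_formant_tracks(schwa, truth,
                                                   config.language)
        bundle["n_tokens"] = len(corpus)
        bundle["n_schwa_tokens"] = len(schwa)

        stage("train")
        specs = _network_specs(config)
        weights: Dict[str, WeightMatrix] = {}
        activation_frames = []
        for colname, spec in specs.items():
            events = list(stream_events(corpus, spec))
            wm = train(events, config.learning)
            weights[colname] = wm
            acts = activations_for_corpus(wm, corpus, spec)
            acts["network"] = colname  # disambiguate the ablation run
            activation_frames.append(acts)
        activations = pd.concat(activation_frames, ignore_index=True)

        stage("prep")
        durations = {t.token_id: t.vowel_duration for t in schwa}
        kept, filter_report = formants.filter_tracks(tracks, durations,
                                                     config.thresholds)
        corpus_frame = synthetic.corpus_to_frame(schwa)
        info = corpus_frame[["token_id", "word_class", "vowel_duration_s"]].copy()
        info["vowel_duration_s"] = info["vowel_duration_s"].astype(float)
        prepped = formants.normalize_tracks(kept, info)
        table = formants.assemble_model_table(prepped, activations)
        bundle["filter_report"] = dataclasses.asdict(filter_report)

        stage("ladder")
        ladders = {}
        all_fits = {}
        ls = config.ladder
        m0_fit = None
        for colname in specs:
            report, fits = ml_ladder(
                table, colname, ar1_rho=ls.ar1_rho, te_k=ls.te_k,
                act_k=ls.act_k, ti_k=ls.ti_k, fs_k=ls.fs_k,
                models=ls.models, m0_fit=m0_fit,
                n_restarts=ls.n_restarts,
                random_state=config._stage_seeds[2],
                collapse_check=ls.collapse_check and colname == "functional_input")
            m0_fit = fits["m0"]
            ladders[colname] = report
            all_fits[colname] = fits
        bundle["ladders"] = ladders
        if keep_internals:
            bundle["_internals"] = {
                "corpus": corpus,
                "truth": truth,
                "table": table,
                "fits": all_fits,
                "latent": synthetic.standardized_log_bundle_frequency(corpus),
            }

        stage("trajectories")
        traj_frames = []
        for colname, fits in all_fits.items():
            if "m2" not in fits:
                continue
            traj = predict_percentile_trajectories(fits["m2"], colname)
            traj["network"] = colname
            traj_frames.append(traj)
        trajectories = (pd.concat(traj_frames, ignore_index=True)
                        if traj_frames else pd.DataFrame())
        bundle["n_trajectory_rows"] = len(trajectories)

        if config.run_duration_model:
            stage("duration")
            act_wide = activations.pivot_table(
                index="token_id", columns="network", values="activation",
                aggfunc="first")
            token_table = corpus_frame.merge(
                act_wide.reset_index(), on="token_id", how="inner")
            token_table = token_table[
                token_table["token_id"].isin(prepped["token_id"])]
            bundle["duration"] = {
                col: duration_analysis(token_table, col) for col in specs
            }

        stage("compare")
        bundle["comparison"] = compare_networks(bundle)
    except SchwalearnError as exc:
        raise SchwalearnError(
            f"stage {log[-1]['stage']!r} failed: {exc}; "
            f"completed stages: {[e['stage'] for e in log[:-1]]}") from exc

    if out is not None:
        _write_bundle(out, config, corpus, tracks, truth, weights,
                      activations, filter_report, table, bundle, log,
                      trajectories)
    return bundle


def compare_networks(bundle: dict) -> pd.DataFrame:
    """Figure-style summary: delta ML per ladder model and network."""
    if "ladders" not in bundle or not bundle["ladders"]:
        raise ConfigError("bundle has no ladder reports")
    rows = []
    for network, report in bundle["ladders"].items():
        for model, entry in report.items():
            if model.startswith("m") and model != "m0":
                rows.append({"network": network, "model": model,
                             "delta_ml": entry["delta_ml"],
                             "delta_edf": entry["delta_edf"]})
    return pd.DataFrame(rows).sort_values(["model", "network"]).reset_index(drop=True)


def best_delta_ml(bundle: dict) -> Dict[str, float]:
    """Best (max over ladder models) delta ML per network."""
    comp = compare_networks(bundle)
    return comp.groupby("network")["delta_ml"].max().to_dict()


def _write_bundle(out: Path, config, corpus, tracks, truth, weights,
                  activations, filter_report, table, bundle, log,
                  trajectories=None) -> None:
    config.to_yaml(out / "config.yaml")
    synthetic.write_corpus(corpus, out / "corpus.tsv")
    synthetic.write_tracks(tracks, out / "tracks.csv")
    (out / "ground_truth.json").write_text(truth.to_json())
    for name, wm in weights.items():
        wm.to_tsv(out / f"weights_{name}.tsv", config.learning)
    activations.to_csv(out / "activations.csv", index=False,
                       float_format="%.10g")
    (out / "filter_report.json").write_text(filter_report.to_json())
    table.to_csv(out / "model_table.csv", index=False, float_format="%.10g")
    for network, report in bundle["ladders"].items():
        (out / f"ladder_{network}.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    if "duration" in bundle:
        (out / "duration_fits.json").write_text(
            json.dumps(bundle["duration"], indent=2, sort_keys=True))
    bundle["comparison"].to_csv(out / "comparison.csv", index=False,
                                float_format="%.10g")
    if trajectories is not None and len(trajectories):
        trajectories.to_csv(out / "percentile_trajectories.csv", index=False,
                            float_format="%.10g")
    with open(out / "log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps({"stage": entry["stage"]}) + "\n")
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name in ("MANIFEST.json", "log.jsonl"):
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
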