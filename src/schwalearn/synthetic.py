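"""Artificial-language corpus and formant-track generator.

The generator emulates the statistical structure of a spontaneous-speech
corpus in which a word-final central vowel (transcribed ``"5"``) discriminates
a large inventory of inflectional functions:

* Zipfian word-type frequencies over a lexicon of a few hundred types;
* schwa-final types carrying bundles of 1-3 inflectional-function labels
  (grammatical class x number x gender x case style) drawn from a fixed
  inventory (default 60 labels);
* three word classes for schwa-final types (content words, morphologically
  complex function words, morphologically simple function words);
* context words that are partially predictive of the following target's
  function bundle;
* per-token F1/F2 trajectories: class-specific quadratic (u-shaped) base
  curves, a duration-dependent height shift, a shift along a latent
  "predictability" axis (standardized log function-bundle frequency), fixed
  per-speaker offsets, and stationary AR1 measurement noise.

Ground-truth effect sizes are recorded so that downstream recovery tests can
ask whether network activations recover the latent axis without reading it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

#: phone inventory pool; "5" is reserved for the word-final schwa and "#"
#: for window boundaries, so neither may appear here.
PHONE_POOL = "abdefgiklmnoprstuvwyzhjx"
SCHWA = "5"

WORD_CLASSES = ("content", "complex_function", "simple_function")

_FUNCTION_FAMILIES = ("Wortart", "Numerus", "Genus", "Kasus")


@dataclass
class LanguageConfig:
    """Parameters of the artificial language.

    ``context_predictivity`` is the probability that the word immediately
    preceding a schwa-final target is replaced by a signal word that
    deterministically identifies the target's function bundle.
    ``class_mix`` gives the proportions of (content, complex_function,
    simple_function) among schwa-final types.
    """

    n_word_types: int = 250
    n_phones: int = 18
    n_functions: int = 60
    prop_schwa_final: float = 0.3
    zipf_exponent: float = 1.0
    n_speakers: int = 6
    n_tokens: int = 6000
    context_predictivity: float = 0.5
    class_mix: Tuple[float, float, float] = (0.48, 0.09, 0.43)
    mean_utterance_len: float = 8.0
    seed: int = 0

    def validate(self) -> "LanguageConfig":
        for name in ("n_word_types", "n_phones", "n_functions", "n_speakers",
                     "n_tokens"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a count >= 1, got {v!r}")
        for name in ("prop_schwa_final", "context_predictivity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if not self.zipf_exponent > 0:
            raise ConfigError(
                f"zipf_exponent must be > 0, got {self.zipf_exponent!r}")
        if len(self.class_mix) != 3 or any(not (0 <= c <= 1) for c in self.class_mix):
            raise ConfigError(f"class_mix must be three fractions, got {self.class_mix!r}")
        if abs(sum(self.class_mix) - 1.0) > 1e-12:
            raise ConfigError(
                f"class_mix must sum to 1 within 1e-12, got sum {sum(self.class_mix)!r}")
        if self.n_phones > len(PHONE_POOL):
            raise ConfigError(
                f"n_phones must be <= {len(PHONE_POOL)}, got {self.n_phones}")
        if self.seed is None:
            raise ConfigError("seed must be set")
        return self


@dataclass(frozen=True)
class LexiconEntry:
    form: str
    phones: Tuple[str, ...]
    word_class: str  # content | complex_function | simple_function | other
    functions: frozenset
    schwa_final: bool

    def __post_init__(self):
        if self.schwa_final and self.phones[-1] != SCHWA:
            raise ConfigError(f"schwa-final entry {self.form!r} must end in {SCHWA!r}")
        if self.schwa_final != bool(self.functions):
            raise ConfigError(
                f"entry {self.form!r}: functions nonempty iff schwa_final")


@dataclass
class CorpusToken:
    token_id: str
    utterance_id: int
    position: int
    speaker_id: str
    entry: LexiconEntry
    vowel_duration: float | None  # seconds; present iff schwa_final
    local_speaking_rate: float  # syllables / second
    n_segments: int


@dataclass
class FormantGroundTruth:
    """Generating effect sizes for the formant tracks.

    ``delta_uncertainty`` is the F1 shift in Hz per one standard deviation of
    the latent predictability axis (standardized log function-bundle
    frequency); F2 moves by ``f2_uncertainty_ratio`` times that amount.
    ``delta_duration`` is the F1 shift in Hz per unit of centred log duration.
    ``noise_sd`` is the stationary marginal SD of the AR1 noise, in Hz.
    """

    delta_uncertainty: float = 30.0
    delta_duration: float = 40.0
    speaker_offsets: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    ar1_coef: float = 0.8
    noise_sd: float = 25.0
    f2_uncertainty_ratio: float = -1.5

    def validate(self) -> "FormantGroundTruth":
        if not self.noise_sd > 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd!r}")
        if not abs(self.ar1_coef) < 1:
            raise ConfigError(f"|ar1_coef| must be < 1, got {self.ar1_coef!r}")
        return self

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["speaker_offsets"] = {k: list(v) for k, v in self.speaker_offsets.items()}
        return json.dumps(d, indent=2, sort_keys=True)


def _function_inventory(n_functions: int) -> List[List[str]]:
    """Split the inventory into four label families.

    Labels are split near-evenly across grammatical class, number, gender
    and case families; a bundle combines labels from 1-3 distinct families.
    """
    base, rem = divmod(n_functions, len(_FUNCTION_FAMILIES))
    sizes = [base + (1 if i < rem else 0)
             for i in range(len(_FUNCTION_FAMILIES))]
    return [
        [f"{fam}{i + 1}" for i in range(size)]
        for fam, size in zip(_FUNCTION_FAMILIES, sizes)
    ]


def build_lexicon(config: LanguageConfig) -> List[LexiconEntry]:
    """Generate the word-type inventory.

    Schwa-final types end in the schwa symbol and carry a bundle of 1-3
    function labels; bundles are drawn from a shared pool so that several
    types can realize the same paradigm cell. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    phones = list(PHONE_POOL[: config.n_phones])
    n_schwa = int(round(config.n_word_types * config.prop_schwa_final))

    families = _function_inventory(config.n_functions)
    nonempty = [f for f in families if f]
    # bundles are shared paradigm cells: many word types realize the same
    # function combination (roughly an order of magnitude more types than
    # bundles, as in large spontaneous-speech corpora)
    n_bundles = max(4, n_schwa // 8)
    bundles: List[frozenset] = []
    guard = 0
    while len(bundles) < n_bundles and guard < 200 * n_bundles:
        guard += 1
        k = int(rng.integers(1, min(3, len(nonempty)) + 1))
        fam_idx = rng.choice(len(nonempty), size=k, replace=False)
        bundle = frozenset(
            nonempty[i][int(rng.integers(len(nonempty[i])))]
            for i in sorted(fam_idx)
        )
        if bundle not in bundles:
            bundles.append(bundle)

    seen_forms = set()
    entries: List[LexiconEntry] = []

    def draw_form(schwa: bool) -> Tuple[str, Tuple[str, ...]]:
        for _ in range(10000):
            length = int(rng.integers(2, 6))
            seq = [phones[int(rng.integers(len(phones)))] for _ in range(length)]
            if schwa:
                seq.append(SCHWA)
            form = "".join(seq)
            if form not in seen_forms:
                seen_forms.add(form)
                return form, tuple(seq)
        raise ConfigError("n_word_types too large for the phone inventory")

    class_probs = np.asarray(config.class_mix, dtype=float)
    for i in range(config.n_word_types):
        schwa = i < n_schwa
        form, seq = draw_form(schwa)
        if schwa:
            wc = WORD_CLASSES[int(rng.choice(3, p=class_probs))]
            bundle = bundles[int(rng.integers(len(bundles)))]
            entries.append(LexiconEntry(form, seq, wc, bundle, True))
        else:
            entries.append(LexiconEntry(form, seq, "other", frozenset(), False))
    return entries


def sample_corpus(lexicon: Sequence[LexiconEntry],
                  config: LanguageConfig) -> List[CorpusToken]:
    """Draw a token stream of utterances from the lexicon.

    Type probabilities are Zipfian with exponent ``zipf_exponent`` over a
    seeded random rank assignment. Utterance lengths are geometric (mean
    ``mean_utterance_len``, min 1). With probability ``context_predictivity``
    the word preceding a schwa-final target is overwritten with the signal
    word of that target's function bundle.
    """
    config.validate()
    if not lexicon:
        raise ConfigError("lexicon must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    V = len(lexicon)
    ranks = rng.permutation(V) + 1
    probs = ranks.astype(float) ** (-config.zipf_exponent)
    probs /= probs.sum()

    # one dedicated non-schwa signal type per function bundle
    non_schwa_idx = [i for i, e in enumerate(lexicon) if not e.schwa_final]
    bundle_list = sorted(
        {e.functions for e in lexicon if e.schwa_final},
        key=lambda b: tuple(sorted(b)),
    )
    signal_for_bundle = {}
    if non_schwa_idx:
        for j, bundle in enumerate(bundle_list):
            signal_for_bundle[bundle] = non_schwa_idx[j % len(non_schwa_idx)]

    speakers = [f"spk{j:02d}" for j in range(config.n_speakers)]
    speaker_rate = {
        s: float(rng.normal(5.5, 0.5)) for s in speakers
    }

    tokens: List[CorpusToken] = []
    utt_id = 0
    while len(tokens) < config.n_tokens:
        length = int(rng.geometric(1.0 / config.mean_utterance_len))
        length = max(1, min(length, config.n_tokens - len(tokens)))
        speaker = speakers[int(rng.integers(len(speakers)))]
        idx = rng.choice(V, size=length, p=probs)
        # context predictivity: overwrite the pre-target slot
        for pos in range(1, length):
            ent = lexicon[int(idx[pos])]
            if ent.schwa_final and signal_for_bundle:
                if rng.random() < config.context_predictivity:
                    idx[pos - 1] = signal_for_bundle[ent.functions]
        for pos in range(length):
            ent = lexicon[int(idx[pos])]
            rate = max(2.0, speaker_rate[speaker] + float(rng.normal(0, 0.4)))
            dur = None
            if ent.schwa_final:
                dur = float(np.exp(rng.normal(math.log(0.055), 0.35))) * 5.5 / rate
            tokens.append(CorpusToken(
                token_id=f"t{len(tokens):06d}",
                utterance_id=utt_id,
                position=pos,
                speaker_id=speaker,
                entry=ent,
                vowel_duration=dur,
                local_speaking_rate=rate,
                n_segments=len(ent.phones),
            ))
        utt_id += 1
    return tokens


def standardized_log_bundle_frequency(tokens: Sequence[CorpusToken]) -> Dict[str, float]:
    """Latent predictability axis: z-scored log function-bundle frequency.

    Bundle frequencies are counted over the schwa-final tokens of the corpus;
    each schwa token is assigned the standardized (mean 0, SD 1, population
    SD) natural log of its bundle's count. This is the axis the generated
    trajectories are shifted along and that recovery tests condition on.
    """
    schwa = [t for t in tokens if t.entry.schwa_final]
    if not schwa:
        return {}
    counts: Dict[frozenset, int] = {}
    for t in schwa:
        counts[t.entry.functions] = counts.get(t.entry.functions, 0) + 1
    logf = np.array([math.log(counts[t.entry.functions]) for t in schwa])
    sd = logf.std()
    if sd == 0:
        z = np.zeros_like(logf)
    else:
        z = (logf - logf.mean()) / sd
    return {t.token_id: float(v) for t, v in zip(schwa, z)}


# class-specific quadratic base curves: value(t) = level + span * (1 - 4 (t - .5)^2)
# F1 peaks mid-vowel (tongue lowering), F2 dips mid-vowel (retraction); the
# complex-function class is fronted and wide, the simple-function class
# retracted and narrow, matching the qualitative class separation the
# analysis is meant to detect.
_BASE_CURVES = {
    "content": {"F1": (560.0, 140.0), "F2": (1520.0, -160.0)},
    "complex_function": {"F1": (540.0, 180.0), "F2": (1720.0, -140.0)},
    "simple_function": {"F1": (600.0, 90.0), "F2": (1300.0, -80.0)},
}
_REF_DURATION = 0.055  # seconds; centre of the log-duration shift


def default_ground_truth(config: LanguageConfig,
                         **overrides) -> FormantGroundTruth:
    """Ground truth with seeded per-speaker offsets (F1 sd 20 Hz, F2 sd 40 Hz)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    offsets = {
        f"spk{j:02d}": (float(rng.normal(0, 20.0)), float(rng.normal(0, 40.0)))
        for j in range(config.n_speakers)
    }
    truth = FormantGroundTruth(speaker_offsets=offsets, **overrides)
    return truth.validate()


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR1 series with marginal SD ``sd`` and lag-1 corr ``rho``."""
    innov_sd = sd * math.sqrt(1.0 - rho ** 2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + rng.normal(0.0, innov_sd)
    return e


def generate_formant_tracks(tokens: Sequence[CorpusToken],
                            truth: FormantGroundTruth,
                            config: LanguageConfig) -> pd.DataFrame:
    """Simulate F1/F2 tracks for schwa-final tokens.

    Returns a long table (token_id, speaker, t_s, F1_Hz, F2_Hz). The number
    of samples per token grows with duration (one per 8 ms, clipped to
    [3, 15]). Raises :class:`DomainError` for non-schwa input tokens.
    """
    truth.validate()
    z_axis = standardized_log_bundle_frequency(tokens)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    rows = []
    for tok in tokens:
        if not tok.entry.schwa_final or tok.vowel_duration is None:
            raise DomainError(
                f"token {tok.token_id} is not schwa-final with a duration")
        d = tok.vowel_duration
        if d <= 0:
            raise DomainError(f"token {tok.token_id} has non-positive duration")
        m = int(np.clip(round(d / 0.008), 3, 15))
        t = np.linspace(0.0, d, m)
        tn = t / d
        shape = 1.0 - 4.0 * (tn - 0.5) ** 2
        z = z_axis.get(tok.token_id, 0.0)
        dur_shift = truth.delta_duration * (math.log(d) - math.log(_REF_DURATION))
        off1, off2 = truth.speaker_offsets.get(tok.speaker_id, (0.0, 0.0))
        base = _BASE_CURVES[tok.entry.word_class]
        f1 = (base["F1"][0] + base["F1"][1] * shape
              + dur_shift + truth.delta_uncertainty * z + off1)
        f2 = (base["F2"][0] + base["F2"][1] * shape
              - dur_shift + truth.f2_uncertainty_ratio * truth.delta_uncertainty * z
              + off2)
        f1 = f1 + _ar1_noise(rng, m, truth.ar1_coef, truth.noise_sd)
        f2 = f2 + _ar1_noise(rng, m, truth.ar1_coef, truth.noise_sd)
        for j in range(m):
            rows.append((tok.token_id, tok.speaker_id, float(t[j]),
                         float(f1[j]), float(f2[j])))
    return pd.DataFrame(rows, columns=["token_id", "speaker", "t_s", "F1_Hz", "F2_Hz"])


# ---------------------------------------------------------------------------
# I/O: tab-separated corpus table, long-format track CSV, ground-truth JSON

CORPUS_COLUMNS = ["utterance_id", "position", "speaker", "form", "phones",
                  "word_class", "functions", "schwa_final",
                  "vowel_duration_s", "speaking_rate", "n_segments"]


def corpus_to_frame(tokens: Sequence[CorpusToken]) -> pd.DataFrame:
    rows = []
    for t in tokens:
        rows.append({
            "token_id": t.token_id,
            "utterance_id": t.utterance_id,
            "position": t.position,
            "speaker": t.speaker_id,
            "form": t.entry.form,
            "phones": " ".join(t.entry.phones),
            "word_class": t.entry.word_class,
            "functions": ";".join(sorted(t.entry.functions)),
            "schwa_final": t.entry.schwa_final,
            "vowel_duration_s": t.vowel_duration if t.vowel_duration is not None else "",
            "speaking_rate": t.local_speaking_rate,
            "n_segments": t.n_segments,
        })
    return pd.DataFrame(rows, columns=["token_id"] + CORPUS_COLUMNS)


def write_corpus(tokens: Sequence[CorpusToken], path) -> None:
    corpus_to_frame(tokens).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_corpus(path) -> List[CorpusToken]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"functions": str, "vowel_duration_s": str})
    tokens = []
    for _, r in df.iterrows():
        funcs = frozenset(x for x in str(r["functions"]).split(";") if x)
        entry = LexiconEntry(
            form=str(r["form"]),
            phones=tuple(str(r["phones"]).split()),
            word_class=str(r["word_class"]),
            functions=funcs,
            schwa_final=bool(r["schwa_final"] in (True, "True", "true", 1, "1")),
        )
        dur = str(r["vowel_duration_s"])
        tokens.append(CorpusToken(
            token_id=str(r["token_id"]),
            utterance_id=int(r["utterance_id"]),
            position=int(r["position"]),
            speaker_id=str(r["speaker"]),
            entry=entry,
            vowel_duration=float(dur) if dur else None,
            local_speaking_rate=float(r["speaking_rate"]),
            n_segments=int(r["n_segments"]),
        ))
    return tokens


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False, float_format="%.10g")


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path)
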