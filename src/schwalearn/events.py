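"""Sliding-window learning events for the two network structures.

A five-word window slides over each utterance (never crossing utterance
boundaries; truncated at the edges). Two contrasting cue-outcome structures
are supported:

* ``functional_output``: cues are the word forms of the non-centre window
  words plus all window diphones; outcomes are the centre word's
  inflectional-function labels, or a single placeholder when the centre
  carries none (keeping cue competition alive on every trial).
* ``functional_input``: cues are the same word and diphone cues plus,
  optionally, the centre word's function labels; outcomes are the centre
  word form plus an abstract articulatory-gesture label ``g:ER`` whenever the
  centre is schwa-final.

Labels are namespaced (``w:`` word cue, ``d:`` diphone cue, ``f:`` function
cue; ``fn:`` function outcome, ``ph:`` placeholder, ``o:`` word-form outcome,
``g:`` gesture outcome) so cue and outcome vocabularies never collide. Word
cues are lower-cased; the centre word form is never a cue in either
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Sequence

from .errors import ConfigError, DomainError
from .synthetic import CorpusToken

PLACEHOLDER_OUTCOME = "ph:NoFunction"
GESTURE_OUTCOME = "g:ER"

STRUCTURES = ("functional_output", "functional_input")


@dataclass
class NetworkSpec:
    structure: str = "functional_input"
    include_function_cues: bool = True  # ablation switch, functional_input only
    window_size: int = 5
    boundary_symbol: str = "#"

    def validate(self) -> "NetworkSpec":
        if self.structure not in STRUCTURES:
            raise ConfigError(f"structure must be one of {STRUCTURES}, "
                              f"got {self.structure!r}")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ConfigError(f"window_size must be odd and >= 1, "
                              f"got {self.window_size!r}")
        if len(self.boundary_symbol) != 1:
            raise ConfigError("boundary_symbol must be a single symbol")
        return self


@dataclass(frozen=True)
class LearningEvent:
    cues: frozenset
    outcomes: frozenset
    center_token_id: str


def extract_diphones(phone_sequences: Sequence[Sequence[str]],
                     boundary_symbol: str = "#") -> List[str]:
    """All adjacent symbol pairs of the boundary-wrapped window string.

    The per-word phone sequences are concatenated across word boundaries,
    one boundary symbol is prepended and appended to the whole string, and
    every adjacent pair is returned in order (duplicates preserved; a window
    of total phone length L yields exactly L + 1 diphones).
    """
    concat = "".join("".join(seq) for seq in phone_sequences)
    if not concat:
        raise DomainError("cannot extract diphones from an empty window")
    s = boundary_symbol + concat + boundary_symbol
    return [s[i:i + 2] for i in range(len(s) - 1)]


def build_event(window: Sequence[CorpusToken], center_index: int,
                spec: NetworkSpec) -> LearningEvent:
    """Build one learning event from a centred window of tokens."""
    spec.validate()
    if not window or not (0 <= center_index < len(window)):
        raise DomainError("window must be nonempty with a defined centre")
    center = window[center_index]

    word_cues = {
        f"w:{tok.entry.form.lower()}"
        for i, tok in enumerate(window) if i != center_index
    }
    diphones = extract_diphones([tok.entry.phones for tok in window],
                                spec.boundary_symbol)
    cues = word_cues | {f"d:{d}" for d in diphones}

    if spec.structure == "functional_output":
        if center.entry.functions:
            outcomes = frozenset(f"fn:{f}" for f in center.entry.functions)
        else:
            outcomes = frozenset({PLACEHOLDER_OUTCOME})
    else:  # functional_input
        if spec.include_function_cues and center.entry.schwa_final:
            cues |= {f"f:{f}" for f in center.entry.functions}
        outcomes = {f"o:{center.entry.form.lower()}"}
        if center.entry.schwa_final:
            outcomes.add(GESTURE_OUTCOME)
        outcomes = frozenset(outcomes)

    return LearningEvent(cues=frozenset(cues), outcomes=outcomes,
                         center_token_id=center.token_id)


def stream_events(corpus: Sequence[CorpusToken],
                  spec: NetworkSpec) -> Iterator[LearningEvent]:
    """One event per token in corpus order; windows truncated at utterance
    edges and never crossing utterance boundaries."""
    spec.validate()
    half = spec.window_size // 2
    utterance: List[CorpusToken] = []

    def flush(utt: List[CorpusToken]) -> Iterator[LearningEvent]:
        for i in range(len(utt)):
            lo = max(0, i - half)
            hi = min(len(utt), i + half + 1)
            yield build_event(utt[lo:hi], i - lo, spec)

    current = None
    for tok in corpus:
        if current is not None and tok.utterance_id != current:
            yield from flush(utterance)
            utterance = []
        current = tok.utterance_id
        utterance.append(tok)
    if utterance:
        yield from flush(utterance)


# ---------------------------------------------------------------------------
# serialization: two-column TSV, space-joined label lists

def events_to_tsv(events: Iterable[LearningEvent], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("center_token_id\tcues\toutcomes\n")
        for ev in events:
            fh.write(f"{ev.center_token_id}\t"
                     f"{' '.join(sorted(ev.cues))}\t"
                     f"{' '.join(sorted(ev.outcomes))}\n")


def events_from_tsv(path) -> List[LearningEvent]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("center_token_id"):
            raise DomainError("not an event TSV file")
        for line in fh:
            tid, cues, outcomes = line.rstrip("\n").split("\t")
            out.append(LearningEvent(frozenset(cues.split()),
                                     frozenset(outcomes.split()), tid))
    return out
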