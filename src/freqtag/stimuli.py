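"""Tone-stream construction for auditory statistical-learning experiments.

Builds the three stream types used in frequency-tagging studies of
statistical learning:

* STAT streams — four "tritones" (ordered triples of pure tones with
  within-triple transitional probability 1) alternate randomly, never
  repeating immediately, so triple-to-triple TP is 1/3.
* RDM streams — the same 12 tones in random order with no immediate
  repetition, so tone-to-tone TP is 1/11 (~9%).
* HAB streams — ascending/descending chromatic scales, with a fraction of
  ascending scales immediately repeated (the vigilance task during
  habituation).

Tones are 150 ms pure sinusoids with 5 ms raised-cosine ramps, a 25 ms
inter-stimulus interval, and in STAT/RDM streams an extra 20 ms blank every
three tones. This places the tone rate at 1/(0.175 + 0.020/3) = 5.505 Hz and
the triple rate at a third of that, 1.835 Hz, the two tagging frequencies of
the paradigm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "TONE_NAMES",
    "TONE_DURATION",
    "TONE_RAMP",
    "INTER_STIMULUS_INTERVAL",
    "BLANK_EVERY_3",
    "STAT_SET",
    "TEST_SET",
    "TimingGrid",
    "TritoneSet",
    "TokenSequence",
    "TPMatrix",
    "AFCTest",
    "tone_frequencies",
    "generate_stat_sequence",
    "generate_rdm_sequence",
    "generate_hab_sequence",
    "empirical_tp_matrix",
    "triple_transition_matrix",
    "render_audio",
    "write_wav",
    "build_2afc_test",
    "find_tritone_set",
]

#: Chromatic pitch classes, C lowest, in the English notation scheme.
TONE_NAMES: tuple[str, ...] = (
    "C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B",
)

TONE_DURATION = 0.150  # s
TONE_RAMP = 0.005  # s, raised-cosine rise and fall
INTER_STIMULUS_INTERVAL = 0.025  # s
BLANK_EVERY_3 = 0.020  # s, extra blank after every third tone (STAT/RDM)

_TONE_INDEX: Mapping[str, int] = {name: i for i, name in enumerate(TONE_NAMES)}


def tone_frequencies(reference_a: float = 440.0) -> dict[str, float]:
    """Equal-temperament frequencies for the single octave C..B.

    The octave is anchored so that A equals ``reference_a`` (A4 = 440 Hz by
    default, i.e. the C4–B4 octave): f(name) = reference_a * 2**((k-9)/12)
    with k the semitone index counted from C.
    """
    if reference_a <= 0:
        raise ValueError("reference_a must be positive")
    return {
        name: reference_a * 2.0 ** ((k - 9) / 12.0)
        for k, name in enumerate(TONE_NAMES)
    }


@dataclass(frozen=True)
class TimingGrid:
    """Stimulus timing grid.

    ``tone_onset_interval`` is the tone-onset asynchrony (duration + ISI);
    ``blank_every_3`` the extra silent gap inserted after every third tone.
    The tone rate follows as 1/(SOA + blank/3) and the triple rate as a
    third of that.
    """

    tone_onset_interval: float = TONE_DURATION + INTER_STIMULUS_INTERVAL
    blank_every_3: float = BLANK_EVERY_3

    @property
    def tritone_period(self) -> float:
        return 3.0 * self.tone_onset_interval + self.blank_every_3

    @property
    def tone_rate(self) -> float:
        return 1.0 / (self.tone_onset_interval + self.blank_every_3 / 3.0)

    @property
    def tritone_rate(self) -> float:
        return self.tone_rate / 3.0

    def onsets(self, n_tokens: int) -> np.ndarray:
        i = np.arange(n_tokens)
        return (i // 3) * self.tritone_period + (i % 3) * self.tone_onset_interval


#: Default grid for STAT/RDM streams (tone rate 5.505 Hz, triple rate 1.835 Hz).
DEFAULT_GRID = TimingGrid()
#: HAB streams use the plain 175 ms grid without the segmentation blank.
HAB_GRID = TimingGrid(blank_every_3=0.0)

#: Tagging rates implied by the default grid.
TONE_RATE = DEFAULT_GRID.tone_rate  # 5.50459... Hz
TRITONE_RATE = DEFAULT_GRID.tritone_rate  # 1.83486... Hz
TRITONE_PERIOD = DEFAULT_GRID.tritone_period  # 0.545 s


@dataclass(frozen=True)
class TritoneSet:
    """Four ordered tone triples covering the 12 pitch classes exactly once."""

    triples: tuple[tuple[str, str, str], ...]
    label: str = "STAT"

    def __post_init__(self) -> None:
        if len(self.triples) != 4 or any(len(t) != 3 for t in self.triples):
            raise ValueError("a tritone set holds exactly 4 ordered triples")
        flat = [tone for t in self.triples for tone in t]
        if sorted(flat) != sorted(TONE_NAMES):
            raise ValueError("the 12 triple slots must cover each pitch class once")

    @property
    def bigrams(self) -> set[tuple[str, str]]:
        """Within-triple ordered tone pairs (8 per set)."""
        out: set[tuple[str, str]] = set()
        for a, b, c in self.triples:
            out.add((a, b))
            out.add((b, c))
        return out

    def shares_structure_with(self, other: "TritoneSet") -> bool:
        """True if the two sets share a bigram, an initial or a final tone."""
        if self.bigrams & other.bigrams:
            return True
        starts = {t[0] for t in self.triples}
        ends = {t[2] for t in self.triples}
        o_starts = {t[0] for t in other.triples}
        o_ends = {t[2] for t in other.triples}
        return bool(starts & o_starts or ends & o_ends)


#: The exposure (STAT) set used throughout.
STAT_SET = TritoneSet(
    (("G#", "C", "D"), ("A", "C#", "G"), ("F", "A#", "D#"), ("E", "F#", "B")),
    label="STAT",
)
#: The never-heard foil set used in the 2AFC recognition test.
TEST_SET = TritoneSet(
    (("D", "G#", "F"), ("D#", "A#", "A"), ("B", "C#", "F#"), ("G", "C", "E")),
    label="TEST",
)


def find_tritone_set(
    rng: np.random.Generator | int | None = None,
    existing: TritoneSet | None = None,
    max_tries: int = 100_000,
    label: str = "TEST",
) -> TritoneSet:
    """Search for a fresh tritone set by rejection sampling.

    A random partition of the 12 tones into 4 ordered triples is accepted if
    it shares no within-triple bigram and no initial/final tone with
    ``existing`` (when given). Mirrors the constrained pseudo-random
    construction of the printed sets.
    """
    rng = np.random.default_rng(rng)
    for _ in range(max_tries):
        perm = rng.permutation(12)
        triples = tuple(
            tuple(TONE_NAMES[j] for j in perm[3 * i : 3 * i + 3]) for i in range(4)
        )
        cand = TritoneSet(triples, label=label)  # type: ignore[arg-type]
        if existing is None or not cand.shares_structure_with(existing):
            return cand
    raise RuntimeError("no admissible tritone set found")


@dataclass
class TokenSequence:
    """An ordered tone stream on a timing grid.

    ``triplet_id`` numbers the triple each token belongs to (STAT streams);
    ``trigger_onsets`` mark every third tone, mirroring the trigger channel
    of the recording; ``repeat_marks`` are onsets of repeated ascending
    scales (HAB streams).
    """

    tokens: list[str]
    stream_type: str  # {"STAT", "RDM", "HAB"}
    grid: TimingGrid = field(default_factory=TimingGrid)
    triplet_id: np.ndarray | None = None
    repeat_marks: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.tokens) - set(TONE_NAMES)
        if unknown:
            raise ValueError(f"unknown tone names: {sorted(unknown)}")
        self.onsets = self.grid.onsets(len(self.tokens))

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def trigger_onsets(self) -> np.ndarray:
        return self.onsets[::3]

    @property
    def duration(self) -> float:
        """Stream length including the trailing ISI (and blank after a
        complete triple), so STAT streams span n_triples * 0.545 s."""
        n = self.n_tokens
        if n == 0:
            return 0.0
        end = self.onsets[-1] + self.grid.tone_onset_interval
        if n % 3 == 0:
            end += self.grid.blank_every_3
        return float(end)

    def token_indices(self) -> np.ndarray:
        return np.array([_TONE_INDEX[t] for t in self.tokens], dtype=np.intp)

    def to_events_frame(self) -> pd.DataFrame:
        trig = np.zeros(self.n_tokens, dtype=bool)
        trig[::3] = True
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "token": self.tokens,
                "triplet_id": (
                    self.triplet_id if self.triplet_id is not None else -1
                ),
                "trigger_flag": trig.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_events_frame().to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        return {
            "stream_type": self.stream_type,
            "n_tokens": self.n_tokens,
            "seed": self.seed,
            "tone_onset_interval_s": self.grid.tone_onset_interval,
            "blank_every_3_s": self.grid.blank_every_3,
            "tone_rate_hz": self.grid.tone_rate,
            "tritone_rate_hz": self.grid.tritone_rate,
            "duration_s": self.duration,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_stat_sequence(
    n_triples: int,
    tritone_set: TritoneSet = STAT_SET,
    seed: np.random.Generator | int | None = None,
) -> TokenSequence:
    """Random alternation of the four triples, immediate repetition barred.

    The successor triple is drawn uniformly from the other three, giving the
    design triple-to-triple transitional probability of 1/3 while every
    within-triple tone transition has probability 1.
    """
    if n_triples < 1:
        raise ValueError("n_triples must be >= 1")
    rng = _as_rng(seed)
    order = np.empty(n_triples, dtype=np.intp)
    order[0] = rng.integers(4)
    steps = rng.integers(1, 4, size=n_triples - 1)
    for i in range(1, n_triples):
        order[i] = (order[i - 1] + steps[i - 1]) % 4
    tokens: list[str] = []
    for idx in order:
        tokens.extend(tritone_set.triples[idx])
    triplet_id = np.repeat(np.arange(n_triples), 3)
    return TokenSequence(
        tokens,
        stream_type="STAT",
        triplet_id=triplet_id,
        seed=seed if isinstance(seed, int) else None,
    )


def generate_rdm_sequence(
    n_tones: int, seed: np.random.Generator | int | None = None
) -> TokenSequence:
    """Uniform random tone stream with no immediate repetition.

    Each successor is drawn uniformly from the 11 other tones, so every
    off-diagonal transitional probability is 1/11 (the "9%" random baseline).
    The timing grid is identical to STAT streams, blank included.
    """
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    rng = _as_rng(seed)
    idx = np.empty(n_tones, dtype=np.intp)
    idx[0] = rng.integers(12)
    steps = rng.integers(1, 12, size=n_tones - 1)
    for i in range(1, n_tones):
        idx[i] = (idx[i - 1] + steps[i - 1]) % 12
    tokens = [TONE_NAMES[j] for j in idx]
    return TokenSequence(
        tokens, stream_type="RDM", seed=seed if isinstance(seed, int) else None
    )


def generate_hab_sequence(
    n_scales: int,
    repeat_prob: float = 0.3,
    seed: np.random.Generator | int | None = None,
) -> TokenSequence:
    """Habituation stream: ascending then descending chromatic scales.

    Each of the ``n_scales`` ascending scales is independently repeated with
    probability ``repeat_prob`` (the listener's vigilance target); repeats
    are logged in ``repeat_marks``. HAB streams run on the plain 175 ms grid
    without the 20 ms segmentation blank.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if not 0.0 <= repeat_prob <= 1.0:
        raise ValueError("repeat_prob must lie in [0, 1]")
    rng = _as_rng(seed)
    ascending = list(TONE_NAMES)
    descending = list(TONE_NAMES[::-1])
    repeats = rng.random(n_scales) < repeat_prob
    tokens: list[str] = []
    mark_token_idx: list[int] = []
    for rep in repeats:
        tokens.extend(ascending)
        if rep:
            mark_token_idx.append(len(tokens))
            tokens.extend(ascending)
        tokens.extend(descending)
    seq = TokenSequence(
        tokens,
        stream_type="HAB",
        grid=HAB_GRID,
        seed=seed if isinstance(seed, int) else None,
    )
    seq.repeat_marks = seq.onsets[np.asarray(mark_token_idx, dtype=np.intp)]
    return seq


@dataclass
class TPMatrix:
    """Empirical 12x12 tone transition counts and row-normalised probabilities."""

    counts: np.ndarray
    probs: np.ndarray
    tones: tuple[str, ...] = TONE_NAMES

    def prob(self, a: str, b: str) -> float:
        return float(self.probs[_TONE_INDEX[a], _TONE_INDEX[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.tones, columns=self.tones)

    def mean_offdiagonal(self) -> float:
        off = ~np.eye(12, dtype=bool)
        return float(self.probs[off].mean())


def empirical_tp_matrix(seq: TokenSequence) -> TPMatrix:
    """Ordered-bigram counts and row-normalised transitional probabilities."""
    if seq.n_tokens < 2:
        raise ValueError("need at least 2 tokens to estimate transitions")
    idx = seq.token_indices()
    counts = np.zeros((12, 12))
    np.add.at(counts, (idx[:-1], idx[1:]), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    probs = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    return TPMatrix(counts=counts, probs=probs)


def triple_transition_matrix(
    seq: TokenSequence, tritone_set: TritoneSet = STAT_SET
) -> np.ndarray:
    """4x4 row-stochastic matrix of triple-to-triple transitions in a STAT stream."""
    if seq.n_tokens % 3 != 0:
        raise ValueError("STAT sequence length must be a multiple of 3")
    lookup = {t: i for i, t in enumerate(tritone_set.triples)}
    toks = seq.tokens
    order = [lookup[tuple(toks[i : i + 3])] for i in range(0, len(toks), 3)]
    counts = np.zeros((4, 4))
    o = np.asarray(order)
    np.add.at(counts, (o[:-1], o[1:]), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)


def _tone_envelope(n: int, fs: float, ramp: float = TONE_RAMP) -> np.ndarray:
    env = np.ones(n)
    nr = int(round(ramp * fs))
    if nr > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def render_audio(
    seq: TokenSequence,
    sample_rate: float = 96_000.0,
    amplitude: float = 0.9,
    reference_a: float = 440.0,
) -> np.ndarray:
    """Render the stream as a float32 waveform of pure ramped sinusoids.

    Silence fills the inter-stimulus intervals and blanks; total duration is
    ``seq.duration`` (560 triples -> 305.20 s for STAT streams).
    """
    freqs = tone_frequencies(reference_a)
    if sample_rate < 2.0 * max(freqs.values()):
        raise ValueError("sample_rate below Nyquist for the tone set")
    n_total = int(round(seq.duration * sample_rate))
    out = np.zeros(n_total, dtype=np.float64)
    n_tone = int(round(TONE_DURATION * sample_rate))
    env = _tone_envelope(n_tone, sample_rate)
    t = np.arange(n_tone) / sample_rate
    # pre-render the 12 tones once
    bank = {
        name: amplitude * env * np.sin(2.0 * np.pi * f * t)
        for name, f in freqs.items()
    }
    for token, onset in zip(seq.tokens, seq.onsets):
        i0 = int(round(onset * sample_rate))
        out[i0 : i0 + n_tone] = bank[token][: max(0, n_total - i0)]
    return out.astype(np.float32)


def write_wav(path, waveform: np.ndarray, sample_rate: float = 96_000.0) -> None:
    """Write a float32 WAV file (PCM float, byte-identical under a fixed seed)."""
    wavfile.write(path, int(round(sample_rate)), np.asarray(waveform, dtype=np.float32))


@dataclass
class AFCTest:
    """Two-alternative forced-choice recognition test.

    16 trials pair each exposure (STAT) triple with each foil (TEST) triple
    exactly once; ``order_flags`` records whether the STAT member is played
    first (counterbalanced, 8 of 16).
    """

    trials: list[tuple[tuple[str, str, str], tuple[str, str, str]]]
    order_flags: np.ndarray  # True -> STAT triple first
    isi: float = 1.0

    def __post_init__(self) -> None:
        if len(self.trials) != 16:
            raise ValueError("a 2AFC test has 16 trials")
        if int(np.sum(self.order_flags)) != 8:
            raise ValueError("order must be counterbalanced (8 STAT-first)")


def build_2afc_test(
    stat: TritoneSet = STAT_SET,
    test: TritoneSet = TEST_SET,
    seed: np.random.Generator | int | None = None,
) -> AFCTest:
    """All 16 STAT x TEST pairings in random order, presentation order balanced."""
    if len(stat.triples) != 4 or len(test.triples) != 4:
        raise ValueError("both sets must hold 4 triples")
    rng = _as_rng(seed)
    pairs = [(s, t) for s in stat.triples for t in test.triples]
    order = rng.permutation(16)
    trials = [pairs[i] for i in order]
    flags = np.zeros(16, dtype=bool)
    flags[rng.choice(16, size=8, replace=False)] = True
    return AFCTest(trials=trials, order_flags=flags)
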