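"""Corpora of symbolic melodies: MIDI I/O, tokenization, synthetic corpora.

The learner consumes :class:`SymbolSequence` objects whose tokens are base
symbols of the form ``p<pitch>d<duration>`` — absolute MIDI pitch plus the
note duration quantized to a small grid of beat values. Duration is part of
the alphabet so that generated songs can vary rhythm, which the downstream
amplitude-modulation analysis measures.

Real corpora are read from Standard MIDI Files; synthetic corpora with
planted high-transition-probability motifs stand in for a children's-song
corpus when none is available, and give tests a known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .midi import (
    DEFAULT_BPM,
    NoteEvent,
    read_midi_file,
    write_midi_file,
)

#: Quantization grid for note durations, in beats.
DURATION_GRID = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)

#: C-major scale used to map synthetic alphabet indices onto pitches.
_SCALE = (60, 62, 64, 65, 67, 69, 71)


@dataclass
class SymbolSequence:
    """A tokenized song: ordered base-symbol ids plus rendering metadata."""

    tokens: list[str]
    source_id: str = ""
    tempo: float = DEFAULT_BPM

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("SymbolSequence must be non-empty")

    def __len__(self) -> int:
        return len(self.tokens)


def make_token(pitch: int, duration: float) -> str:
    """Encode (pitch, quantized duration) as a base-symbol id."""
    return f"p{pitch}d{duration:g}"


def parse_token(token: str) -> tuple[int, float]:
    """Decode a base-symbol id back to (pitch, duration in beats)."""
    pitch_s, dur_s = token[1:].split("d")
    return int(pitch_s), float(dur_s)


def quantize_duration(duration: float, grid: Sequence[float] = DURATION_GRID) -> float:
    """Snap a duration in beats to the nearest grid value (clamping extremes)."""
    arr = np.asarray(grid, dtype=float)
    if duration < arr[0] / 2 or duration > arr[-1] * 1.5:
        warnings.warn(
            f"duration {duration:.3g} beats outside quantization grid; clamped",
            stacklevel=2,
        )
    return float(arr[np.argmin(np.abs(arr - duration))])


def tokenize(
    events: Sequence[NoteEvent],
    source_id: str = "",
    tempo: float = DEFAULT_BPM,
    grid: Sequence[float] = DURATION_GRID,
) -> SymbolSequence:
    """Map monophonic note events to a base-symbol sequence.

    Each event becomes one token ``(pitch, quantized duration)``; onsets are
    dropped (rests are absorbed at render time).
    """
    if not events:
        raise ValueError("cannot tokenize an empty event list")
    tokens = [make_token(e.pitch, quantize_duration(e.duration, grid)) for e in events]
    return SymbolSequence(tokens=tokens, source_id=source_id, tempo=tempo)


def detokenize(seq: SymbolSequence, velocity: int = 80) -> list[NoteEvent]:
    """Render tokens back to note events, onsets chained end-to-end."""
    events = []
    onset = 0.0
    for tok in seq.tokens:
        pitch, dur = parse_token(tok)
        events.append(NoteEvent(onset=onset, pitch=pitch, duration=dur, velocity=velocity))
        onset += dur
    return events


def read_midi(path: str | Path, source_id: str | None = None) -> SymbolSequence:
    """Read an SMF, reduce to a monophonic line, and tokenize it."""
    events, tempo = read_midi_file(path)
    sid = source_id if source_id is not None else Path(path).stem
    return tokenize(events, source_id=sid, tempo=tempo)


def write_midi(seq: SymbolSequence, path: str | Path) -> None:
    """Write a token sequence as a format-0 SMF at the sequence's tempo."""
    write_midi_file(path, detokenize(seq), tempo_bpm=seq.tempo)


# ---------------------------------------------------------------------------
# Synthetic corpora with planted motifs
# ---------------------------------------------------------------------------


def build_alphabet(
    alphabet_size: int, durations: Sequence[float] | float = 0.5
) -> list[str]:
    """Construct `alphabet_size` distinct base tokens on a diatonic scale.

    `durations` is either one duration for every token or a per-token list;
    values are snapped to the quantization grid.
    """
    if np.isscalar(durations):
        durations = [float(durations)] * alphabet_size
    if len(durations) != alphabet_size:
        raise ValueError("durations must match alphabet_size")
    tokens = []
    for k in range(alphabet_size):
        pitch = _SCALE[k % len(_SCALE)] + 12 * (k // len(_SCALE))
        tokens.append(make_token(pitch, quantize_duration(durations[k])))
    if len(set(tokens)) != alphabet_size:
        raise ValueError("alphabet collapsed under quantization; vary durations")
    return tokens


@dataclass
class SyntheticCorpusSpec:
    """Parameters of a planted-motif corpus.

    At each emission step a song either emits a full motif (probability
    `motif_rate`) or a single uniform-random alphabet token. Motifs are given
    as tuples of alphabet indices, 2-4 tokens long.
    """

    n_songs: int = 50
    alphabet_size: int = 12
    motifs: tuple[tuple[int, ...], ...] = ((0, 1, 2),)
    motif_rate: float = 0.5
    song_length: int = 60
    seed: int = 0
    durations: Sequence[float] | float = 0.5
    #: relative emission weights among motifs (uniform when None); unequal
    #: weights plant motifs of graded strength, like frequent and rare
    #: figures in a real song corpus
    motif_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must be a probability")
        for motif in self.motifs:
            if not 2 <= len(motif) <= 4:
                raise ValueError("motifs must be 2-4 tokens long")
            if max(motif) >= self.alphabet_size:
                raise ValueError("motif token index outside alphabet")
        if self.n_songs < 1 or self.song_length < 2:
            raise ValueError("need at least one song of at least two tokens")
        if self.motif_weights is not None and (
            len(self.motif_weights) != len(self.motifs)
            or any(w < 0 for w in self.motif_weights)
        ):
            raise ValueError("motif_weights must be non-negative, one per motif")


def generate_synthetic_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[SymbolSequence], list[tuple[str, ...]]]:
    """Generate a corpus with planted motifs; returns (songs, ground truth).

    Reproducible: all randomness derives from ``spec.seed``. Ground truth is
    the planted motifs expressed as base-token tuples.
    """
    alphabet = build_alphabet(spec.alphabet_size, spec.durations)
    motif_tokens = [tuple(alphabet[i] for i in m) for m in spec.motifs]
    if spec.motif_weights is not None:
        weights = np.asarray(spec.motif_weights, dtype=float)
        weights = weights / weights.sum()
    else:
        weights = None
    rng = np.random.default_rng(spec.seed)
    songs = []
    for s in range(spec.n_songs):
        tokens: list[str] = []
        while len(tokens) < spec.song_length:
            if spec.motifs and rng.random() < spec.motif_rate:
                tokens.extend(motif_tokens[rng.choice(len(motif_tokens), p=weights)])
            else:
                tokens.append(alphabet[rng.integers(spec.alphabet_size)])
        songs.append(
            SymbolSequence(tokens=tokens[: spec.song_length], source_id=f"synth-{s:03d}")
        )
    return songs, motif_tokens


def corpus_manifest(
    songs: Sequence[SymbolSequence], culture: str = "synthetic"
) -> pd.DataFrame:
    """Tabulate a corpus: song_id, path (if rendered), token count, culture tag."""
    return pd.DataFrame(
        {
            "song_id": [s.source_id for s in songs],
            "path": ["" for _ in songs],
            "n_tokens": [len(s) for s in songs],
            "culture": culture,
        }
    )
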