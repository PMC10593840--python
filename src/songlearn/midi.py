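"""Minimal Standard MIDI File (SMF) reader/writer for monophonic melodies.

Supports format 0 and 1 files, note on/off events, running status and the
set-tempo meta event — the subset needed to move children's-song melodies in
and out of the learner. Times are converted between MIDI ticks and beats via
the file's ticks-per-quarter-note; tempo only matters at audio render time.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

DEFAULT_TICKS_PER_BEAT = 480
DEFAULT_BPM = 120.0


class MidiFormatError(ValueError):
    """Raised when a file is not a parseable Standard MIDI File."""


@dataclass(frozen=True, order=True)
class NoteEvent:
    """One melodic note: MIDI pitch, onset and duration in beats, velocity."""

    onset: float
    pitch: int
    duration: float
    velocity: int = 80

    def __post_init__(self) -> None:
        if not (0 <= self.pitch <= 127):
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0-127")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (1 <= self.velocity <= 127):
            raise ValueError("velocity must be in 1-127")


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes):
    """Yield (abs_tick, status, data1, data2) channel events and tempo metas."""
    pos = 0
    tick = 0
    running = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running = status
        else:
            if running is None:
                raise MidiFormatError("data byte with no running status")
            status = running
        kind = status & 0xF0
        if status == 0xFF:  # meta
            meta_type = data[pos]
            length, pos = _read_varlen(data, pos + 1)
            payload = data[pos : pos + length]
            pos += length
            if meta_type == 0x51 and length == 3:
                usec_per_beat = int.from_bytes(payload, "big")
                yield tick, "tempo", usec_per_beat, 0
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        elif kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
            d1, d2 = data[pos], data[pos + 1]
            pos += 2
            if kind == 0x90 and d2 == 0:
                kind = 0x80  # note-on vel 0 == note-off
            if kind == 0x90:
                yield tick, "on", d1, d2
            elif kind == 0x80:
                yield tick, "off", d1, d2
        elif kind in (0xC0, 0xD0):
            pos += 1
        else:
            raise MidiFormatError(f"unsupported status byte 0x{status:02x}")


def read_midi_file(path: str | Path) -> tuple[list[NoteEvent], float]:
    """Read an SMF and return (monophonic note events in beats, tempo in BPM).

    Note on/off pairs are resolved per pitch; overlapping notes are reduced to
    a single melodic line (highest pitch wins, earlier notes truncated at the
    onset of a higher overlapping note). The first tempo event found sets the
    returned BPM; files without one default to 120.
    """
    data = Path(path).read_bytes()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError(f"{path}: missing MThd header")
    header_len = struct.unpack(">I", data[4:8])[0]
    fmt, ntracks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise MidiFormatError(f"{path}: unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiFormatError(f"{path}: SMPTE time division not supported")
    ticks_per_beat = division or DEFAULT_TICKS_PER_BEAT

    pos = 8 + header_len
    events = []
    tempo_bpm = None
    for _ in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise MidiFormatError(f"{path}: missing MTrk chunk")
        length = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        track = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        try:
            for tick, kind, d1, d2 in _parse_track(track):
                if kind == "tempo" and tempo_bpm is None:
                    tempo_bpm = 60_000_000 / d1
                elif kind in ("on", "off"):
                    events.append((tick, kind, d1, d2))
        except IndexError as exc:
            raise MidiFormatError(f"{path}: truncated track data") from exc

    events.sort(key=lambda e: (e[0], e[1] == "on"))  # offs before ons at a tick
    open_notes: dict[int, tuple[int, int]] = {}
    notes: list[NoteEvent] = []
    for tick, kind, pitch, vel in events:
        if kind == "on":
            open_notes[pitch] = (tick, vel)
        elif pitch in open_notes:
            start, vel_on = open_notes.pop(pitch)
            if tick > start:
                notes.append(
                    NoteEvent(
                        onset=start / ticks_per_beat,
                        pitch=pitch,
                        duration=(tick - start) / ticks_per_beat,
                        velocity=max(1, vel_on),
                    )
                )
    if not notes:
        raise MidiFormatError(f"{path}: file contains no notes")
    return to_monophonic(notes), tempo_bpm or DEFAULT_BPM


def to_monophonic(notes: Iterable[NoteEvent]) -> list[NoteEvent]:
    """Reduce possibly-overlapping notes to one melodic line.

    Simultaneous onsets keep the highest pitch. A note starting inside the
    previous kept note either truncates it (if higher-pitched) or is dropped.
    """
    by_onset: dict[float, NoteEvent] = {}
    for n in sorted(notes, key=lambda n: (n.onset, -n.pitch)):
        by_onset.setdefault(n.onset, n)
    line: list[NoteEvent] = []
    for n in by_onset.values():
        if line:
            prev = line[-1]
            prev_end = prev.onset + prev.duration
            if n.onset < prev_end:
                if n.pitch > prev.pitch and n.onset > prev.onset:
                    line[-1] = NoteEvent(
                        onset=prev.onset,
                        pitch=prev.pitch,
                        duration=n.onset - prev.onset,
                        velocity=prev.velocity,
                    )
                elif n.pitch <= prev.pitch:
                    continue
                else:  # same onset already handled by by_onset
                    continue
        line.append(n)
    return line


def write_midi_file(
    path: str | Path,
    notes: Iterable[NoteEvent],
    tempo_bpm: float = DEFAULT_BPM,
    ticks_per_beat: int = DEFAULT_TICKS_PER_BEAT,
) -> None:
    """Write note events as a format-0 SMF with a single tempo event."""
    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for n in sorted(notes):
        start = round(n.onset * ticks_per_beat)
        end = round((n.onset + n.duration) * ticks_per_beat)
        end = max(end, start + 1)
        events.append((start, 1, bytes((0x90, n.pitch, n.velocity))))
        events.append((end, 0, bytes((0x80, n.pitch, 0))))
    events.sort(key=lambda e: (e[0], e[1]))

    usec = round(60_000_000 / tempo_bpm)
    track = bytearray()
    track += _write_varlen(0) + bytes((0xFF, 0x51, 0x03)) + usec.to_bytes(3, "big")
    last_tick = 0
    for tick, _, msg in events:
        track += _write_varlen(tick - last_tick) + msg
        last_tick = tick
    track += _write_varlen(0) + bytes((0xFF, 0x2F, 0x00))  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_beat))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
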