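"""Minimal Standard MIDI File support for keystroke performance data.

Performance recordings arrive as SMF format 0/1 files whose note-on events
carry keystroke onsets (delta times), pitches and velocities.  Only what the
trialwise analysis needs is implemented: note-on extraction with a
tempo-map-correct tick-to-seconds conversion, and segmentation of the onset
stream into trials at silent gaps.  A small writer exists so tests can
round-trip synthetic performances; neither reader nor writer aims to cover
the full MIDI specification.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MidiParseError", "NoteOn", "read_midi_notes", "read_midi", "write_midi"]

DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 bpm)


class MidiParseError(ValueError):
    """Malformed Standard MIDI File."""


@dataclass(frozen=True)
class NoteOn:
    onset_s: float
    note: int
    velocity: int
    track: int


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiParseError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiParseError("variable-length quantity too long")


def _parse_track(data: bytes, track_no: int) -> list[tuple[int, str, tuple]]:
    """Return [(abs_tick, kind, payload)] for note-on and tempo events."""
    events = []
    pos = 0
    tick = 0
    status = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        if pos >= len(data):
            raise MidiParseError("truncated event")
        byte = data[pos]
        if byte == 0xFF:                      # meta event
            if pos + 2 > len(data):
                raise MidiParseError("truncated meta event")
            meta_type = data[pos + 1]
            length, p = _read_varlen(data, pos + 2)
            payload = data[p:p + length]
            pos = p + length
            if meta_type == 0x51:
                if length != 3:
                    raise MidiParseError("malformed set-tempo event")
                tempo = int.from_bytes(payload, "big")
                events.append((tick, "tempo", (tempo,)))
            status = None
            continue
        if byte in (0xF0, 0xF7):              # sysex: skip
            length, p = _read_varlen(data, pos + 1)
            pos = p + length
            status = None
            continue
        if byte & 0x80:
            status = byte
            pos += 1
        elif status is None:
            raise MidiParseError("running status without prior status byte")
        if status is None:
            raise MidiParseError("unexpected data byte")
        kind = status & 0xF0
        n_data = 1 if kind in (0xC0, 0xD0) else 2
        if pos + n_data > len(data):
            raise MidiParseError("truncated channel event")
        d = data[pos:pos + n_data]
        pos += n_data
        if kind == 0x90 and d[1] > 0:
            events.append((tick, "note_on", (d[0], d[1], track_no)))
    return events


def read_midi_notes(path) -> list[NoteOn]:
    """All note-on events of an SMF file, with onsets in seconds.

    Tick times are converted to seconds through the file's tempo map (all
    set-tempo events across tracks, as in format-1 files with a dedicated
    tempo track); SMPTE divisions are not supported.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 14 or blob[:4] != b"MThd":
        raise MidiParseError("missing MThd header")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", blob[4:14])
    if header_len != 6:
        raise MidiParseError(f"unexpected header length {header_len}")
    if fmt not in (0, 1):
        raise MidiParseError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiParseError("SMPTE time division not supported")
    if division == 0:
        raise MidiParseError("zero ticks-per-quarter division")

    pos = 14
    all_events: list[tuple[int, str, tuple]] = []
    for track_no in range(n_tracks):
        if pos + 8 > len(blob):
            raise MidiParseError("truncated track header")
        if blob[pos:pos + 4] != b"MTrk":
            raise MidiParseError("missing MTrk chunk")
        (length,) = struct.unpack(">I", blob[pos + 4:pos + 8])
        chunk = blob[pos + 8:pos + 8 + length]
        if len(chunk) != length:
            raise MidiParseError("truncated track data")
        all_events.extend(_parse_track(chunk, track_no))
        pos += 8 + length

    # tempo map: piecewise-constant microseconds per quarter over ticks
    all_events.sort(key=lambda e: e[0])
    notes = []
    seconds = 0.0
    last_tick = 0
    tempo = DEFAULT_TEMPO_US
    for tick, kind, payload in all_events:
        seconds += (tick - last_tick) * tempo / (1e6 * division)
        last_tick = tick
        if kind == "tempo":
            tempo = payload[0]
        else:
            note, vel, track_no = payload
            notes.append(NoteOn(seconds, note, vel, track_no))
    return notes


def read_midi(path, gap_s: float = 2.0, min_notes: int = 2) -> pd.DataFrame:
    """Trialwise keystroke table from an SMF performance recording.

    Consecutive note onsets separated by more than ``gap_s`` seconds start a
    new trial (trials are separated by feedback presentation in the task).
    Returns columns (trial, position, iki_s, velocity, pitch); ``iki_s`` is
    empty for the first keystroke of each trial.  Trials with fewer than
    ``min_notes`` keystrokes are reported with a warning but kept.
    """
    notes = read_midi_notes(path)
    if not notes:
        warnings.warn("no note-on events found; zero trials", stacklevel=2)
        return pd.DataFrame(
            columns=["trial", "position", "iki_s", "velocity", "pitch"])

    rows = []
    trial = 1
    position = 0
    prev_onset = None
    short_trials = 0
    trial_len = 0
    for n in notes:
        if prev_onset is not None and n.onset_s - prev_onset > gap_s:
            if trial_len < min_notes:
                short_trials += 1
            trial += 1
            position = 0
            trial_len = 0
        position += 1
        trial_len += 1
        rows.append({
            "trial": trial,
            "position": position,
            "iki_s": np.nan if position == 1 else n.onset_s - prev_onset,
            "velocity": n.velocity,
            "pitch": n.note,
        })
        prev_onset = n.onset_s
    if trial_len < min_notes:
        short_trials += 1
    if short_trials:
        warnings.warn(
            f"{short_trials} trial(s) shorter than {min_notes} notes; "
            "segmentation may be ambiguous — check gap_s", stacklevel=2)
    return pd.DataFrame(rows)


def _varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def write_midi(path, events, division: int = 480) -> None:
    """Write a single-track SMF format-0 file from low-level events.

    ``events`` is an iterable of tuples: ``("note_on", delta_ticks, note,
    velocity)``, ``("note_off", delta_ticks, note)`` or ``("tempo",
    delta_ticks, us_per_quarter)``.  Intended for constructing test fixtures
    with a known tempo map.
    """
    track = bytearray()
    for ev in events:
        kind, delta = ev[0], int(ev[1])
        track += _varlen(delta)
        if kind == "note_on":
            track += bytes((0x90, ev[2], ev[3]))
        elif kind == "note_off":
            track += bytes((0x80, ev[2], 0))
        elif kind == "tempo":
            track += bytes((0xFF, 0x51, 0x03)) + int(ev[2]).to_bytes(3, "big")
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    track += bytes((0x00, 0xFF, 0x2F, 0x00))  # end of track
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, division))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
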