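"""Bit-exact event-packet format and tidy CSV conversion.

Every metronome window is serialized as a fixed 12-byte packet: a 4-byte
unsigned onset time (integer ms, truncated from the engine's real-valued
time) followed by four signed 2-byte tap times relative to the tone, in
tapper order.  Missing taps -- and unused slots when fewer than four
tappers play -- are encoded as the sentinel -32768, the minimum int16,
which lies outside any legal attribution window.  Byte order is
little-endian (the AVR convention).  A trial file (``.gem``) is the
concatenation of its packets, optionally accompanied by a JSON sidecar
carrying the trial config and seed.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from gemtap.engine import MISSING, TrialConfig, TrialData, WindowRecord

log = logging.getLogger("gemtap.packet")

PACKET_SIZE = 12
N_SLOTS = 4
MISSING_SENTINEL = -32768

_PACKET = struct.Struct("<I4h")
assert _PACKET.size == PACKET_SIZE


class PacketError(ValueError):
    """Raised on malformed or unserializable packet data."""


def write_packet(record: WindowRecord) -> bytes:
    """Serialize one window record into exactly 12 bytes."""
    onset = int(record.tone_time)  # truncate to integer ms
    if not 0 <= onset < 2**32:
        raise PacketError(f"tone onset {onset} ms does not fit in 32 bits")
    slots = []
    for rel in record.tap_rel:
        if rel is MISSING:
            slots.append(MISSING_SENTINEL)
            continue
        value = int(round(rel))
        if not -32767 <= value <= 32767:
            raise PacketError(f"relative tap time {value} ms does not fit in 15 bits")
        slots.append(value)
    if len(slots) > N_SLOTS:
        raise PacketError(f"{len(slots)} tap slots exceed packet capacity {N_SLOTS}")
    slots.extend([MISSING_SENTINEL] * (N_SLOTS - len(slots)))
    return _PACKET.pack(onset, *slots)


def read_packet(data: bytes, tone_index: int = 0) -> WindowRecord:
    """Parse a single 12-byte packet into a window record (4 tap slots)."""
    if len(data) != PACKET_SIZE:
        raise PacketError(f"packet must be {PACKET_SIZE} bytes, got {len(data)}")
    onset, *slots = _PACKET.unpack(data)
    rel = tuple(MISSING if s == MISSING_SENTINEL else float(s) for s in slots)
    return WindowRecord(tone_index=tone_index, tone_time=float(onset), tap_rel=rel)


def read_stream(data: bytes) -> list[WindowRecord]:
    """Parse a concatenation of packets, validating onset monotonicity."""
    if len(data) % PACKET_SIZE != 0:
        offset = (len(data) // PACKET_SIZE) * PACKET_SIZE
        raise PacketError(
            f"truncated stream: {len(data)} bytes is not a multiple of "
            f"{PACKET_SIZE}; trailing partial packet at byte offset {offset}"
        )
    records = []
    prev_onset = None
    for k in range(len(data) // PACKET_SIZE):
        rec = read_packet(data[k * PACKET_SIZE : (k + 1) * PACKET_SIZE], tone_index=k)
        if prev_onset is not None and rec.tone_time <= prev_onset:
            log.warning(
                "non-increasing tone onset at packet %d: %.0f after %.0f",
                k, rec.tone_time, prev_onset,
            )
        prev_onset = rec.tone_time
        records.append(rec)
    return records


def write_stream(trial: TrialData) -> bytes:
    """Serialize a whole trial; the result is exactly 12 x n_tones bytes."""
    return b"".join(write_packet(rec) for rec in trial.records)


def _trim(record: WindowRecord, n_tappers: int) -> WindowRecord:
    return WindowRecord(
        tone_index=record.tone_index,
        tone_time=record.tone_time,
        tap_rel=record.tap_rel[:n_tappers],
    )


def save_gem(trial: TrialData, path: str | Path) -> None:
    """Write a ``.gem`` binary plus a JSON sidecar with config and seed."""
    path = Path(path)
    path.write_bytes(write_stream(trial))
    sidecar = {
        "config": asdict(trial.config),
        "seed": list(trial.seed) if trial.seed is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_gem(path: str | Path) -> TrialData:
    """Read a ``.gem`` binary, using the sidecar for config if present;
    without a sidecar the trial is assumed to have four tappers and the
    config is inferred from the packet stream."""
    path = Path(path)
    records = read_stream(path.read_bytes())
    sidecar_path = path.with_suffix(path.suffix + ".json")
    seed = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        cfg = TrialConfig(**sidecar["config"])
        seed = tuple(sidecar["seed"]) if sidecar["seed"] is not None else None
        records = [_trim(r, cfg.n_tappers) for r in records]
    else:
        ioi = records[1].tone_time - records[0].tone_time if len(records) > 1 else 500.0
        cfg = TrialConfig(ioi_nominal=ioi, n_tones=max(len(records), 2), n_tappers=N_SLOTS)
    return TrialData(config=cfg, seed=seed, records=tuple(records))


#: Tidy CSV schema: one row per window per tapper.
CSV_COLUMNS = ["trial_id", "alpha", "tone_index", "tone_time", "tapper_id", "tap_rel", "missed"]


def to_csv(trial: TrialData, trial_id: int | str = 0) -> pd.DataFrame:
    """Flatten a trial into the tidy one-row-per-window-per-tapper layout.

    Missing taps render as an empty ``tap_rel`` cell with ``missed = 1``.
    """
    rows = []
    for rec in trial.records:
        for i, rel in enumerate(rec.tap_rel):
            rows.append(
                {
                    "trial_id": trial_id,
                    "alpha": trial.config.alpha,
                    "tone_index": rec.tone_index,
                    "tone_time": rec.tone_time,
                    "tapper_id": i,
                    "tap_rel": float("nan") if rel is MISSING else float(rel),
                    "missed": int(rel is MISSING),
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def from_csv(
    frame: pd.DataFrame,
    config: Optional[TrialConfig] = None,
    seed: Optional[tuple] = None,
) -> TrialData:
    """Rebuild a trial from the tidy layout; lossless for integer-ms data.

    Unknown columns are ignored with a warning.  If no config is given,
    IOI, tone count, tapper count and alpha are inferred from the table.
    """
    unknown = [c for c in frame.columns if c not in CSV_COLUMNS]
    if unknown:
        log.warning("ignoring unknown columns: %s", unknown)
    missing_cols = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise PacketError(f"tidy table lacks required columns: {missing_cols}")
    n_tappers = int(frame["tapper_id"].nunique())
    tones = frame.sort_values(["tone_index", "tapper_id"])
    records = []
    for tone_index, group in tones.groupby("tone_index", sort=True):
        tone_time = float(group["tone_time"].iloc[0])
        rel: list[Optional[float]] = [MISSING] * n_tappers
        for _, row in group.iterrows():
            if not row["missed"] and pd.notna(row["tap_rel"]):
                rel[int(row["tapper_id"])] = float(row["tap_rel"])
        records.append(
            WindowRecord(tone_index=int(tone_index), tone_time=tone_time, tap_rel=tuple(rel))
        )
    if config is None:
        ioi = records[1].tone_time - records[0].tone_time if len(records) > 1 else 500.0
        config = TrialConfig(
            ioi_nominal=ioi,
            alpha=float(frame["alpha"].iloc[0]),
            n_tones=max(len(records), 2),
            n_tappers=n_tappers,
        )
    return TrialData(config=config, seed=seed, records=tuple(records))


def trials_to_csv(trials: Sequence[TrialData]) -> pd.DataFrame:
    """Concatenate trials into one tidy table, trial_id = position."""
    frames = [to_csv(t, trial_id=i) for i, t in enumerate(trials)]
    return pd.concat(frames, ignore_index=True)
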