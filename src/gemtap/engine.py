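"""Adaptive metronome timing engine.

The metronome emits tones separated nominally by the inter-onset interval
(IOI).  After each tone, taps arriving inside the attribution window
(± half an IOI around the tone) are ascribed to that tone; once the window
closes, the next tone is scheduled at

    t[n+1] = t[n] + IOI + alpha * mean(async[n])

where ``async`` is tap time minus tone time for each tapper (a missed tap
contributes 0 to the adaptation) and ``alpha`` is the adaptivity fraction.
With ``alpha = 0`` the metronome is an ordinary fixed metronome; with a
group of I tappers the mean asynchrony of the group drives the adjustment.
The first two inter-tone intervals are always exactly the nominal IOI: they
establish the tempo, and tappers are instructed to join at the third tone.

All times are real-valued milliseconds inside the engine; rounding to
integer ms happens only when records are serialized (see
:mod:`gemtap.packet`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

log = logging.getLogger("gemtap.engine")

#: Sentinel for a window with no registered tap.  ``None`` keeps missing
#: distinguishable from a true zero asynchrony; the binary packet format
#: maps it to an out-of-range int16 sentinel instead.
MISSING = None

#: Tone index at which adaptation starts: tappers join at the third tone
#: (index 2), so the first adapted interval is the one leading to tone 3.
ADAPTATION_START = 2

FEEDBACK_CONDITIONS = ("none", "self", "all")


class ConfigError(ValueError):
    """Raised for invalid trial or experiment configuration."""


@dataclass(frozen=True)
class TrialConfig:
    """Static parameters of one round of tapping.

    Parameters
    ----------
    ioi_nominal : float
        Nominal inter-onset interval in ms (default 500, i.e. 120 bpm).
    alpha : float
        Adaptivity fraction: proportion of the current (mean) asynchrony
        added to the next interval.  0 = non-adaptive control.
    n_tones : int
        Number of metronome tones in the trial (>= 2; the first two set
        the tempo).
    n_tappers : int
        Group size I (1-4; the packet format carries four tap slots).
    feedback_condition : str
        Auditory feedback tag, one of ``none``/``self``/``all``.  Metadata
        only: the engine does not model audition.
    start_time : float
        Time of the first tone in ms.
    """

    ioi_nominal: float = 500.0
    alpha: float = 0.0
    n_tones: int = 25
    n_tappers: int = 1
    feedback_condition: str = "none"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.ioi_nominal > 0:
            raise ConfigError(f"ioi_nominal must be positive, got {self.ioi_nominal}")
        if self.n_tones < 2:
            raise ConfigError(f"n_tones must be >= 2, got {self.n_tones}")
        if not 1 <= self.n_tappers <= 4:
            raise ConfigError(f"n_tappers must be in 1..4, got {self.n_tappers}")
        if self.alpha < 0:
            raise ConfigError(f"alpha must be non-negative, got {self.alpha}")
        if self.feedback_condition not in FEEDBACK_CONDITIONS:
            raise ConfigError(
                f"feedback_condition must be one of {FEEDBACK_CONDITIONS}, "
                f"got {self.feedback_condition!r}"
            )


@dataclass(frozen=True)
class WindowRecord:
    """One metronome tone plus each tapper's tap relative to it.

    ``tap_rel[i]`` is tapper *i*'s tap time minus the tone time (ms), or
    :data:`MISSING` if no tap was registered in this window.
    """

    tone_index: int
    tone_time: float
    tap_rel: tuple[Optional[float], ...]


@dataclass
class MetronomeState:
    """Mutable scheduling state: the tone just emitted and the history."""

    tone_index: int
    tone_time: float
    schedule: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class TrialData:
    """A completed trial: config, seed provenance and the window records."""

    config: TrialConfig
    seed: Optional[tuple] = None
    records: tuple[WindowRecord, ...] = ()

    @property
    def tone_times(self) -> list[float]:
        return [r.tone_time for r in self.records]

    @property
    def miss_counts(self) -> list[int]:
        """Per-tapper count of windows with no registered tap."""
        counts = [0] * self.config.n_tappers
        for rec in self.records:
            for i, rel in enumerate(rec.tap_rel):
                if rel is MISSING:
                    counts[i] += 1
        return counts


def attribution_window(tone_time: float, ioi_nominal: float) -> tuple[float, float]:
    """Half-open interval ``[lo, hi)`` of tap times ascribed to a tone.

    Spans half an IOI on either side of the tone; e.g. with a 500 ms IOI,
    taps from 250 ms before to (not including) 250 ms after the tone belong
    to it.  The right-open convention makes boundary assignment
    unambiguous between consecutive windows.
    """
    if not ioi_nominal > 0:
        raise ConfigError(f"ioi_nominal must be positive, got {ioi_nominal}")
    half = ioi_nominal / 2.0
    return (tone_time - half, tone_time + half)


def window_asynchronies(record: WindowRecord) -> list[float]:
    """Per-tapper asynchronies used for metronome adaptation.

    Missing taps contribute 0, so a fully missed window leaves the tempo at
    the default IOI.  Metrics treat misses differently (they exclude them);
    the :class:`WindowRecord` keeps the distinction by storing
    :data:`MISSING` rather than zero.
    """
    return [0.0 if rel is MISSING else float(rel) for rel in record.tap_rel]


def next_tone_time(
    state: MetronomeState, asyncs: Sequence[float], cfg: TrialConfig
) -> float:
    """Time of the next tone given the current window's asynchronies.

    For a single tapper the adjustment is ``alpha * async``; for a group it
    is ``alpha`` times the mean asynchrony, which reduces to the
    single-tapper rule when I = 1.  No adaptation is applied before the
    third tone (the tempo-establishing interval).
    """
    if len(asyncs) != cfg.n_tappers:
        raise ValueError(
            f"expected {cfg.n_tappers} asynchronies, got {len(asyncs)}"
        )
    if state.tone_index < ADAPTATION_START:
        return state.tone_time + cfg.ioi_nominal
    adjustment = cfg.alpha * (sum(asyncs) / len(asyncs))
    return state.tone_time + cfg.ioi_nominal + adjustment


TapSource = Callable[[int, float], Sequence[Optional[float]]]


def run_trial_engine(
    cfg: TrialConfig,
    tap_source: TapSource,
    seed: Optional[tuple] = None,
) -> TrialData:
    """Run the window-by-window metronome loop against a tap source.

    ``tap_source(tone_index, tone_time)`` returns one absolute tap time (ms)
    or :data:`MISSING` per tapper for the window around that tone.  Taps
    falling outside the attribution window are dropped with a warning and
    recorded as missing, mirroring hardware that only registers taps within
    the current window.  Tone n+1's time is computed only from window n's
    asynchronies, so the engine is deterministic given the tap source.
    """
    state = MetronomeState(tone_index=0, tone_time=cfg.start_time)
    records: list[WindowRecord] = []
    for n in range(cfg.n_tones):
        state.tone_index = n
        state.schedule.append(state.tone_time)
        taps = tap_source(n, state.tone_time)
        if len(taps) != cfg.n_tappers:
            raise ValueError(
                f"tap_source returned {len(taps)} taps for {cfg.n_tappers} tappers"
            )
        lo, hi = attribution_window(state.tone_time, cfg.ioi_nominal)
        rel: list[Optional[float]] = []
        for i, tap in enumerate(taps):
            if tap is MISSING:
                rel.append(MISSING)
            elif lo <= tap < hi:
                rel.append(float(tap) - state.tone_time)
            else:
                log.warning(
                    "tap at %.3f ms from tapper %d outside window [%.3f, %.3f) "
                    "of tone %d; dropped",
                    tap, i, lo, hi, n,
                )
                rel.append(MISSING)
        record = WindowRecord(tone_index=n, tone_time=state.tone_time, tap_rel=tuple(rel))
        records.append(record)
        upcoming = next_tone_time(state, window_asynchronies(record), cfg)
        if upcoming <= hi:
            # possible at extreme alpha with a very early group asynchrony;
            # allowed rather than clamped, but worth surfacing
            log.warning(
                "tone %d scheduled at %.3f ms, at or before window close %.3f ms",
                n + 1, upcoming, hi,
            )
        state.tone_time = upcoming
    return TrialData(config=cfg, seed=seed, records=tuple(records))


def replay_trial(trial: TrialData) -> TrialData:
    """Re-run the engine feeding back a trial's own recorded taps.

    Reconstructs absolute tap times as ``tone_time + tap_rel`` and replays
    them through :func:`run_trial_engine`; the regenerated tone schedule is
    identical to the original, which is the engine's determinism contract.
    """
    by_index = {r.tone_index: r for r in trial.records}

    def source(n: int, tone_time: float) -> Sequence[Optional[float]]:
        rec = by_index[n]
        return [
            MISSING if rel is MISSING else rec.tone_time + rel
            for rel in rec.tap_rel
        ]

    return run_trial_engine(trial.config, source, seed=trial.seed)
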