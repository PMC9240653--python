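"""Stochastic virtual tappers.

Each virtual tapper is a linear phase corrector on top of a two-level
timekeeper/motor noise generator in the Wing-Kristofferson tradition: a
central timekeeper produces intervals perturbed by white noise T (SD
``sigma_timekeeper``), each tap is realized with an independent motor delay
M (SD ``sigma_motor``), and the tapper shifts its next planned tap by a
fraction ``beta`` of its last asynchrony to the metronome:

    tap[k+1] = tap[k] + IOI - beta * async[k] + T[k] + (M[k+1] - M[k])

``beta`` plays the role for the tapper that ``alpha`` plays for the
metronome, so a tapper coupled to the adaptive metronome follows the
asynchrony recursion

    async[k+1] = phi * async[k] + T[k] + M[k+1] - M[k],   phi = 1 - alpha - beta

an AR(1) driven by ARMA-type noise, whose stationary SD has the closed form
implemented in :func:`stationary_async_sd` and used as the analytic oracle
for validating long simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

PERIOD_MODES = ("nominal", "tracking")


@dataclass(frozen=True)
class TapperParams:
    """Parameters of one virtual tapper.

    Parameters
    ----------
    beta : float
        Phase-correction gain: fraction of the last asynchrony subtracted
        from the next planned interval.  0 = no correction; 1 = full
        one-step correction.  Typically 0-1.
    sigma_timekeeper : float
        SD of the central timekeeper interval noise, ms.
    sigma_motor : float
        SD of the peripheral motor delay, ms.
    p_miss : float
        Per-window probability that a planned tap fails to register.
    initial_async : float
        Asynchrony (ms) of the tapper's very first tap, before noise; 0
        means the first tap is aimed exactly at the expected tone time.
    period_mode : str
        ``nominal`` (default): the timekeeper always targets the nominal
        IOI.  ``tracking``: it targets the last observed inter-tone
        interval instead, following the metronome's tempo adjustments.
        The closed-form stationary oracle applies to ``nominal`` only.
    """

    beta: float = 0.2
    sigma_timekeeper: float = 10.0
    sigma_motor: float = 10.0
    p_miss: float = 0.0
    initial_async: float = 0.0
    period_mode: str = "nominal"

    def __post_init__(self) -> None:
        if self.sigma_timekeeper < 0 or self.sigma_motor < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.p_miss < 1:
            raise ValueError(f"p_miss must be in [0, 1), got {self.p_miss}")
        if self.period_mode not in PERIOD_MODES:
            raise ValueError(
                f"period_mode must be one of {PERIOD_MODES}, got {self.period_mode!r}"
            )


@dataclass
class TapperState:
    """Evolving state of one tapper: its own seeded RNG stream, the last
    planned (possibly covert) tap time and the last motor-delay sample."""

    rng: np.random.Generator
    prev_tap: float
    prev_motor: float = 0.0


def plan_next_tap(
    state: TapperState,
    params: TapperParams,
    own_async: float,
    ioi_target: float,
) -> tuple[float, bool]:
    """Advance the tapper one cycle and return ``(tap_time, missed)``.

    ``own_async`` is the tapper's asynchrony to the most recent tone.  When
    the previous tap was missed the caller passes the covert asynchrony of
    the planned-but-unregistered tap: the tapper keeps its internal cycle
    going and corrects from it regardless of registration.

    The RNG stream is consumed in a fixed order (timekeeper noise, motor
    delay, miss draw), so sequences are reproducible given the seed and
    unchanged by parameter values.
    """
    t_noise = state.rng.normal(0.0, params.sigma_timekeeper)
    motor = state.rng.normal(0.0, params.sigma_motor)
    missed = bool(state.rng.random() < params.p_miss)
    tap = (
        state.prev_tap
        + ioi_target
        - params.beta * own_async
        + t_noise
        + (motor - state.prev_motor)
    )
    state.prev_tap = tap
    state.prev_motor = motor
    return tap, missed


def initial_tap(
    state: TapperState, params: TapperParams, expected_tone_time: float
) -> tuple[float, bool]:
    """The tapper's first tap, aimed at the expected third tone.

    Set to the expected tone time plus ``initial_async`` plus a motor-delay
    sample; the timekeeper contributes from the next cycle on.
    """
    motor = state.rng.normal(0.0, params.sigma_motor)
    missed = bool(state.rng.random() < params.p_miss)
    tap = expected_tone_time + params.initial_async + motor
    state.prev_tap = tap
    state.prev_motor = motor
    return tap, missed


def stationary_async_sd(
    alpha: float,
    beta: float,
    sigma_timekeeper: float,
    sigma_motor: float,
) -> float:
    """Closed-form stationary SD of a single tapper's asynchrony (ms).

    For a nominal-period tapper coupled to the adaptive metronome the
    asynchrony follows ``a[k+1] = phi*a[k] + T[k] + M[k+1] - M[k]`` with
    ``phi = 1 - alpha - beta``.  Because ``a[k]`` carries ``M[k]`` with
    coefficient +1, ``Cov(a[k], M[k]) = sigma_M^2``, giving the stationary
    variance

        Var(a) = (sigma_T^2 + 2*(1 - phi)*sigma_M^2) / (1 - phi^2)

    Requires ``|phi| < 1``; outside that region the recursion diverges and
    a ValueError is raised.  This expression is an analytic oracle: the
    simulator is validated against it by long-run Monte Carlo.
    """
    phi = 1.0 - alpha - beta
    if not abs(phi) < 1.0:
        raise ValueError(
            f"non-stationary parameters: |1 - alpha - beta| = {abs(phi)} >= 1"
        )
    var_t = sigma_timekeeper**2
    var_m = sigma_motor**2
    variance = (var_t + 2.0 * (1.0 - phi) * var_m) / (1.0 - phi**2)
    return math.sqrt(variance)


def make_state(
    params: TapperParams,
    seed: Optional[int | np.random.SeedSequence] = None,
) -> TapperState:
    """Fresh tapper state with an independent seeded RNG stream."""
    rng = np.random.default_rng(seed)
    return TapperState(rng=rng, prev_tap=float("nan"))
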