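"""Coupled tapper-metronome simulation and experiment designs.

``run_trial`` wires a set of virtual tappers to the adaptive metronome
engine window by window: each tapper's tap for window n was planned after
window n-1, the engine schedules tone n+1 from window n's registered
asynchronies, and each tapper then plans its next tap from its own (covert,
if unregistered) asynchrony.  ``run_experiment`` runs a full design --
rounds x adaptivity levels in seeded randomized order -- and the presets
encode the study designs this package emulates: single tappers at five
adaptivity levels (10 rounds of 25 tones each) and groups of four at four
levels (6 rounds of ~30 s each), all at a 500 ms IOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from gemtap.engine import (
    ADAPTATION_START,
    MISSING,
    TrialConfig,
    TrialData,
    run_trial_engine,
)
from gemtap.tappers import (
    TapperParams,
    initial_tap,
    make_state,
    plan_next_tap,
)


@dataclass(frozen=True)
class ExperimentDesign:
    """A full experiment: adaptivity levels x rounds, one tapper set.

    ``alphas`` are the adaptivity levels, each run ``rounds`` times; the
    trial order is a seeded permutation of the full factorial list when
    ``randomize`` is on.  ``practice_rounds`` non-adaptive rounds are
    prepended and tagged so analysis can exclude them.
    """

    alphas: tuple[float, ...]
    rounds: int
    config: TrialConfig
    tappers: tuple[TapperParams, ...]
    master_seed: int = 0
    randomize: bool = True
    practice_rounds: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        if len(set(self.alphas)) != len(self.alphas):
            raise ValueError(f"alpha levels must be distinct, got {self.alphas}")
        if any(a < 0 for a in self.alphas):
            raise ValueError(f"alpha levels must be non-negative, got {self.alphas}")
        if len(self.tappers) != self.config.n_tappers:
            raise ValueError(
                f"{len(self.tappers)} tapper parameter sets for "
                f"{self.config.n_tappers} tappers"
            )

    @property
    def n_trials(self) -> int:
        return len(self.alphas) * self.rounds


def run_trial(
    cfg: TrialConfig,
    tappers: Sequence[TapperParams],
    seed: int | tuple | np.random.SeedSequence,
) -> TrialData:
    """Simulate one round of tapping; bit-reproducible from the seed.

    Each tapper gets an independent RNG stream spawned from the trial seed.
    Tappers sit out the first two (tempo-establishing) tones, aim their
    first tap at the expected third tone, and from then on phase-correct
    from their own asynchrony each window.  A planned tap that falls
    outside the attribution window, or is flagged missed, is recorded as
    missing; the tapper still continues from its covert asynchrony.
    """
    if len(tappers) != cfg.n_tappers:
        raise ValueError(
            f"{len(tappers)} tapper parameter sets for {cfg.n_tappers} tappers"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    states = [make_state(p, child) for p, child in zip(tappers, ss.spawn(cfg.n_tappers))]
    # planned absolute tap time and registered flag for the current window
    planned: list[Optional[float]] = [None] * cfg.n_tappers
    registered: list[bool] = [False] * cfg.n_tappers
    prev_tone: Optional[float] = None

    def source(n: int, tone_time: float) -> list[Optional[float]]:
        nonlocal prev_tone
        if n < ADAPTATION_START:
            prev_tone = tone_time
            return [MISSING] * cfg.n_tappers
        if n == ADAPTATION_START:
            expected = tone_time  # first two intervals are exactly the IOI
            for i, params in enumerate(tappers):
                tap, missed = initial_tap(states[i], params, expected)
                planned[i] = tap
                registered[i] = not missed
        taps = [planned[i] if registered[i] else MISSING for i in range(cfg.n_tappers)]
        # plan the next window's taps from this window's covert asynchronies
        for i, params in enumerate(tappers):
            own_async = planned[i] - tone_time
            if params.period_mode == "tracking" and prev_tone is not None:
                ioi_target = tone_time - prev_tone
            else:
                ioi_target = cfg.ioi_nominal
            tap, missed = plan_next_tap(states[i], params, own_async, ioi_target)
            planned[i] = tap
            registered[i] = not missed
        prev_tone = tone_time
        return taps

    seed_tuple = tuple(ss.entropy) if isinstance(ss.entropy, (list, tuple)) else (ss.entropy,)
    return run_trial_engine(cfg, source, seed=seed_tuple + ss.spawn_key)


def trial_seed(master_seed: int, trial_index: int) -> np.random.SeedSequence:
    """Per-trial seed derived from the master seed and trial index."""
    return np.random.SeedSequence((master_seed, trial_index))


def run_experiment(design: ExperimentDesign) -> list[TrialData]:
    """Run every trial of a design; returns practice trials first (alpha 0,
    tagged by position: the first ``practice_rounds`` entries), then the
    rounds x levels trials in seeded-permuted (or listed) order."""
    factorial = [a for a in design.alphas for _ in range(design.rounds)]
    if design.randomize:
        order_rng = np.random.default_rng(
            np.random.SeedSequence((design.master_seed, len(factorial)))
        )
        factorial = [factorial[i] for i in order_rng.permutation(len(factorial))]
    trials: list[TrialData] = []
    index = 0
    for _ in range(design.practice_rounds):
        cfg = replace(design.config, alpha=0.0)
        trials.append(run_trial(cfg, design.tappers, trial_seed(design.master_seed, index)))
        index += 1
    for alpha in factorial:
        cfg = replace(design.config, alpha=alpha)
        trials.append(run_trial(cfg, design.tappers, trial_seed(design.master_seed, index)))
        index += 1
    return trials


#: Default virtual-tapper parameters: moderate phase correction with equal
#: timekeeper and motor noise of 10 ms each, a plausible regime for
#: practiced tapping at a 500 ms period, and a small miss rate.
DEFAULT_TAPPER = TapperParams(beta=0.2, sigma_timekeeper=10.0, sigma_motor=10.0, p_miss=0.02)

_SINGLE_ALPHAS = (0.0, 0.25, 0.5, 0.75, 1.0)
_GROUP_ALPHAS = (0.0, 0.35, 0.7, 1.0)

#: Preset designs.  Single-tapper presets: 10 rounds at each of five
#: adaptivity levels, 25 tones per round at a 500 ms IOI (~13 s).  Group
#: presets: four tappers, 6 rounds at each of four levels; 60 tones per
#: round (~30 s at 500 ms).  Feedback tags are metadata carried through to
#: outputs; tapper parameters are identical across presets by default.
_PRESETS = {
    "exp1": dict(alphas=_SINGLE_ALPHAS, rounds=10, n_tones=25, n_tappers=1, feedback="none"),
    "exp2": dict(alphas=_SINGLE_ALPHAS, rounds=10, n_tones=25, n_tappers=1, feedback="self"),
    "exp3": dict(alphas=_GROUP_ALPHAS, rounds=6, n_tones=60, n_tappers=4, feedback="none"),
    "exp4": dict(alphas=_GROUP_ALPHAS, rounds=6, n_tones=60, n_tappers=4, feedback="self"),
    "exp5": dict(alphas=_GROUP_ALPHAS, rounds=6, n_tones=60, n_tappers=4, feedback="all"),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(
    name: str,
    master_seed: int = 0,
    tappers: Optional[Sequence[TapperParams]] = None,
    rounds: Optional[int] = None,
    n_tones: Optional[int] = None,
    randomize: bool = True,
    practice_rounds: int = 0,
) -> ExperimentDesign:
    """Build a preset design, optionally overriding rounds/tones/tappers."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    p = _PRESETS[name]
    cfg = TrialConfig(
        ioi_nominal=500.0,
        alpha=0.0,
        n_tones=n_tones if n_tones is not None else p["n_tones"],
        n_tappers=p["n_tappers"],
        feedback_condition=p["feedback"],
    )
    if tappers is None:
        tappers = tuple(DEFAULT_TAPPER for _ in range(p["n_tappers"]))
    return ExperimentDesign(
        alphas=p["alphas"],
        rounds=rounds if rounds is not None else p["rounds"],
        config=cfg,
        tappers=tuple(tappers),
        master_seed=master_seed,
        randomize=randomize,
        practice_rounds=practice_rounds,
        name=name,
    )
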