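"""Trial-level synchrony metrics.

The primary stability measure is the standard deviation of tap-tone
asynchronies over a trial's windows, computed for each tapper, for the
group-mean asynchrony series, and for the cross-tapper spread:

* individual asynchrony: tap minus tone per window and tapper;
* group asynchrony: per-window mean over tappers with an observed tap;
* SD asynchrony difference: an individual's SD asynchrony minus the
  group's (negative = more stable than the group-average series);
* within-window SD: the SD across tappers inside one window, and its SD
  over windows ("SD of SD"), indexing how tightly members track each
  other independent of the metronome;
* tapper rank per trial: 1 = smallest absolute SD asynchrony difference;
* adaptivity benefit: mean SD asynchrony at a baseline adaptivity level
  minus at the optimal level (positive = the adaptive metronome helped).

All SDs are population SDs (denominator N) to match the defining formulas;
a sample-SD variant is available via ``ddof=1``.  Windows where a tapper
has no registered tap are excluded from that tapper's series rather than
zero-filled -- zero-filling would bias SDs toward zero -- in contrast to
the engine, which substitutes zero for adaptation purposes.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from gemtap.engine import MISSING, TrialData

log = logging.getLogger("gemtap.metrics")


def sd_async(series: Sequence[float], ddof: int = 0) -> float:
    """SD of an asynchrony series; population form (ddof=0) by default."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        return float("nan")
    if arr.size <= ddof:
        return float("nan")
    return float(np.std(arr, ddof=ddof))


def individual_asyncs(trial: TrialData) -> list[dict[int, float]]:
    """Per-tapper asynchrony series as ``{window_index: async_ms}`` maps.

    Keeping window indices (rather than bare lists) preserves alignment
    after missed windows are excluded.
    """
    out: list[dict[int, float]] = [dict() for _ in range(trial.config.n_tappers)]
    for rec in trial.records:
        for i, rel in enumerate(rec.tap_rel):
            if rel is not MISSING:
                out[i][rec.tone_index] = float(rel)
    return out


def group_asyncs(trial: TrialData) -> dict[int, float]:
    """Per-window mean asynchrony over tappers with an observed tap.

    Windows in which nobody tapped are excluded (and logged); for a single
    tapper the result is identical to the individual series.
    """
    out: dict[int, float] = {}
    for rec in trial.records:
        observed = [float(rel) for rel in rec.tap_rel if rel is not MISSING]
        if observed:
            out[rec.tone_index] = sum(observed) / len(observed)
        else:
            log.debug("window %d has no observed taps; excluded", rec.tone_index)
    return out


def sd_async_difference(trial: TrialData, ddof: int = 0) -> list[float]:
    """Per-tapper SD asynchrony minus group SD asynchrony (ms).

    Each series is computed over its own retained windows.  Identically
    zero for a single tapper.
    """
    group_sd = sd_async(list(group_asyncs(trial).values()), ddof=ddof)
    return [
        sd_async(list(series.values()), ddof=ddof) - group_sd
        for series in individual_asyncs(trial)
    ]


def within_window_sd(trial: TrialData, ddof: int = 0) -> dict[int, float]:
    """Per-window SD of asynchronies across tappers (observed taps only)."""
    out: dict[int, float] = {}
    for rec in trial.records:
        observed = [float(rel) for rel in rec.tap_rel if rel is not MISSING]
        if len(observed) > ddof:
            out[rec.tone_index] = sd_async(observed, ddof=ddof)
    return out


def sd_of_sd(trial: TrialData, ddof: int = 0) -> float:
    """SD over windows of the within-window cross-tapper SD (ms)."""
    return sd_async(list(within_window_sd(trial, ddof=ddof).values()), ddof=ddof)


def rank_tappers(sd_diffs: Sequence[float]) -> list[int]:
    """Rank tappers by absolute SD asynchrony difference, 1 = smallest.

    For example, difference values ``[10.9, -7.8, 6.5, 15.4]`` rank
    ``[3, 2, 1, 4]``.  Ties are broken by tapper index for determinism.
    """
    order = sorted(range(len(sd_diffs)), key=lambda i: (abs(sd_diffs[i]), i))
    ranks = [0] * len(sd_diffs)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def trial_metrics(trial: TrialData, trial_id: int | str = 0, ddof: int = 0) -> dict:
    """All per-trial metrics as one flat record (a metric-table row)."""
    indiv = individual_asyncs(trial)
    group = group_asyncs(trial)
    diffs = sd_async_difference(trial, ddof=ddof)
    row: dict = {
        "trial_id": trial_id,
        "alpha": trial.config.alpha,
        "n_windows": len(trial.records),
        "group_sd_async": sd_async(list(group.values()), ddof=ddof),
        "group_mean_async": float(np.mean(list(group.values()))) if group else float("nan"),
        "sd_of_sd": sd_of_sd(trial, ddof=ddof),
    }
    ranks = rank_tappers(diffs)
    for i in range(trial.config.n_tappers):
        series = list(indiv[i].values())
        row[f"sd_async_{i}"] = sd_async(series, ddof=ddof)
        row[f"sd_async_diff_{i}"] = diffs[i]
        row[f"rank_{i}"] = ranks[i]
        row[f"n_missed_{i}"] = len(trial.records) - len(series)
    return row


def metric_table(trials: Sequence[TrialData], ddof: int = 0) -> pd.DataFrame:
    """Per-trial metric table, one row per trial."""
    return pd.DataFrame(
        [trial_metrics(t, trial_id=i, ddof=ddof) for i, t in enumerate(trials)]
    )


def adaptivity_benefit(
    table: pd.DataFrame,
    baseline_alpha: float = 0.0,
    optimal_alpha: float = 0.35,
    column: str = "group_sd_async",
) -> float:
    """Mean SD asynchrony at baseline minus at the optimal adaptivity level.

    A positive value corresponds to improved tapping synchrony under the
    adaptive metronome.
    """
    def _mean_at(alpha: float) -> float:
        mask = np.isclose(table["alpha"].to_numpy(dtype=float), alpha)
        if not mask.any():
            raise ValueError(f"no trials at alpha = {alpha}")
        return float(table.loc[mask, column].mean())

    return _mean_at(baseline_alpha) - _mean_at(optimal_alpha)


def summarize_by_alpha(table: pd.DataFrame, column: str = "group_sd_async") -> pd.DataFrame:
    """Mean and SD of a metric per adaptivity level, one row per level."""
    grouped = table.groupby("alpha")[column]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out.columns = ["alpha", f"{column}_mean", f"{column}_sd", "n_trials"]
    return out
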