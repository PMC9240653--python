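"""Missed-tap exclusion rules.

Tapping datasets are cleaned in a fixed order before analysis:

single-tapper datasets
    (1) a participant who missed 30% *or more* of the required taps
    overall is dropped; (2) of the remaining data, any round missing
    *more than* 30% of its taps is discarded; (3) a participant left with
    no observations in some adaptivity condition is dropped.

group datasets
    (1) a group in which 30% or more of the required taps were missed,
    pooled across the whole group, is dropped; (2) remaining rounds
    missing more than 30% of their pooled taps are discarded.

The asymmetry between the participant-level inclusive threshold (>= 30%)
and the round-level strict one (> 30%) is deliberate and preserved.  By
default every metronome window counts toward the required taps, including
the two tempo-establishing lead-in tones that nobody taps to;
``exclude_lead_in=True`` removes them from the accounting.

Cleaning operates on the tidy window-level table (one row per window per
tapper) and is idempotent: cleaning an already-clean dataset is a no-op.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from gemtap.engine import ADAPTATION_START

DEFAULT_MISS_THRESHOLD = 0.30


@dataclass
class CleaningReport:
    """What was dropped and why; ``dropped + retained = input``."""

    n_input_rows: int = 0
    n_retained_rows: int = 0
    dropped_participants: list = field(default_factory=list)
    dropped_groups: list = field(default_factory=list)
    dropped_runs: list = field(default_factory=list)
    reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_retained_rows": self.n_retained_rows,
            "n_dropped_rows": self.n_input_rows - self.n_retained_rows,
            "dropped_participants": self.dropped_participants,
            "dropped_groups": self.dropped_groups,
            "dropped_runs": [list(r) for r in self.dropped_runs],
            "reasons": self.reasons,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))


def _counting_view(df: pd.DataFrame, exclude_lead_in: bool) -> pd.DataFrame:
    if exclude_lead_in and "tone_index" in df.columns:
        return df[df["tone_index"] >= ADAPTATION_START]
    return df


def clean_single(
    df: pd.DataFrame,
    miss_threshold: float = DEFAULT_MISS_THRESHOLD,
    exclude_lead_in: bool = False,
    participant_col: str = "participant_id",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the single-tapper exclusion rules to a tidy window table.

    Requires columns ``participant_id`` (or ``participant_col``),
    ``trial_id``, ``alpha`` and ``missed``.  Returns the retained rows and
    a report of everything dropped.
    """
    report = CleaningReport(n_input_rows=len(df))
    if df.empty:
        return df, report
    for col in (participant_col, "trial_id", "alpha", "missed"):
        if col not in df.columns:
            raise ValueError(f"cleaning requires column {col!r}")

    counted = _counting_view(df, exclude_lead_in)
    all_alphas = set(df["alpha"].unique())

    # (1) participant overall miss fraction >= threshold
    frac = counted.groupby(participant_col)["missed"].mean()
    bad_participants = set(frac[frac >= miss_threshold].index)
    for p in sorted(bad_participants, key=str):
        report.dropped_participants.append(p)
        report.reasons[str(p)] = (
            f"missed {frac[p]:.1%} of required taps (>= {miss_threshold:.0%})"
        )
    kept = df[~df[participant_col].isin(bad_participants)]
    counted = _counting_view(kept, exclude_lead_in)

    # (2) run miss fraction > threshold
    if not kept.empty:
        run_frac = counted.groupby([participant_col, "trial_id"])["missed"].mean()
        bad_runs = set(run_frac[run_frac > miss_threshold].index)
        for key in sorted(bad_runs, key=str):
            report.dropped_runs.append(key)
            report.reasons[str(key)] = (
                f"round missed {run_frac[key]:.1%} of taps (> {miss_threshold:.0%})"
            )
        if bad_runs:
            index = pd.MultiIndex.from_frame(kept[[participant_col, "trial_id"]])
            kept = kept[~index.isin(bad_runs)]

    # (3) participants with an empty adaptivity-condition cell
    if not kept.empty:
        for p, sub in kept.groupby(participant_col):
            lacking = all_alphas - set(sub["alpha"].unique())
            if lacking:
                report.dropped_participants.append(p)
                report.reasons[str(p)] = (
                    f"no observations left in condition(s) {sorted(lacking)}"
                )
        dropped = set(report.dropped_participants)
        kept = kept[~kept[participant_col].isin(dropped)]

    report.n_retained_rows = len(kept)
    return kept, report


def clean_group(
    df: pd.DataFrame,
    miss_threshold: float = DEFAULT_MISS_THRESHOLD,
    exclude_lead_in: bool = False,
    group_col: str = "group_id",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the group exclusion rules: pooled group-level threshold
    (inclusive), then the round-level rule on pooled round misses."""
    report = CleaningReport(n_input_rows=len(df))
    if df.empty:
        return df, report
    for col in (group_col, "trial_id", "alpha", "missed"):
        if col not in df.columns:
            raise ValueError(f"cleaning requires column {col!r}")

    counted = _counting_view(df, exclude_lead_in)

    # (1) pooled group miss fraction >= threshold
    frac = counted.groupby(group_col)["missed"].mean()
    bad_groups = set(frac[frac >= miss_threshold].index)
    for g in sorted(bad_groups, key=str):
        report.dropped_groups.append(g)
        report.reasons[str(g)] = (
            f"group missed {frac[g]:.1%} of required taps (>= {miss_threshold:.0%})"
        )
    kept = df[~df[group_col].isin(bad_groups)]
    counted = _counting_view(kept, exclude_lead_in)

    # (2) pooled round miss fraction > threshold
    if not kept.empty:
        run_frac = counted.groupby([group_col, "trial_id"])["missed"].mean()
        bad_runs = set(run_frac[run_frac > miss_threshold].index)
        for key in sorted(bad_runs, key=str):
            report.dropped_runs.append(key)
            report.reasons[str(key)] = (
                f"round missed {run_frac[key]:.1%} of pooled taps (> {miss_threshold:.0%})"
            )
        if bad_runs:
            index = pd.MultiIndex.from_frame(kept[[group_col, "trial_id"]])
            kept = kept[~index.isin(bad_runs)]

    report.n_retained_rows = len(kept)
    return kept, report
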