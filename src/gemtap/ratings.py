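"""Post-trial rating normalization and enjoyment scoring.

After each round, participants rate on 5-point scales how much they felt
in the groove, in synchrony with the metronome (and, in groups, with the
other players), how much they liked the task, how difficult it was, and
how much influence they felt over the pulse.  Ratings are z-scored within
each participant and scale across that participant's trials; in group
designs the z-scores are then averaged across the group per trial.

A single "enjoyment" latent factor summarizes the scales: groove,
synchrony and liking load positively, difficulty negatively, and felt
influence (loading < 0.3) is excluded.  Scores here are loading-weighted
sums of the z-scored items -- a documented approximation to
regression-method factor scores, which would require the fitted factor
model; user-supplied weights are accepted.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import pandas as pd

log = logging.getLogger("gemtap.ratings")

RATING_ITEMS = (
    "groove",
    "synchrony_metronome",
    "synchrony_group",
    "liking",
    "difficulty",
    "influence",
)

#: Enjoyment-factor loadings for single-tapper designs (groove, synchrony
#: with the metronome, liking, and negatively loaded difficulty; influence
#: is excluded by the < 0.3 rule).
SINGLE_LOADINGS: Mapping[str, float] = {
    "groove": 0.663,
    "synchrony_metronome": 0.836,
    "liking": 0.460,
    "difficulty": -0.772,
}

#: Loadings for group designs, where synchrony with the other players is
#: an additional, strongly loading item.
GROUP_LOADINGS: Mapping[str, float] = {
    "groove": 0.893,
    "synchrony_metronome": 0.937,
    "synchrony_group": 0.823,
    "liking": 0.517,
    "difficulty": -0.792,
}

REQUIRED_COLUMNS = ("trial_id", "participant_id", "item", "value")


def _validate(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"rating table requires column {col!r}")
    unknown = set(table["item"].unique()) - set(RATING_ITEMS)
    if unknown:
        log.warning("unrecognized rating items: %s", sorted(unknown))


def znormalize(table: pd.DataFrame, group_average: bool = False) -> pd.DataFrame:
    """Z-score ratings within each participant and scale.

    Input is long-form: ``trial_id, participant_id, item, value``.  The
    z-score uses the sample SD (N-1); a scale a participant rated
    identically on every trial has zero SD and maps to 0 with a warning.
    With ``group_average=True`` z-scores are additionally averaged across
    participants within each trial, yielding ``trial_id, item, z``.
    """
    _validate(table)
    out = table.copy()

    def _z(values: pd.Series) -> pd.Series:
        sd = values.std(ddof=1)
        if not sd > 0 or pd.isna(sd):
            log.warning("zero or undefined SD for a participant x scale; z set to 0")
            return pd.Series(0.0, index=values.index)
        return (values - values.mean()) / sd

    out["z"] = (
        out.groupby(["participant_id", "item"], group_keys=False)["value"].apply(_z)
    )
    if group_average:
        return out.groupby(["trial_id", "item"], as_index=False)["z"].mean()
    return out[["trial_id", "participant_id", "item", "z"]]


def enjoyment_score(
    z_table: pd.DataFrame,
    loadings: Optional[Mapping[str, float]] = None,
) -> pd.Series:
    """Loading-weighted enjoyment score per trial.

    ``z_table`` is the output of :func:`znormalize`: per-trial (group
    mode) or per-trial-and-participant z-scored items.  The score is the
    sum of ``loading * z`` over the loaded items; items without a loading
    (e.g. influence) are ignored.  Defaults to the single-design loadings
    when the table has no ``synchrony_group`` item, the group loadings
    otherwise.
    """
    items = set(z_table["item"].unique())
    if loadings is None:
        loadings = GROUP_LOADINGS if "synchrony_group" in items else SINGLE_LOADINGS
    absent = set(loadings) - items
    if absent:
        log.warning("loaded items missing from table: %s", sorted(absent))

    keys = ["trial_id", "participant_id"] if "participant_id" in z_table.columns else ["trial_id"]
    loaded = z_table[z_table["item"].isin(loadings)].copy()
    loaded["weighted"] = loaded["z"] * loaded["item"].map(loadings)
    score = loaded.groupby(keys)["weighted"].sum()
    score.name = "enjoyment"
    return score
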