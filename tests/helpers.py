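"""Shared builders for hand-made trials used across test modules."""

from gemtap.engine import MISSING, TrialConfig, TrialData, WindowRecord


def build_trial(tap_rel_by_window, ioi=500.0, alpha=0.0, start=0.0):
    """Hand-build a TrialData from per-window tap_rel lists.

    Tone times are laid out at the nominal IOI; metrics only consume the
    relative tap times so this is sufficient for metric tests.
    """
    n_tappers = len(tap_rel_by_window[0])
    records = tuple(
        WindowRecord(tone_index=k, tone_time=start + k * ioi, tap_rel=tuple(rels))
        for k, rels in enumerate(tap_rel_by_window)
    )
    cfg = TrialConfig(
        ioi_nominal=ioi,
        alpha=alpha,
        n_tones=max(len(records), 2),
        n_tappers=n_tappers,
    )
    return TrialData(config=cfg, records=records)


def random_trial(rng, n_windows=12, n_tappers=4, miss_prob=0.15, ioi=500.0):
    """Random small trial with scattered missing taps, for oracle checks."""
    windows = []
    for _ in range(n_windows):
        rels = [
            MISSING if rng.random() < miss_prob else float(rng.uniform(-ioi / 2, ioi / 2 - 1))
            for _ in range(n_tappers)
        ]
        windows.append(rels)
    return build_trial(windows, ioi=ioi)
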