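"""Trial-aligned spike counting and the cross-session duplicate screen.

Counting uses half-open windows ``(start, end]`` relative to stimulus onset
so each spike belongs to at most one window: the 200-1000 ms response window
and the matched-length 1000-200 ms pre-onset background window.  The
resulting trial count matrix (one row per trial, paired response/background
counts) is the input to every statistical stage.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .types import COUNT_COLUMNS, CountWindows, SpikeTrain

logger = logging.getLogger(__name__)

#: Rate-difference threshold of the duplicate-cluster screen.
DUPLICATE_RATE_TOL = 0.5


def _window_counts(
    times: np.ndarray, onsets: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Spike counts in the half-open window ``(onset+w0, onset+w1]``."""
    lo = np.searchsorted(times, onsets + window[0], side="right")
    hi = np.searchsorted(times, onsets + window[1], side="right")
    return (hi - lo).astype(int)


def count_trials(
    train: SpikeTrain,
    trials: pd.DataFrame,
    windows: CountWindows | None = None,
) -> pd.DataFrame:
    """Build the trial count matrix of one neuron.

    Returns a DataFrame with columns ``neuron_id, area, trial_id, category,
    response_count, background_count``.  Raises if the response window of one
    trial overlaps the background window of the next (cannot happen under the
    3 s trial clock, but guards arbitrary trial tables).
    """
    if windows is None:
        windows = CountWindows()
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")

    onsets = trials["onset_s"].to_numpy(float)
    order = np.argsort(onsets)
    o = onsets[order]
    # Response window of trial i must end before background of trial i+1 begins.
    resp_end = o[:-1] + windows.response[1]
    bg_start = o[1:] + windows.background[0]
    bad = np.flatnonzero(resp_end > bg_start)
    if bad.size:
        i = int(bad[0])
        t1 = trials["trial_id"].to_numpy()[order][i]
        t2 = trials["trial_id"].to_numpy()[order][i + 1]
        raise ValueError(
            f"counting windows overlap between trials {t1} and {t2} "
            f"(onsets {o[i]:.3f} s and {o[i + 1]:.3f} s)"
        )

    times = train.spike_times_s
    return pd.DataFrame(
        {
            "neuron_id": train.neuron_id,
            "area": train.area,
            "trial_id": trials["trial_id"].to_numpy(),
            "category": trials["category"].to_numpy(),
            "response_count": _window_counts(times, onsets, windows.response),
            "background_count": _window_counts(times, onsets, windows.background),
        },
        columns=list(COUNT_COLUMNS),
    )


def screen_duplicates(trains: list[SpikeTrain]) -> pd.DataFrame:
    """Flag putative duplicate clusters recorded across sessions.

    For every pair of units on the same channel in different sessions, the
    pair is flagged as a likely duplicate when the average firing rates
    differ by less than 50% (relative to the larger rate) and the waveform
    peak signs are equal.  Pairs where both rates are zero are not flagged
    (the ratio is undefined) and are logged.

    Returns a DataFrame with one row per flagged pair:
    ``neuron_id_1, neuron_id_2, channel_id, rate_1, rate_2, rate_diff``.
    """
    rows = []
    by_channel: dict[str, list[SpikeTrain]] = {}
    for t in trains:
        by_channel.setdefault(t.channel_id, []).append(t)

    for channel_id, group in by_channel.items():
        for a, b in combinations(group, 2):
            if a.session_id == b.session_id:
                continue
            r1, r2 = a.mean_rate_hz, b.mean_rate_hz
            if max(r1, r2) == 0:
                logger.info(
                    "both rates zero for %s/%s on %s; not flagged",
                    a.neuron_id,
                    b.neuron_id,
                    channel_id,
                )
                continue
            diff = abs(r1 - r2) / max(r1, r2)
            if diff < DUPLICATE_RATE_TOL and a.waveform_peak_sign == b.waveform_peak_sign:
                rows.append(
                    {
                        "neuron_id_1": a.neuron_id,
                        "neuron_id_2": b.neuron_id,
                        "channel_id": channel_id,
                        "rate_1": r1,
                        "rate_2": r2,
                        "rate_diff": diff,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["neuron_id_1", "neuron_id_2", "channel_id", "rate_1", "rate_2", "rate_diff"],
    )
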