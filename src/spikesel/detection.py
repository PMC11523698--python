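"""Extracellular spike detection: bandpass filtering, two-sided threshold
crossing, and aligned 32-sample waveform extraction.

Detection follows the classic microwire pipeline: a 300-3000 Hz bandpass, a
two-sided threshold at 2.8 times the channel's standard deviation, and
waveforms extracted with the crossing aligned at the 9th of 32 samples
(1-based).  Clustering of the detected events into units is out of scope;
sorted unit labels are accepted as upstream input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import ALIGN_IDX, WAVEFORM_LEN, RawRecording

#: Default detection band (Hz) and threshold in channel standard deviations.
DEFAULT_BAND_HZ = (300.0, 3000.0)
DEFAULT_K_SD = 2.8
#: Post-detection dead time; the source procedure states none, but without a
#: lockout a single spike yields several consecutive crossings.
DEFAULT_LOCKOUT_S = 0.001


@dataclass
class EventSet:
    """Detected threshold crossings for one channel.

    ``events`` has one row per detection (``channel_id, event_time_s,
    sample_index, peak_sign``); ``waveforms`` is the matching
    ``(n_events, 32)`` array with the crossing at column 8 (the 9th sample,
    1-based).
    """

    events: pd.DataFrame
    waveforms: np.ndarray

    def __len__(self) -> int:
        return len(self.events)


def bandpass(
    record: RawRecording | np.ndarray,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    sampling_rate_hz: float | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of a raw trace.

    A 4th-order Butterworth applied forward-backward (``sosfiltfilt``), so
    event times are not shifted by filter group delay.  Output has the same
    length as the input.
    """
    if isinstance(record, RawRecording):
        x = record.samples
        fs = record.sampling_rate_hz
    else:
        x = np.asarray(record, float)
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for a bare array")
        fs = sampling_rate_hz
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_events(
    filtered: np.ndarray,
    sampling_rate_hz: float,
    k_sd: float = DEFAULT_K_SD,
    lockout_s: float = DEFAULT_LOCKOUT_S,
    channel_id: str = "ch0",
    robust_sd: bool = False,
) -> EventSet:
    """Two-sided threshold detection on a filtered trace.

    An event is the first sample at or above ``k_sd`` channel standard
    deviations in absolute value (a below-to-above transition of
    ``|x| >= threshold``); within each ``lockout_s`` window after a kept
    event further crossings are ignored.  A 32-sample waveform is extracted
    per event with the crossing at sample 9 (1-based); events too close to
    the record edges for a full waveform are dropped.

    ``robust_sd`` estimates the standard deviation as MAD/0.6745 instead of
    the plain standard deviation of the full record (the default).
    """
    x = np.asarray(filtered, float)
    if x.size < WAVEFORM_LEN:
        raise ValueError(
            f"record has {x.size} samples; need at least {WAVEFORM_LEN}"
        )
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if lockout_s < 0:
        raise ValueError("lockout_s must be >= 0")

    if robust_sd:
        sd = np.median(np.abs(x - np.median(x))) / 0.6745
    else:
        sd = float(np.std(x))
    threshold = k_sd * sd

    above = np.abs(x) >= threshold
    # Below-to-above transitions; a record starting above threshold counts.
    onsets = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))

    lockout_n = int(round(lockout_s * sampling_rate_hz))
    kept: list[int] = []
    last = -np.inf
    for idx in onsets:
        if idx - last > lockout_n:
            kept.append(int(idx))
            last = idx

    rows = []
    waveforms = []
    for idx in kept:
        lo = idx - ALIGN_IDX
        hi = lo + WAVEFORM_LEN
        if lo < 0 or hi > x.size:
            continue
        w = x[lo:hi]
        rows.append(
            {
                "channel_id": channel_id,
                "event_time_s": idx / sampling_rate_hz,
                "sample_index": idx,
                "peak_sign": int(np.sign(w[np.argmax(np.abs(w))]) or 1),
            }
        )
        waveforms.append(w)

    events = pd.DataFrame(
        rows, columns=["channel_id", "event_time_s", "sample_index", "peak_sign"]
    )
    wf = np.asarray(waveforms, float) if waveforms else np.empty((0, WAVEFORM_LEN))
    return EventSet(events=events, waveforms=wf)


def detect(
    record: RawRecording,
    k_sd: float = DEFAULT_K_SD,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    lockout_s: float = DEFAULT_LOCKOUT_S,
    robust_sd: bool = False,
) -> EventSet:
    """Bandpass a raw recording and run threshold detection on it."""
    filtered = bandpass(record, band_hz[0], band_hz[1])
    return detect_events(
        filtered,
        sampling_rate_hz=record.sampling_rate_hz,
        k_sd=k_sd,
        lockout_s=lockout_s,
        channel_id=record.channel_id,
        robust_sd=robust_sd,
    )
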