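"""Core domain types and constants shared across the pipeline.

The analysis revolves around three containers:

* a *trial table* — one row per stimulus presentation, held as a pandas
  DataFrame with columns ``trial_id, session_id, face_id, category, onset_s``;
* a :class:`SpikeTrain` — sorted event times for one putative single unit;
* a *trial count matrix* — one row per trial with paired response/background
  spike counts, held as a DataFrame with columns
  ``neuron_id, area, trial_id, category, response_count, background_count``.

Categories follow the four-step morph continuum of the face stimuli and their
order is fixed so that all tabular outputs have a stable column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: The four race-morph categories of the stimulus faces, in fixed order.
CATEGORIES: tuple[str, ...] = ("White", "AmbiguousWhite", "AmbiguousBlack", "Black")

#: Recorded brain areas: amygdala, anterior cingulate, hippocampus, vmPFC.
AREAS: tuple[str, ...] = ("A", "ACC", "H", "vmPFC")

#: Label of the pre-stimulus reference condition in the selectivity model.
BACKGROUND_LABEL = "background"

#: Default A/D sampling rate of the microwire recording system, in Hz.
DEFAULT_SAMPLING_RATE_HZ = 29412.0

#: Extracted waveform length in samples.
WAVEFORM_LEN = 32

#: 0-based index of the alignment sample (the 9th of 32 samples, 1-based).
ALIGN_IDX = 8

TRIAL_COLUMNS = ("trial_id", "session_id", "face_id", "category", "onset_s")
COUNT_COLUMNS = (
    "neuron_id",
    "area",
    "trial_id",
    "category",
    "response_count",
    "background_count",
)


@dataclass(frozen=True)
class CountWindows:
    """Paired counting windows relative to stimulus onset, in seconds.

    Both windows are half-open ``(start, end]`` so a spike belongs to at most
    one window.  The defaults are the 200–1000 ms post-onset response window
    and the matched-length 1000–200 ms pre-onset background window.
    """

    response: tuple[float, float] = (0.200, 1.000)
    background: tuple[float, float] = (-1.000, -0.200)

    def __post_init__(self) -> None:
        r0, r1 = self.response
        b0, b1 = self.background
        if not (r1 > r0 and b1 > b0):
            raise ValueError("window end must exceed window start")
        if b1 > 0:
            raise ValueError("background window must end at or before onset")
        if not np.isclose(r1 - r0, b1 - b0):
            raise ValueError(
                f"response ({r1 - r0:g} s) and background ({b1 - b0:g} s) "
                "windows must have identical length"
            )

    @property
    def length_s(self) -> float:
        return self.response[1] - self.response[0]


@dataclass
class NeuronTuning:
    """Ground-truth firing model of one simulated neuron.

    Firing is Poisson at ``baseline_rate_hz`` everywhere except during
    ``[onset + latency_s, onset + latency_s + response_duration_s)`` of each
    trial, where the rate is multiplied by ``gain[category]``.  All gains at
    1.0 describe a null (non-selective) neuron.
    """

    neuron_id: str
    area: str = "A"
    baseline_rate_hz: float = 5.0
    gain: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CATEGORIES}
    )
    latency_s: float = 0.200
    response_duration_s: float = 0.800

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")
        if self.response_duration_s <= 0:
            raise ValueError("response_duration_s must be > 0")
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}; expected one of {AREAS}")
        gain = {c: 1.0 for c in CATEGORIES}
        gain.update(self.gain)
        unknown = set(gain) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in gain: {sorted(unknown)}")
        if any(g < 0 for g in gain.values()):
            raise ValueError("gains must be >= 0")
        self.gain = gain


@dataclass
class SpikeTrain:
    """Sorted spike times of one putative single unit."""

    neuron_id: str
    area: str
    session_id: str
    channel_id: str
    spike_times_s: np.ndarray
    mean_rate_hz: float = np.nan
    waveform_peak_sign: int = -1

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times_s must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("spike_times_s must be sorted ascending")
        if t.size and np.any(np.diff(t) == 0):
            raise ValueError("duplicate spike timestamps")
        self.spike_times_s = t
        if self.waveform_peak_sign not in (-1, 1):
            raise ValueError("waveform_peak_sign must be +1 or -1")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass
class RawRecording:
    """Single-channel raw voltage trace (arbitrary units)."""

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    session_id: str = "sess0"
    channel_id: str = "ch0"
    true_spike_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D sequence")
        if self.sampling_rate_hz <= 2 * 3000:
            raise ValueError(
                "sampling_rate_hz must exceed 6000 Hz (Nyquist for the "
                "300-3000 Hz detection band)"
            )
        if self.true_spike_times_s is not None:
            self.true_spike_times_s = np.asarray(self.true_spike_times_s, float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


def validate_categories(values: Sequence[str]) -> None:
    """Raise if any value is not one of the four stimulus categories."""
    unknown = set(values) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
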