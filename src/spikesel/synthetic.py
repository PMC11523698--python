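"""Synthetic experiment generator.

Emulates the statistical structure of the face-classification recording
sessions: 120 distinct face stimuli per session (30 per race-morph category,
with the 60 "ambiguous" morphs split evenly into AmbiguousWhite and
AmbiguousBlack), each presented 6 times for 720 trials; 1 s stimulus followed
by a 2 s response period; spike trains as piecewise-constant-rate Poisson
processes whose rate is multiplied by a per-category gain inside the response
window of each trial.

Spikes are generated as a continuous-time point process (not per-trial count
draws) so the voltage-synthesis/detection stage and the counting stage share
one ground truth; per-trial window counts remain exactly Poisson because the
windows are disjoint.

Every stochastic function takes an explicit integer seed; there is no hidden
global RNG state.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ALIGN_IDX,
    CATEGORIES,
    DEFAULT_SAMPLING_RATE_HZ,
    TRIAL_COLUMNS,
    WAVEFORM_LEN,
    NeuronTuning,
    RawRecording,
    SpikeTrain,
)

logger = logging.getLogger(__name__)

#: Faces per category in a default session (120 faces total).
DEFAULT_FACES_PER_CAT: dict[str, int] = {c: 30 for c in CATEGORIES}

#: Presentations of each face in a session (720 trials with the default design).
DEFAULT_N_REPEATS = 6

#: Stimulus duration (s) plus response period (s): the fixed part of the
#: inter-onset interval.  The jitter below is an artifact choice.
STIMULUS_S = 1.0
RESPONSE_PERIOD_S = 2.0
ITI_JITTER_MAX_S = 0.5

#: First onset leaves room for a full pre-onset background window.
SESSION_START_S = 2.0


def make_session(
    seed: int,
    n_faces_per_cat: Mapping[str, int] | None = None,
    n_repeats: int = DEFAULT_N_REPEATS,
    session_id: str = "sess0",
) -> pd.DataFrame:
    """Generate the trial table of one session.

    Each of the ``sum(n_faces_per_cat.values())`` distinct faces is presented
    ``n_repeats`` times in uniformly random (seeded) order.  Onsets are spaced
    by 1 s stimulus + 2 s response period + uniform 0-0.5 s jitter.

    Returns a DataFrame with columns
    ``trial_id, session_id, face_id, category, onset_s``.
    """
    if n_faces_per_cat is None:
        n_faces_per_cat = DEFAULT_FACES_PER_CAT
    unknown = set(n_faces_per_cat) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if n_repeats <= 0:
        raise ValueError("n_repeats must be positive")
    if any(n <= 0 for n in n_faces_per_cat.values()) or not n_faces_per_cat:
        raise ValueError("face counts must be positive")

    rng = np.random.default_rng(seed)

    face_cats = [c for c in CATEGORIES if c in n_faces_per_cat for _ in range(n_faces_per_cat[c])]
    face_ids = np.arange(len(face_cats))

    # One entry per presentation, shuffled uniformly.
    order = np.repeat(face_ids, n_repeats)
    rng.shuffle(order)

    n_trials = order.size
    gaps = STIMULUS_S + RESPONSE_PERIOD_S + rng.uniform(0.0, ITI_JITTER_MAX_S, n_trials)
    onsets = SESSION_START_S + np.concatenate([[0.0], np.cumsum(gaps[:-1])])

    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "session_id": session_id,
            "face_id": order,
            "category": [face_cats[i] for i in order],
            "onset_s": onsets,
        },
        columns=list(TRIAL_COLUMNS),
    )


def _response_windows(
    trials: pd.DataFrame, tuning: NeuronTuning
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Start, end and gain arrays of the rate-modulated window of each trial."""
    onsets = trials["onset_s"].to_numpy(float)
    starts = onsets + tuning.latency_s
    ends = starts + tuning.response_duration_s
    gains = np.array([tuning.gain[c] for c in trials["category"]], float)
    return starts, ends, gains


def simulate_spike_train(
    tuning: NeuronTuning,
    trials: pd.DataFrame,
    seed: int,
    session_id: str | None = None,
    channel_id: str = "ch0",
    waveform_peak_sign: int = -1,
) -> SpikeTrain:
    """Simulate one neuron's spike train across a session.

    The rate is ``baseline_rate_hz`` everywhere except during
    ``[onset + latency, onset + latency + duration)`` of each trial, where it
    is ``baseline * gain[category]``.  Implemented exactly by superposition
    and thinning of a homogeneous baseline process: windows with gain > 1
    receive extra Poisson spikes at rate ``baseline * (gain - 1)``; baseline
    spikes inside windows with gain < 1 are kept with probability ``gain``.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(seed)

    starts, ends, gains = _response_windows(trials, tuning)
    duration = float(ends.max() + RESPONSE_PERIOD_S)
    base = tuning.baseline_rate_hz

    if base == 0.0:
        times = np.empty(0)
    else:
        n_base = rng.poisson(base * duration)
        times = np.sort(rng.uniform(0.0, duration, n_base))

        # Thin baseline spikes inside gain<1 windows.
        low = gains < 1.0
        if low.any() and times.size:
            keep = np.ones(times.size, bool)
            for s, e, g in zip(starts[low], ends[low], gains[low]):
                i0, i1 = np.searchsorted(times, [s, e])
                keep[i0:i1] &= rng.uniform(size=i1 - i0) < g
            times = times[keep]

        # Superpose extra spikes in gain>1 windows.
        high = gains > 1.0
        if high.any():
            extra_rate = base * (gains[high] - 1.0) * (ends[high] - starts[high])
            n_extra = rng.poisson(extra_rate)
            extra = np.concatenate(
                [
                    rng.uniform(s, e, n)
                    for s, e, n in zip(starts[high], ends[high], n_extra)
                ]
            ) if n_extra.sum() else np.empty(0)
            times = np.sort(np.concatenate([times, extra]))

        times = np.unique(times)  # ties have probability zero; be safe

    if session_id is None:
        sid = trials["session_id"].iloc[0]
    else:
        sid = session_id
    return SpikeTrain(
        neuron_id=tuning.neuron_id,
        area=tuning.area,
        session_id=str(sid),
        channel_id=channel_id,
        spike_times_s=times,
        mean_rate_hz=times.size / duration,
        waveform_peak_sign=waveform_peak_sign,
    )


def default_template(
    peak_amplitude: float = 10.0, peak_sign: int = -1
) -> np.ndarray:
    """A 32-sample biphasic extracellular waveform template.

    The main peak sits at the alignment sample (9th of 32, 1-based) and the
    pre-peak samples are near zero, so a threshold detector first crosses at
    the alignment sample.
    """
    t = np.arange(WAVEFORM_LEN, dtype=float) - ALIGN_IDX
    main = np.exp(-0.5 * (t / 1.5) ** 2)
    rebound = -0.35 * np.exp(-0.5 * ((t - 6.0) / 4.0) ** 2)
    shape = main + rebound
    # Quiet onset: everything before the sample preceding the peak is zero,
    # so the first threshold crossing lands within one sample of the peak.
    shape[: ALIGN_IDX - 1] = 0.0
    shape[ALIGN_IDX - 1] *= 0.4
    shape /= np.abs(shape).max()
    return peak_sign * peak_amplitude * shape


def synthesize_voltage(
    train: SpikeTrain,
    template: np.ndarray | None = None,
    noise_sd: float = 1.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    seed: int = 0,
    duration_s: float | None = None,
) -> RawRecording:
    """Render a spike train as a raw voltage trace.

    White Gaussian noise of ``noise_sd`` plus one ``template`` instance per
    spike, placed so the template's alignment sample (index 8, i.e. the 9th
    of 32 samples 1-based) lands on the spike time.  Spikes too close to the
    record edges are skipped with a warning.  Ground-truth times of rendered
    spikes are carried in ``true_spike_times_s``.
    """
    if template is None:
        template = default_template(peak_sign=train.waveform_peak_sign)
    template = np.asarray(template, float)
    if template.size != WAVEFORM_LEN:
        raise ValueError(f"template must have {WAVEFORM_LEN} samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    times = train.spike_times_s
    if duration_s is None:
        duration_s = (times.max() + 1.0) if times.size else 1.0
    n = int(round(duration_s * sampling_rate_hz))

    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    rendered = []
    for t in times:
        idx = int(round(t * sampling_rate_hz))
        lo = idx - ALIGN_IDX
        hi = lo + WAVEFORM_LEN
        if lo < 0 or hi > n:
            logger.warning(
                "spike at %.6f s too close to record edge; skipped", t
            )
            continue
        samples[lo:hi] += template
        rendered.append(t)

    return RawRecording(
        samples=samples,
        sampling_rate_hz=sampling_rate_hz,
        session_id=train.session_id,
        channel_id=train.channel_id,
        true_spike_times_s=np.asarray(rendered, float),
    )


def simulate_population(
    seed: int,
    n_neurons_per_area: Mapping[str, int] | None = None,
    selective_fraction: float = 0.2,
    gain: float = 3.0,
    baseline_rate_hz: float = 5.0,
    trials: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[SpikeTrain], pd.DataFrame]:
    """Simulate a whole recorded population over one session.

    A ``selective_fraction`` of neurons in each area receive a multiplicative
    ``gain`` on one uniformly drawn category; the rest are null.  Returns
    ``(trials, spike_trains, ground_truth)`` where ground_truth records each
    neuron's selective category (empty string for null neurons).
    """
    if not 0.0 <= selective_fraction <= 1.0:
        raise ValueError("selective_fraction must be in [0, 1]")
    if n_neurons_per_area is None:
        n_neurons_per_area = {"A": 10, "ACC": 10, "H": 10, "vmPFC": 10}
    rng = np.random.default_rng(seed)
    if trials is None:
        trials = make_session(int(rng.integers(2**31)))

    trains: list[SpikeTrain] = []
    truth_rows = []
    for area, n_neurons in n_neurons_per_area.items():
        for i in range(n_neurons):
            nid = f"{area}_{i:03d}"
            selective = rng.uniform() < selective_fraction
            cat = str(rng.choice(CATEGORIES)) if selective else ""
            gains = {c: 1.0 for c in CATEGORIES}
            if selective:
                gains[cat] = gain
            tuning = NeuronTuning(
                neuron_id=nid,
                area=area,
                baseline_rate_hz=baseline_rate_hz,
                gain=gains,
            )
            trains.append(
                simulate_spike_train(
                    tuning,
                    trials,
                    seed=int(rng.integers(2**31)),
                    channel_id=f"{area}_ch{i:03d}",
                )
            )
            truth_rows.append(
                {"neuron_id": nid, "area": area, "selective_category": cat, "gain": gain if selective else 1.0}
            )
    return trials, trains, pd.DataFrame(truth_rows)
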