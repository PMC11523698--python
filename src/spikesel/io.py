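"""File formats: trial/spike/count CSVs and raw voltage binary + JSON sidecar.

All CSVs are UTF-8 with "." as the decimal separator.  Raw voltage is stored
as little-endian 16-bit signed integers with a JSON sidecar carrying the
sampling rate and channel identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    COUNT_COLUMNS,
    TRIAL_COLUMNS,
    RawRecording,
    SpikeTrain,
    validate_categories,
)

SPIKE_COLUMNS = ("neuron_id", "area", "session_id", "channel_id", "spike_time_s")
NEURON_COLUMNS = (
    "neuron_id",
    "area",
    "session_id",
    "channel_id",
    "mean_rate_hz",
    "waveform_peak_sign",
)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file missing columns: {sorted(missing)}")
    validate_categories(df["category"].unique())
    return df[list(TRIAL_COLUMNS)]


def write_spike_trains(trains: list[SpikeTrain], spikes_path: str | Path, neurons_path: str | Path) -> None:
    """One row per spike in ``spikes_path``; per-unit metadata (mean rate and
    waveform peak sign, needed by the duplicate screen) in ``neurons_path``."""
    spike_rows = []
    neuron_rows = []
    for t in trains:
        neuron_rows.append(
            {
                "neuron_id": t.neuron_id,
                "area": t.area,
                "session_id": t.session_id,
                "channel_id": t.channel_id,
                "mean_rate_hz": t.mean_rate_hz,
                "waveform_peak_sign": t.waveform_peak_sign,
            }
        )
        spike_rows.append(
            pd.DataFrame(
                {
                    "neuron_id": t.neuron_id,
                    "area": t.area,
                    "session_id": t.session_id,
                    "channel_id": t.channel_id,
                    "spike_time_s": t.spike_times_s,
                }
            )
        )
    spikes = (
        pd.concat(spike_rows, ignore_index=True)
        if spike_rows
        else pd.DataFrame(columns=list(SPIKE_COLUMNS))
    )
    spikes.to_csv(spikes_path, index=False, columns=list(SPIKE_COLUMNS))
    pd.DataFrame(neuron_rows, columns=list(NEURON_COLUMNS)).to_csv(
        neurons_path, index=False
    )


def read_spike_trains(spikes_path: str | Path, neurons_path: str | Path) -> list[SpikeTrain]:
    spikes = pd.read_csv(spikes_path)
    neurons = pd.read_csv(neurons_path)
    trains = []
    grouped = dict(iter(spikes.groupby("neuron_id"))) if len(spikes) else {}
    for _, row in neurons.iterrows():
        g = grouped.get(row["neuron_id"])
        times = np.sort(g["spike_time_s"].to_numpy(float)) if g is not None else np.empty(0)
        trains.append(
            SpikeTrain(
                neuron_id=str(row["neuron_id"]),
                area=str(row["area"]),
                session_id=str(row["session_id"]),
                channel_id=str(row["channel_id"]),
                spike_times_s=times,
                mean_rate_hz=float(row["mean_rate_hz"]),
                waveform_peak_sign=int(row["waveform_peak_sign"]),
            )
        )
    return trains


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False, columns=list(COUNT_COLUMNS))


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts file missing columns: {sorted(missing)}")
    return df[list(COUNT_COLUMNS)]


def write_raw(record: RawRecording, bin_path: str | Path, scale: float = 1.0) -> None:
    """Raw samples as little-endian int16 plus a ``.json`` sidecar.

    ``scale`` multiplies samples before rounding; values are clipped to the
    int16 range.
    """
    bin_path = Path(bin_path)
    scaled = np.clip(np.round(record.samples * scale), -32768, 32767).astype("<i2")
    scaled.tofile(bin_path)
    sidecar = {
        "sampling_rate_hz": record.sampling_rate_hz,
        "session_id": record.session_id,
        "channel_id": record.channel_id,
        "scale": scale,
    }
    with open(bin_path.with_suffix(bin_path.suffix + ".json"), "w", encoding="utf-8") as f:
        json.dump(sidecar, f, indent=1)


def read_raw(bin_path: str | Path) -> RawRecording:
    bin_path = Path(bin_path)
    with open(bin_path.with_suffix(bin_path.suffix + ".json"), encoding="utf-8") as f:
        sidecar = json.load(f)
    samples = np.fromfile(bin_path, dtype="<i2").astype(float) / sidecar.get("scale", 1.0)
    return RawRecording(
        samples=samples,
        sampling_rate_hz=sidecar["sampling_rate_hz"],
        session_id=sidecar["session_id"],
        channel_id=sidecar["channel_id"],
    )
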