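"""Audio and table I/O with a strict-input policy.

Clinical recordings are accepted only as mono 16-bit PCM WAV at the
expected sample rate; anything else is rejected explicitly rather than
silently resampled or downmixed, because resampling changes the distances
the verifier computes.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .frontend import AudioSignal

__all__ = ["read_wav", "write_wav", "read_scores", "write_scores", "write_json"]

_INT16_SCALE = 32768.0


def read_wav(path, expected_rate: int = 16000) -> AudioSignal:
    """Read a mono 16-bit PCM WAV file, scaling samples to [-1, 1].

    Rejects (with explicit errors) files at the wrong sample rate, bit
    depth, or channel count — downmix or resample upstream if needed.
    """
    rate, data = wavfile.read(path)
    if rate != expected_rate:
        raise ValueError(
            f"{path}: sample rate {rate} Hz, expected {expected_rate} Hz "
            "(no silent resampling)"
        )
    if data.dtype != np.int16:
        raise ValueError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    if data.ndim != 1:
        raise ValueError(
            f"{path}: {data.shape[1]} channels, expected mono "
            "(downmix before verification)"
        )
    return AudioSignal(data.astype(np.float64) / _INT16_SCALE, rate)


def write_wav(path, signal: AudioSignal) -> None:
    """Write an AudioSignal as mono 16-bit PCM WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    ints = np.round(clipped * _INT16_SCALE).astype(np.int64)
    ints = np.clip(ints, -32768, 32767).astype(np.int16)
    wavfile.write(path, signal.sample_rate, ints)


SCORE_COLUMNS = ["patient_id", "item_id", "word", "min_distance",
                 "decision", "truth"]


def write_scores(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.duplicated(["patient_id", "item_id"]).any():
        raise ValueError(f"{path}: duplicate (patient_id, item_id) rows")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
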