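"""WAV, annotation-table, and latent-stack I/O."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .segment import SyllableSegment

__all__ = [
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "segments_to_table",
    "save_latents",
    "load_latents",
]

ANNOTATION_COLUMNS = ["onset_s", "offset_s"]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono RIFF/WAVE file; returns (samples, sample_rate).

    Integer PCM is returned as stored (no rescaling); float32 round-trips
    bit-exactly through :func:`write_wav`.
    """
    import struct

    try:
        sample_rate, samples = wavfile.read(path)
    except (ValueError, struct.error, EOFError) as e:
        raise ValueError(f"malformed WAV file {path}: {e}") from e
    if samples.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {samples.ndim} channels")
    return samples, int(sample_rate)


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    samples = np.asarray(samples)
    if samples.ndim != 1:
        raise ValueError("samples must be 1-D (mono)")
    wavfile.write(path, sample_rate, samples)


def segments_to_table(segments: Sequence[SyllableSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": s.onset,
                "offset_s": s.offset,
                "mean_peak_freq_hz": s.mean_peak_freq,
                "purity": s.spectral_purity,
                "discontinuity": s.spectral_discontinuity,
                "energy": s.total_energy,
                "bandwidth_hz": s.bandwidth,
            }
            for s in segments
        ],
        columns=["onset_s", "offset_s", "mean_peak_freq_hz", "purity",
                 "discontinuity", "energy", "bandwidth_hz"],
    )


def write_annotations(path, table: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    table.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read a segment/annotation CSV; validates required columns and ordering."""
    table = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = table.index[table["offset_s"] <= table["onset_s"]].tolist()
    if bad:
        raise ValueError(f"{path}: offset_s <= onset_s at rows {bad}")
    if not table["onset_s"].is_monotonic_increasing:
        unsorted = table.index[table["onset_s"].diff() < 0].tolist()
        raise ValueError(f"{path}: onset_s not sorted at rows {unsorted}")
    return table


def save_latents(path, means: np.ndarray, variances: np.ndarray,
                 labels: pd.DataFrame | None = None, attrs: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("means", data=means)
        f.create_dataset("variances", data=variances)
        if labels is not None:
            grp = f.create_group("labels")
            for col in labels.columns:
                data = labels[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                grp.create_dataset(col, data=data)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_latents(path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame | None]:
    import h5py

    with h5py.File(path, "r") as f:
        means = f["means"][...]
        variances = f["variances"][...]
        labels = None
        if "labels" in f:
            cols = {}
            for name, ds in f["labels"].items():
                arr = ds[...]
                if arr.dtype.kind == "S":
                    arr = arr.astype(str)
                cols[name] = arr
            labels = pd.DataFrame(cols)
    return means, variances, labels
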