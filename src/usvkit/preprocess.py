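"""Fixed-size syllable spectrogram images for latent embedding.

Each detected (or annotated) syllable is converted to a 128x128 image: the
log-magnitude spectrogram of the syllable span is clipped to a fixed window
[-5.0, -1.5] of natural-log magnitude, rescaled affinely onto [0, 1], cropped
to 30-110 kHz, and interpolated onto a 128x128 grid whose time axis spans the
syllable (all durations are stretched to the full width).  No per-syllable
renormalization is applied, so relative loudness between syllables is
preserved in the pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .segment import SyllableSegment, compute_spectrogram

__all__ = [
    "ImageConfig",
    "SyllableImage",
    "make_syllable_image",
    "build_image_dataset",
    "scale_log_spec",
]


@dataclass(frozen=True)
class ImageConfig:
    min_freq: float = 30_000.0
    max_freq: float = 110_000.0
    nperseg: int = 1024
    noverlap: int = 512
    spec_min_val: float = -5.0
    spec_max_val: float = -1.5
    mel: bool = False
    time_stretch: bool = True
    within_syll_normalize: bool = False
    out_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.spec_min_val >= self.spec_max_val:
            raise ValueError("spec_min_val must be < spec_max_val")
        if self.min_freq >= self.max_freq:
            raise ValueError("min_freq must be < max_freq")
        if self.mel:
            raise NotImplementedError("mel-scaled images are out of scope")


@dataclass
class SyllableImage:
    pixels: np.ndarray  # 128x128 float32 in [0, 1]
    provenance: dict


def scale_log_spec(log_spec: np.ndarray, cfg: ImageConfig) -> np.ndarray:
    """Clip log-magnitude values to the config window and rescale to [0, 1]."""
    clipped = np.clip(log_spec, cfg.spec_min_val, cfg.spec_max_val)
    return (clipped - cfg.spec_min_val) / (cfg.spec_max_val - cfg.spec_min_val)


def make_syllable_image(
    audio: np.ndarray,
    segment: SyllableSegment,
    cfg: ImageConfig | None = None,
    sample_rate: int = 250_000,
    provenance: dict | None = None,
) -> SyllableImage:
    """Image a single syllable span of a recording.

    The span [onset, offset) is excised (zero-padded to at least one STFT
    window), transformed, clipped/rescaled, frequency-cropped, and bilinearly
    interpolated onto the output grid.
    """
    cfg = cfg or ImageConfig()
    if cfg.max_freq > sample_rate / 2:
        raise ValueError("max_freq above Nyquist")
    i0 = int(round(segment.onset * sample_rate))
    i1 = int(round(segment.offset * sample_rate))
    if i0 < 0 or i1 > len(audio) or i1 <= i0:
        raise ValueError(
            f"segment [{segment.onset}, {segment.offset}) outside audio of "
            f"{len(audio) / sample_rate:.3f} s"
        )
    clip = np.asarray(audio[i0:i1], dtype=np.float64)
    if len(clip) < cfg.nperseg:
        pad = cfg.nperseg - len(clip)
        clip = np.pad(clip, (pad // 2, pad - pad // 2))
    spec = compute_spectrogram(clip, sample_rate, cfg.nperseg, cfg.noverlap)
    scaled = scale_log_spec(spec.values, cfg)

    fmask = (spec.freq_axis >= cfg.min_freq) & (spec.freq_axis <= cfg.max_freq)
    freqs = spec.freq_axis[fmask]
    scaled = scaled[fmask, :]
    times = spec.time_axis

    n_f, n_t = cfg.out_shape
    target_f = np.linspace(cfg.min_freq, cfg.max_freq, n_f)
    # both source axes are uniform grids, so bilinear interpolation reduces to
    # an index-space gather with fractional weights
    rows = _interp_rows(scaled, freqs, target_f)
    if rows.shape[1] == 1:
        pixels = np.repeat(rows, n_t, axis=1)
    else:
        ci = np.linspace(0.0, rows.shape[1] - 1.0, n_t)
        c0 = np.floor(ci).astype(int)
        c1 = np.minimum(c0 + 1, rows.shape[1] - 1)
        wc = ci - c0
        pixels = rows[:, c0] * (1.0 - wc) + rows[:, c1] * wc
    pixels = np.clip(pixels, 0.0, 1.0).astype(np.float32)
    return SyllableImage(pixels=pixels, provenance=provenance or {})


def _interp_rows(S: np.ndarray, freqs: np.ndarray, target_f: np.ndarray) -> np.ndarray:
    """Linear interpolation of spectrogram rows onto target frequencies."""
    df = freqs[1] - freqs[0]
    ri = np.clip((target_f - freqs[0]) / df, 0.0, len(freqs) - 1.0)
    r0 = np.floor(ri).astype(int)
    r1 = np.minimum(r0 + 1, len(freqs) - 1)
    wr = (ri - r0)[:, None]
    return S[r0, :] * (1.0 - wr) + S[r1, :] * wr


def build_image_dataset(
    sessions: Sequence,
    segments_per_session: Sequence[Sequence[SyllableSegment]],
    cfg: ImageConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Image every segment of every session into one stack plus metadata.

    Sessions are :class:`usvkit.synth.SyntheticSession`-like objects exposing
    ``samples``, ``sample_rate``, ``mouse_id`` and ``condition``.  The stack is
    ordered by (session order, onset); the metadata table has one row per
    image with matching order.
    """
    cfg = cfg or ImageConfig()
    images: list[np.ndarray] = []
    rows: list[dict] = []
    for si, (sess, segs) in enumerate(zip(sessions, segments_per_session)):
        for k, seg in enumerate(sorted(segs, key=lambda s: s.onset)):
            img = make_syllable_image(sess.samples, seg, cfg, sess.sample_rate)
            images.append(img.pixels)
            rows.append(
                {
                    "mouse_id": sess.mouse_id,
                    "condition": sess.condition,
                    "session": si,
                    "syllable_index": k,
                    "onset_s": seg.onset,
                    "duration_s": seg.offset - seg.onset,
                }
            )
    stack = np.stack(images) if images else np.zeros((0, *cfg.out_shape), dtype=np.float32)
    return stack, pd.DataFrame(rows)


def save_image_dataset(path, stack: np.ndarray, metadata: pd.DataFrame,
                       cfg: ImageConfig | None = None) -> None:
    """Persist an image stack + metadata to HDF5 (config echoed as attrs)."""
    import h5py

    cfg = cfg or ImageConfig()
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=stack, compression="gzip")
        grp = f.create_group("metadata")
        for col in metadata.columns:
            data = metadata[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            grp.create_dataset(col, data=data)
        for k, v in asdict(cfg).items():
            f.attrs[k] = v if not isinstance(v, tuple) else list(v)


def load_image_dataset(path) -> tuple[np.ndarray, pd.DataFrame]:
    import h5py

    with h5py.File(path, "r") as f:
        stack = f["images"][...]
        cols = {}
        for name, ds in f["metadata"].items():
            arr = ds[...]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            cols[name] = arr
    return stack, pd.DataFrame(cols)
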