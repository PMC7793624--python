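"""Peri-stimulus quantification of vocal behavior.

Given syllable onset times and a train of optogenetic stimulation epochs,
these metrics describe how vocal output changes around stimulation: a
peri-stimulus time histogram (PSTH) of USV rate, per-trial latencies to the
first elicited USV, pre/laser/post counts normalized to pre-stimulus output,
and the place-preference score for real-time place preference tests.

All intervals are half-open [start, stop): an event exactly at stimulus onset
belongs to the first post-onset bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusTrain",
    "PeriStimulusSummary",
    "usv_rate_psth",
    "latency_stats",
    "pre_laser_post_normalized",
    "place_preference_score",
]


@dataclass(frozen=True)
class StimulusEpoch:
    onset: float
    offset: float
    pulse_rate_hz: float = 15.0
    pulse_width_s: float = 0.05

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("epoch offset must exceed onset")


@dataclass
class StimulusTrain:
    epochs: list[StimulusEpoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("stimulus train must contain at least one epoch")
        self.epochs = sorted(self.epochs, key=lambda e: e.onset)
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.onset < a.offset:
                raise ValueError(f"overlapping epochs at {a.offset} / {b.onset}")

    @classmethod
    def regular(cls, n_trials: int, first_onset: float, period: float,
                duration: float, **kw) -> "StimulusTrain":
        return cls([
            StimulusEpoch(first_onset + i * period, first_onset + i * period + duration, **kw)
            for i in range(n_trials)
        ])

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.epochs])


@dataclass
class PeriStimulusSummary:
    bin_edges: np.ndarray  # seconds relative to epoch onset
    mean_rate: np.ndarray  # syllables/s per bin
    sem_rate: np.ndarray
    trial_counts: np.ndarray  # (n_trials, n_bins)
    latencies: np.ndarray  # per responsive trial, seconds
    fraction_trials_with_usv: float
    min_latency: float | None
    mean_latency: float | None


def _bin_counts(onsets: np.ndarray, t0: float, edges: np.ndarray) -> np.ndarray:
    """Half-open binning of events relative to t0 (strictly [lo, hi) per bin)."""
    rel = onsets - t0
    width = edges[1] - edges[0]
    idx = np.floor((rel - edges[0]) / width).astype(int)
    good = (idx >= 0) & (idx < len(edges) - 1) & (rel >= edges[0]) & (rel < edges[-1])
    counts = np.bincount(idx[good], minlength=len(edges) - 1)
    return counts.astype(float)


def latency_stats(
    usv_onsets: Sequence[float],
    stimuli: StimulusTrain,
    response_window: float | None = None,
) -> dict:
    """Per-trial latency to the first USV after stimulus onset.

    The response window defaults to the epoch duration plus 1 s (elicited
    bouts often outlast the stimulus).  Trials whose first in-window USV is
    absent are non-responsive.
    """
    onsets = np.sort(np.asarray(usv_onsets, dtype=float))
    latencies = []
    for ep in stimuli.epochs:
        win = response_window if response_window is not None else (ep.offset - ep.onset) + 1.0
        in_win = onsets[(onsets >= ep.onset) & (onsets < ep.onset + win)]
        if len(in_win):
            latencies.append(float(in_win[0] - ep.onset))
    lat = np.array(latencies)
    n_trials = len(stimuli.epochs)
    return {
        "latencies": lat,
        "min_latency": float(lat.min()) if len(lat) else None,
        "mean_latency": float(lat.mean()) if len(lat) else None,
        "fraction_trials_with_usv": len(lat) / n_trials,
    }


def usv_rate_psth(
    usv_onsets: Sequence[float],
    stimuli: StimulusTrain,
    window: tuple[float, float] = (-2.0, 6.0),
    bin_width: float = 0.2,
    response_window: float | None = None,
) -> PeriStimulusSummary:
    """USV rate aligned to stimulus onsets.

    Per-trial binned counts are converted to rates (count / bin width); the
    summary holds the across-trial mean and s.e.m. per bin, plus the latency
    statistics of :func:`latency_stats`.
    """
    onsets = np.sort(np.asarray(usv_onsets, dtype=float))
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    counts = np.stack([_bin_counts(onsets, ep.onset, edges) for ep in stimuli.epochs])
    rates = counts / bin_width
    mean = rates.mean(axis=0)
    n_trials = len(stimuli.epochs)
    sem = rates.std(axis=0, ddof=1) / np.sqrt(n_trials) if n_trials > 1 else np.zeros(n_bins)
    lat = latency_stats(onsets, stimuli, response_window)
    return PeriStimulusSummary(
        bin_edges=edges,
        mean_rate=mean,
        sem_rate=sem,
        trial_counts=counts,
        latencies=lat["latencies"],
        fraction_trials_with_usv=lat["fraction_trials_with_usv"],
        min_latency=lat["min_latency"],
        mean_latency=lat["mean_latency"],
    )


def pre_laser_post_normalized(
    usv_onsets: Sequence[float],
    stimuli: StimulusTrain,
    epoch_len: float = 1.0,
) -> dict:
    """Pre/laser/post USV counts, each normalized by the pre-laser count.

    Counts are taken in [-epoch_len, 0), [0, epoch_len), [epoch_len,
    2*epoch_len) around each stimulus onset and divided by that trial's pre
    count.  Trials with zero pre-laser USVs cannot be normalized; they are
    excluded and reported.
    """
    onsets = np.sort(np.asarray(usv_onsets, dtype=float))
    edges = np.array([-epoch_len, 0.0, epoch_len, 2 * epoch_len])
    triples = []
    excluded = 0
    for ep in stimuli.epochs:
        c = _bin_counts(onsets, ep.onset, edges)
        if c[0] == 0:
            excluded += 1
            continue
        triples.append(c / c[0])
    arr = np.array(triples) if triples else np.zeros((0, 3))
    return {
        "per_trial": arr,
        "mean": arr.mean(axis=0) if len(arr) else np.full(3, np.nan),
        "n_trials_used": len(arr),
        "n_trials_excluded": excluded,
    }


def place_preference_score(
    times: Sequence[float],
    sides: Sequence[str],
    stimulated_side: str,
    total: float = 20 * 60.0,
) -> float:
    """Fraction of the test period spent in the stimulated side.

    ``times``/``sides`` are a sampled occupancy trace (timestamps in seconds
    and 'left'/'right' labels).  Only samples inside [0, total) are scored;
    if the trace does not cover the full period the proportion is computed
    over the observed samples (proportional rescaling) with a warning.
    """
    import warnings

    t = np.asarray(times, dtype=float)
    s = np.asarray(sides)
    mask = (t >= 0) & (t < total)
    if not mask.any():
        raise ValueError("occupancy trace does not overlap the scored period")
    t, s = t[mask], s[mask]
    if len(t) > 1:
        coverage = (t.max() - t.min()) / total
        if coverage < 0.95:
            warnings.warn(
                f"occupancy covers only {coverage:.0%} of the scored period; "
                "proportion computed over observed samples"
            )
    return float(np.mean(s == stimulated_side))
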