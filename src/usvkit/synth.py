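"""Synthetic ultrasonic vocal sessions with ground-truth annotations.

Mouse ultrasonic vocalizations (USVs) are short (5-150 ms) frequency-modulated
whistles with peak frequencies roughly between 45 and 110 kHz, emitted in bouts
separated by silent gaps.  This module generates sessions of such syllables as
pure FM tones over white background noise, together with the exact parameters
of every rendered syllable, so that every downstream stage (detection, imaging,
latent embedding, repertoire statistics) can be validated against ground truth
without any recorded audio.

Two recording conditions per synthetic mouse are supported: condition B is a
shifted copy of condition A (louder by a gain factor and/or with a wider
frequency sweep), emulating a repertoire shift whose direction is shared across
mice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "SyllableSpec",
    "ConditionParams",
    "ConditionShift",
    "SyntheticSession",
    "sample_syllable_spec",
    "render_syllable",
    "render_session",
    "make_two_condition_dataset",
]

#: hard frequency limits for any instantaneous-frequency value (Hz)
FREQ_MIN = 25_000.0
FREQ_MAX = 120_000.0

DEFAULT_SAMPLE_RATE = 250_000


@dataclass(frozen=True)
class SyllableSpec:
    """Parameters of a single FM-tone syllable.

    ``f_start``/``f_end`` give the endpoints of the instantaneous-frequency
    trajectory; ``jump_offset`` adds an instantaneous frequency step (a "jump")
    at fraction ``jump_time_frac`` of the duration.  ``amplitude`` is the peak
    amplitude of the tone in linear units; the session gain convention is
    chosen so that typical syllables land inside the log-spectrogram clip
    window used for imaging (see :mod:`usvkit.preprocess`).
    """

    onset: float = 0.0
    duration: float = 0.05
    f_start: float = 70_000.0
    f_end: float = 78_000.0
    fm_shape: Literal["linear", "sinusoidal"] = "linear"
    jump_offset: float = 0.0
    jump_time_frac: float = 0.5
    amplitude: float = 0.08
    envelope_taper: float = 0.1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        for name, f in (("f_start", self.f_start), ("f_end", self.f_end)):
            if not (FREQ_MIN <= f <= FREQ_MAX):
                raise ValueError(f"{name}={f} outside [{FREQ_MIN}, {FREQ_MAX}] Hz")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if not (0.0 <= self.envelope_taper <= 0.5):
            raise ValueError("envelope_taper must be in [0, 0.5]")
        if self.jump_offset != 0.0 and not (0.0 < self.jump_time_frac < 1.0):
            raise ValueError("jump_time_frac must be strictly interior when a jump is present")
        if self.fm_shape not in ("linear", "sinusoidal"):
            raise ValueError(f"unknown fm_shape {self.fm_shape!r}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def bandwidth(self) -> float:
        """Realized sweep extent |f_end - f_start| in Hz (jump excluded)."""
        return abs(self.f_end - self.f_start)


@dataclass(frozen=True)
class ConditionParams:
    """Distribution over syllables plus the timing/noise process of a condition.

    Syllable fields are drawn as independent Gaussians (truncated to the
    :class:`SyllableSpec` invariants); jumps occur with probability
    ``jump_prob``.  Syllable onsets follow a renewal process: after each
    syllable offset the next onset follows at ``isi_min`` plus an exponential
    tail whose mean is derived from ``rate`` (expected cycle length =
    1/rate).  ``noise_floor`` is the RMS of the additive white background
    noise; the default sits ~30 dB below a typical syllable's RMS.
    """

    duration_mean: float = 0.05
    duration_sd: float = 0.012
    f_start_mean: float = 70_000.0
    f_start_sd: float = 3_000.0
    f_end_mean: float = 78_000.0
    f_end_sd: float = 3_000.0
    amplitude_mean: float = 0.08
    amplitude_sd: float = 0.015
    jump_prob: float = 0.2
    jump_size_mean: float = 20_000.0
    jump_size_sd: float = 4_000.0
    sinusoidal_prob: float = 0.3
    rate: float = 2.0
    isi_min: float = 0.05
    noise_floor: float = 0.0017
    envelope_taper: float = 0.1
    duration_bounds: tuple[float, float] = (0.005, 0.15)

    def __post_init__(self) -> None:
        for name in ("duration_sd", "f_start_sd", "f_end_sd", "amplitude_sd", "jump_size_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.jump_prob <= 1.0):
            raise ValueError("jump_prob must be in [0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.isi_min < 0:
            raise ValueError("isi_min must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")

    @property
    def isi_tail_mean(self) -> float:
        """Mean of the exponential ISI tail implied by ``rate``.

        Expected cycle = duration + isi_min + tail = 1/rate.
        """
        tail = 1.0 / self.rate - self.duration_mean - self.isi_min
        if tail <= 0:
            raise ValueError(
                f"rate={self.rate}/s incompatible with isi_min={self.isi_min}s "
                f"and mean duration {self.duration_mean}s"
            )
        return tail


@dataclass(frozen=True)
class ConditionShift:
    """How condition B's syllable distribution differs from condition A's."""

    amplitude_gain: float = 1.0
    bandwidth_delta_hz: float = 0.0
    duration_delta_s: float = 0.0


@dataclass
class SyntheticSession:
    """A rendered session: waveform, realized syllable specs, labels, seed."""

    samples: np.ndarray
    sample_rate: int
    annotations: list[SyllableSpec]
    mouse_id: str
    condition: str
    seed: int

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def onsets(self) -> np.ndarray:
        return np.array([s.onset for s in self.annotations])

    def annotation_table(self):
        """Realized annotation features as a pandas DataFrame."""
        import pandas as pd

        rows = [
            {
                "onset_s": s.onset,
                "offset_s": s.offset,
                "duration_s": s.duration,
                "f_start_hz": s.f_start,
                "f_end_hz": s.f_end,
                "bandwidth_hz": s.bandwidth,
                "amplitude": s.amplitude,
                "jump_offset_hz": s.jump_offset,
                "mouse_id": self.mouse_id,
                "condition": self.condition,
            }
            for s in self.annotations
        ]
        return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_syllable_spec(cond: ConditionParams, seed: int | np.random.Generator) -> SyllableSpec:
    """Draw one syllable spec from a condition's distributions.

    Deterministic given the seed.  With all sds zero and ``jump_prob`` in
    {0, 1} the draw equals the distribution means exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo_d, hi_d = cond.duration_bounds
    duration = _truncated_normal(rng, cond.duration_mean, cond.duration_sd, lo_d, hi_d)
    f_start = _truncated_normal(rng, cond.f_start_mean, cond.f_start_sd, FREQ_MIN, FREQ_MAX)
    f_end = _truncated_normal(rng, cond.f_end_mean, cond.f_end_sd, FREQ_MIN, FREQ_MAX)
    amplitude = _truncated_normal(rng, cond.amplitude_mean, cond.amplitude_sd,
                                  1e-6, np.inf)
    fm_shape = "sinusoidal" if rng.random() < cond.sinusoidal_prob else "linear"
    jump_offset = 0.0
    jump_time_frac = 0.5
    if rng.random() < cond.jump_prob:
        size = abs(_truncated_normal(rng, cond.jump_size_mean, cond.jump_size_sd,
                                     0.0, np.inf))
        # pick the jump direction that keeps the trajectory inside the band
        top = max(f_start, f_end)
        bottom = min(f_start, f_end)
        if top + size > FREQ_MAX - 2_000.0:
            sign = -1.0
        elif bottom - size < FREQ_MIN + 2_000.0:
            sign = 1.0
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        size = min(size, (FREQ_MAX - 2_000.0 - top) if sign > 0 else (bottom - FREQ_MIN - 2_000.0))
        if size > 1_000.0:
            jump_offset = sign * size
            jump_time_frac = float(rng.uniform(0.3, 0.7))
    return SyllableSpec(
        onset=0.0,
        duration=duration,
        f_start=f_start,
        f_end=f_end,
        fm_shape=fm_shape,
        jump_offset=jump_offset,
        jump_time_frac=jump_time_frac,
        amplitude=amplitude,
        envelope_taper=cond.envelope_taper,
    )


def _freq_trajectory(spec: SyllableSpec, n: int) -> np.ndarray:
    """Instantaneous frequency at each of n samples spanning the syllable."""
    tau = np.linspace(0.0, 1.0, n, endpoint=False)
    if spec.fm_shape == "linear":
        f = spec.f_start + (spec.f_end - spec.f_start) * tau
    else:  # sinusoidal: smooth half-cosine sweep between the endpoints
        f = spec.f_start + (spec.f_end - spec.f_start) * 0.5 * (1 - np.cos(np.pi * tau))
    if spec.jump_offset != 0.0:
        f = f + np.where(tau >= spec.jump_time_frac, spec.jump_offset, 0.0)
    return f


def render_syllable(spec: SyllableSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Render one syllable as an FM tone.

    The phase is the cumulative integral of the instantaneous frequency, so
    the waveform is phase-continuous even across a frequency jump (no
    broadband click).  A Tukey taper of fractional width ``envelope_taper``
    is applied at each edge.
    """
    n = max(int(round(spec.duration * sample_rate)), 2)
    f = _freq_trajectory(spec, n)
    fmax = float(np.max(np.abs(f)))
    if sample_rate < 2.0 * fmax:
        raise ValueError(
            f"sample_rate {sample_rate} Hz below Nyquist requirement for "
            f"max instantaneous frequency {fmax:.0f} Hz"
        )
    phase = 2.0 * np.pi * np.cumsum(f) / sample_rate
    env = tukey(n, alpha=2.0 * spec.envelope_taper) if spec.envelope_taper > 0 else np.ones(n)
    return (spec.amplitude * env * np.sin(phase)).astype(np.float64)


def render_session(
    cond: ConditionParams,
    duration: float = 60.0,
    mouse_id: str = "m0",
    condition: str = "A",
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> SyntheticSession:
    """Render a full session: syllables placed by the ISI renewal process.

    Syllable waveforms are summed onto a white-noise floor; the realized spec
    of every placed syllable (with its onset) is recorded in
    ``annotations``.  Deterministic given (params, seed).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    tail_mean = cond.isi_tail_mean  # validates rate vs isi_min
    # separate noise / syllable streams so annotation-only realizations match
    noise_ss, spec_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(spec_ss)
    n_total = int(round(duration * sample_rate))
    if cond.noise_floor > 0:
        samples = np.random.default_rng(noise_ss).normal(0.0, cond.noise_floor, n_total)
    else:
        samples = np.zeros(n_total)

    annotations: list[SyllableSpec] = []
    t = cond.isi_min + rng.exponential(tail_mean)
    while True:
        spec = sample_syllable_spec(cond, rng)
        if t + spec.duration > duration:
            break
        spec = replace(spec, onset=t)
        wav = render_syllable(spec, sample_rate)
        i0 = int(round(t * sample_rate))
        samples[i0:i0 + len(wav)] += wav[: n_total - i0]
        annotations.append(spec)
        t = spec.offset + cond.isi_min + rng.exponential(tail_mean)
    return SyntheticSession(
        samples=samples.astype(np.float32),
        sample_rate=sample_rate,
        annotations=annotations,
        mouse_id=mouse_id,
        condition=condition,
        seed=seed,
    )


def shift_condition(base: ConditionParams, shift: ConditionShift) -> ConditionParams:
    """Condition B parameters: A with amplitude gained and sweep widened.

    The bandwidth delta moves ``f_end_mean`` away from ``f_start_mean`` (in
    the direction of the mean sweep), so the mean realized |f_end - f_start|
    grows by ~``bandwidth_delta_hz``.
    """
    sweep_sign = 1.0 if base.f_end_mean >= base.f_start_mean else -1.0
    return replace(
        base,
        amplitude_mean=base.amplitude_mean * shift.amplitude_gain,
        f_end_mean=base.f_end_mean + sweep_sign * shift.bandwidth_delta_hz,
        duration_mean=base.duration_mean + shift.duration_delta_s,
    )


def make_two_condition_dataset(
    n_mice: int,
    base: ConditionParams | None = None,
    shift: ConditionShift | None = None,
    seed: int = 0,
    session_duration: float = 60.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    render_audio: bool = True,
) -> list[SyntheticSession]:
    """One session per condition per mouse; B is a shifted copy of A.

    Per-mouse, per-condition seeds are spawned deterministically from the
    master seed.  With ``render_audio=False`` only the annotations are
    realized (the ``samples`` array is empty); this is the fast path for
    repertoire statistics that never touch the session waveform.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    base = base or ConditionParams()
    shift = shift or ConditionShift()
    cond_b = shift_condition(base, shift)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_mice) % (2**31 - 1)
    sessions: list[SyntheticSession] = []
    for i in range(n_mice):
        for j, (label, cond) in enumerate((("A", base), ("B", cond_b))):
            s = int(child_seeds[2 * i + j])
            if render_audio:
                sessions.append(
                    render_session(cond, session_duration, f"m{i:02d}", label, s, sample_rate)
                )
            else:
                sessions.append(
                    _annotate_only(cond, session_duration, f"m{i:02d}", label, s, sample_rate)
                )
    return sessions


def _annotate_only(cond: ConditionParams, duration: float, mouse_id: str,
                   condition: str, seed: int, sample_rate: int) -> SyntheticSession:
    """Realize the syllable process without rendering any audio.

    Uses the same syllable stream as :func:`render_session`, so the
    annotations are identical to the audio-rendered session for a seed.
    """
    tail_mean = cond.isi_tail_mean
    _, spec_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(spec_ss)
    annotations: list[SyllableSpec] = []
    t = cond.isi_min + rng.exponential(tail_mean)
    while True:
        spec = sample_syllable_spec(cond, rng)
        if t + spec.duration > duration:
            break
        annotations.append(replace(spec, onset=t))
        t = annotations[-1].offset + cond.isi_min + rng.exponential(tail_mean)
    return SyntheticSession(
        samples=np.zeros(0, dtype=np.float32),
        sample_rate=sample_rate,
        annotations=annotations,
        mouse_id=mouse_id,
        condition=condition,
        seed=seed,
    )
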