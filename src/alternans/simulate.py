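"""Artificial ECG tracings with known T-wave alternans (TWA).

A clean tracing is a K-fold repetition of a single beat (default: a 0.7 s
parametric beat at 500 Hz, repeated 128 times with constant RR = 0.7 s), so
the TWA-free signal contains no beat-to-beat variability at all.  Alternans
is injected as an additive raised-cosine bump of width 160 ms centred on the
T-wave apex: beat ``n`` receives ``s(n)·b(t)`` with ``s(n) = ±A(n)/2``, so
the maximum absolute sample difference between consecutive beats equals the
intended alternans amplitude ``A(n)``.  Optional disturbances are a
sinusoidal baseline wander (default 0.1 mV) and white noise.

Amplitude sequences: stationary (constant A), sinusoidal (period 128 beats),
cascaded step (50→20 µV over a smoothed 24-beat transition) and phase
reversal (the ABAB parity flips at the listed beats).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EcgTracing, Fiducials

__all__ = [
    "BeatTemplate",
    "TwaPattern",
    "BaselineSpec",
    "SimTruth",
    "make_beat_template",
    "make_twa_sequence",
    "simulate_tracing",
    "DEFAULT_MORPHOLOGY",
]

#: Default beat morphology: (centre s, width s, amplitude µV) of raised-cosine
#: deflections.  R apex at 0.15 s is the QRS fiducial; the monophasic T wave
#: peaks at 0.35 s with 500 µV.  All deflections have compact support, so the
#: segments between them (pre-P, PQ, ST, TP) are exactly isoelectric.
DEFAULT_MORPHOLOGY = {
    "p": (0.08, 0.05, 60.0),
    "q": (0.138, 0.018, -80.0),
    "r": (0.15, 0.024, 1000.0),
    "s": (0.165, 0.02, -120.0),
    "t": (0.35, 0.24, 500.0),
}


def _raised_cosine(n: int, fs: float, center_s: float, width_s: float,
                   amp: float) -> np.ndarray:
    """Compactly supported Hann bump: peak ``amp`` at ``center_s``, zero
    outside ``center_s ± width_s/2``."""
    t = np.arange(n) / fs
    half = width_s / 2.0
    out = np.zeros(n)
    m = np.abs(t - center_s) <= half
    out[m] = amp * 0.5 * (1.0 + np.cos(np.pi * (t[m] - center_s) / half))
    return out


@dataclass(frozen=True)
class BeatTemplate:
    """One beat of a clean ECG, in µV."""

    samples: np.ndarray
    fs: float
    t_apex_index: int
    r_peak_index: int
    beat_duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        n = int(round(self.beat_duration_s * self.fs))
        if self.samples.size != n:
            raise ValueError(
                f"template length {self.samples.size} != round(duration*fs) = {n}"
            )
        if not 0 < self.t_apex_index < self.samples.size - 1:
            raise ValueError("T apex must lie strictly inside the beat")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class TwaPattern:
    """Per-beat alternans amplitude pattern.

    ``kind`` is one of ``none``, ``stationary``, ``sinusoidal``,
    ``cascaded_step``, ``phase_reversal``.  ``amplitude_uv`` is a scalar for
    stationary/sinusoidal/phase-reversal patterns and a (high, low) pair for
    the cascaded step.  Beat indices in ``reversal_beats`` and
    ``transition_start_beat`` are 1-based.
    """

    kind: str = "none"
    amplitude_uv: float | tuple = 0.0
    period_beats: int = 128
    transition_beats: int = 24
    transition_start_beat: int = 52
    reversal_beats: tuple = (40, 80)
    window_ms: float = 160.0

    def __post_init__(self) -> None:
        kinds = {"none", "stationary", "sinusoidal", "cascaded_step", "phase_reversal"}
        if self.kind not in kinds:
            raise ValueError(f"unknown pattern kind {self.kind!r}; expected one of {sorted(kinds)}")
        amp = np.atleast_1d(np.asarray(self.amplitude_uv, dtype=float))
        if np.any(amp < 0):
            raise ValueError("amplitude_uv must be non-negative")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        rb = tuple(self.reversal_beats)
        if list(rb) != sorted(set(rb)):
            raise ValueError("reversal_beats must be strictly increasing")


@dataclass(frozen=True)
class BaselineSpec:
    """Additive sinusoidal baseline wander."""

    amplitude_mv: float = 0.1
    freq_hz: float = 0.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_mv < 0:
            raise ValueError("amplitude_mv must be non-negative")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth attached to a simulated tracing.

    ``a_n`` is the predefined per-beat alternans amplitude sequence A(n) —
    the gold-standard reference for error evaluation.  ``a_n_measured`` is
    the same quantity re-measured from the clean injected waves as the
    maximum absolute sample difference between the n-th and (n+1)-th T wave
    (the last beat inherits its predecessor's value); for stationary
    patterns the two coincide exactly, at phase reversals the measured
    consecutive difference vanishes.
    """

    a_n: np.ndarray
    a_n_measured: np.ndarray
    s_n: np.ndarray
    fiducials: Fiducials
    n_beats: int


def make_beat_template(
    fs: float = 500.0,
    beat_duration_s: float = 0.7,
    morphology: dict | None = None,
) -> BeatTemplate:
    """Build a deterministic parametric beat.

    The beat is a sum of compactly supported raised-cosine deflections
    (P, Q, R, S and a smooth monophasic T wave), so the first and last
    samples sit exactly on the isoelectric level (0 µV).  Identical
    parameters give bit-identical output.
    """
    if fs <= 0 or beat_duration_s <= 0:
        raise ValueError("fs and beat_duration_s must be positive")
    morph = dict(DEFAULT_MORPHOLOGY if morphology is None else morphology)
    if "t" not in morph or "r" not in morph:
        raise ValueError("morphology must define 'r' and 't' deflections")
    n = int(round(beat_duration_s * fs))
    samples = np.zeros(n)
    for center, width, amp in morph.values():
        if center - width / 2 < 0 or center + width / 2 > beat_duration_s:
            raise ValueError(
                f"deflection at {center} s (width {width} s) does not fit in a "
                f"{beat_duration_s} s beat"
            )
        samples += _raised_cosine(n, fs, center, width, amp)
    t_apex = int(round(morph["t"][0] * fs))
    r_peak = int(round(morph["r"][0] * fs))
    return BeatTemplate(samples, fs, t_apex, r_peak, beat_duration_s)


def make_twa_sequence(pattern: TwaPattern, n_beats: int) -> np.ndarray:
    """Signed per-beat alternans half-amplitudes ``s(n)``.

    The injected consecutive-beat difference ``|s(n) - s(n+1)|`` equals the
    intended alternans amplitude wherever the parity does not flip.  The
    sign alternates beat to beat; for ``phase_reversal`` the parity flips at
    each listed (1-based) beat index, i.e. ``s(rb+1) = s(rb)``.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    n1 = np.arange(1, n_beats + 1)  # 1-based beat numbers
    sign = np.where(n1 % 2 == 1, 1.0, -1.0)
    kind = pattern.kind
    if kind == "none":
        a = np.zeros(n_beats)
    elif kind == "stationary":
        a = np.full(n_beats, float(np.asarray(pattern.amplitude_uv)))
    elif kind == "sinusoidal":
        peak = float(np.asarray(pattern.amplitude_uv))
        a = peak / 2.0 * (1.0 + np.sin(2 * np.pi * n1 / pattern.period_beats))
    elif kind == "cascaded_step":
        hi, lo = (float(v) for v in np.atleast_1d(pattern.amplitude_uv)[:2])
        a = np.full(n_beats, hi)
        t0, w = pattern.transition_start_beat, pattern.transition_beats
        ramp = (n1 >= t0) & (n1 < t0 + w)
        a[ramp] = hi + (lo - hi) * 0.5 * (1 - np.cos(np.pi * (n1[ramp] - t0) / w))
        a[n1 >= t0 + w] = lo
    elif kind == "phase_reversal":
        a = np.full(n_beats, float(np.asarray(pattern.amplitude_uv)))
        parity = np.ones(n_beats)
        for rb in pattern.reversal_beats:
            parity[rb:] *= -1.0  # flip from the (1-based) beat after rb
        sign = sign * parity
    else:  # pragma: no cover - guarded in TwaPattern
        raise ValueError(f"unknown pattern kind {kind!r}")
    return sign * a / 2.0


def _alternans_bump(template: BeatTemplate, window_ms: float) -> np.ndarray:
    """Unit-peak raised-cosine bump of ``window_ms`` centred on the T apex."""
    width_s = window_ms / 1000.0
    center_s = template.t_apex_index / template.fs
    half = width_s / 2.0
    if center_s - half < 0 or center_s + half > template.beat_duration_s:
        raise ValueError(
            f"{window_ms} ms alternans window centred at {center_s} s overruns "
            "the beat boundaries"
        )
    return _raised_cosine(template.n_samples, template.fs, center_s, width_s, 1.0)


def simulate_tracing(
    template: BeatTemplate | None = None,
    pattern: TwaPattern | None = None,
    baseline: BaselineSpec | None = None,
    n_beats: int = 128,
    noise_sd_uv: float = 0.0,
    seed: int = 0,
) -> tuple[EcgTracing, SimTruth]:
    """Concatenate ``n_beats`` template repetitions with injected alternans.

    Returns the tracing (alternans + baseline + optional white noise) and
    the ground truth: the predefined A(n) sequence, its wave-measured
    counterpart, and exact fiducials (R-peak sample of every beat).
    """
    template = template or make_beat_template()
    pattern = pattern or TwaPattern()
    s = make_twa_sequence(pattern, n_beats)
    bump = _alternans_bump(template, pattern.window_ms)

    beats = template.samples[None, :] + s[:, None] * bump[None, :]
    clean = beats.ravel()

    # truth measured from the clean injected waves (consecutive-beat max
    # absolute difference over the alternans window; §: last beat inherits)
    a_meas = np.abs(np.diff(s)) * bump.max()
    a_meas = np.append(a_meas, a_meas[-1])

    x = clean.copy()
    t = np.arange(x.size) / template.fs
    if baseline is not None and baseline.amplitude_mv > 0 and baseline.freq_hz != 0:
        x = x + baseline.amplitude_mv * 1000.0 * np.sin(
            2 * np.pi * baseline.freq_hz * t + baseline.phase_rad
        )
    if noise_sd_uv > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_uv, x.size)

    qrs = template.r_peak_index + template.n_samples * np.arange(n_beats)
    fid = Fiducials.from_samples(qrs, template.fs)
    truth = SimTruth(
        a_n=np.abs(2.0 * s),
        a_n_measured=a_meas,
        s_n=s,
        fiducials=fid,
        n_beats=n_beats,
    )
    return EcgTracing(x, template.fs), truth
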