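"""Standardized current-clamp stimulus waveforms.

Four stimulus families drive GLIF fitting and testing:

* band-limited pink noise (1/f power between 1 and 100 Hz, coefficient of
  variation 0.2) delivered at sub-, peri- and supra-threshold base amplitudes,
* a 3 ms short square pulse used to read off the instantaneous threshold,
* a 1 s sub-threshold long square used to estimate intrinsic membrane noise,
* "triple short squares" — three 3 ms pulses at a fixed inter-pulse interval,
  repeated at several intervals, used to fit spike-driven threshold dynamics.

All generators are pure functions of their arguments (including the seed) and
return :class:`StimulusEpoch` objects in SI units (amperes, seconds, Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusEpoch",
    "SHORT_SQUARE_WIDTH",
    "make_pink_noise",
    "make_square_pulse",
    "make_triple_short_square",
    "assemble_noise_protocol",
]

#: Canonical short-square pulse width (seconds).
SHORT_SQUARE_WIDTH = 3e-3

#: Pink-noise pass band in Hz.
NOISE_BAND = (1.0, 100.0)

#: Target coefficient of variation (std / mean) of a noise epoch.
NOISE_CV = 0.2


@dataclass
class StimulusEpoch:
    """One stimulus epoch: a current waveform sampled at ``fs``.

    Sample ``i`` covers the half-open interval ``[i/fs, (i+1)/fs)``.
    """

    name: str
    current: np.ndarray  # amperes
    fs: float  # Hz
    base_amplitude: float = 0.0  # amperes
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("stimulus current contains non-finite values")

    @property
    def duration(self) -> float:
        return self.current.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.current.size) / self.fs


def make_pink_noise(
    base_amplitude: float,
    duration: float = 3.0,
    fs: float = 10_000.0,
    seed: int = 0,
) -> StimulusEpoch:
    """Band-limited pink-noise current epoch.

    Synthesized in the frequency domain: unit-variance Gaussian spectral
    coefficients are shaped by ``1/sqrt(f)`` inside [1, 100] Hz and zeroed
    outside, inverse-transformed, and then affinely rescaled so that the
    epoch has mean ``base_amplitude`` and std ``0.2 * |base_amplitude|``
    exactly.  Power (excluding DC) therefore follows 1/f restricted to the
    pass band, and the per-epoch CV is 0.2 by construction.

    Parameters
    ----------
    base_amplitude : amperes. Must be nonzero (the CV is relative to it).
    duration : seconds.
    fs : sampling rate in Hz; must be at least twice the 100 Hz band edge.
    seed : RNG seed; identical seeds give bit-identical waveforms.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if base_amplitude == 0:
        raise ValueError("base_amplitude must be nonzero")
    if fs < 2 * NOISE_BAND[1]:
        raise ValueError(f"fs must be at least {2 * NOISE_BAND[1]} Hz")

    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = NOISE_BAND
    band = (freqs >= lo) & (freqs <= hi)

    coeffs = np.zeros(freqs.size, dtype=complex)
    k = int(band.sum())
    phases = rng.normal(size=k) + 1j * rng.normal(size=k)
    coeffs[band] = phases / np.sqrt(np.maximum(freqs[band], lo))
    x = np.fft.irfft(coeffs, n=n)

    sd = x.std()
    if sd == 0:  # pragma: no cover - band always non-empty for valid fs
        raise ValueError("degenerate noise draw")
    x = base_amplitude + (x - x.mean()) * (NOISE_CV * abs(base_amplitude) / sd)
    return StimulusEpoch(
        name="pink_noise",
        current=x,
        fs=fs,
        base_amplitude=base_amplitude,
        seed=seed,
        meta={"band_hz": NOISE_BAND, "cv": NOISE_CV},
    )


def make_square_pulse(
    amplitude: float,
    width: float,
    onset: float,
    total: float,
    fs: float,
    name: str = "square",
) -> StimulusEpoch:
    """Rectangular current pulse: ``amplitude`` on [onset, onset+width), else 0."""
    if width <= 0:
        raise ValueError("width must be positive")
    if fs <= 0 or total <= 0:
        raise ValueError("fs and total duration must be positive")
    if onset < 0 or onset + width > total + 0.5 / fs:
        raise ValueError("pulse [onset, onset+width) must fit inside total duration")
    n = int(round(total * fs))
    i0 = int(round(onset * fs))
    i1 = int(round((onset + width) * fs))
    current = np.zeros(n)
    current[i0:i1] = amplitude
    return StimulusEpoch(
        name=name,
        current=current,
        fs=fs,
        base_amplitude=amplitude,
        meta={"onset_s": onset, "width_s": width},
    )


def make_triple_short_square(
    amplitude: float,
    inter_pulse_interval: float | None = None,
    fs: float = 10_000.0,
    n_sets: int = 3,
    intervals: tuple[float, ...] | None = None,
    pulse_width: float = SHORT_SQUARE_WIDTH,
    pre: float = 0.1,
    post: float = 0.2,
) -> list[StimulusEpoch]:
    """Triple-short-square epochs: three ``pulse_width`` pulses per epoch.

    Either a single ``inter_pulse_interval`` (n_sets epochs at onset-to-onset
    intervals interval, 2*interval, 4*interval, ...) or an explicit tuple of
    ``intervals`` may be given.  Intervals are measured onset-to-onset and
    must exceed the pulse width.
    """
    if intervals is None:
        if inter_pulse_interval is None:
            intervals = tuple(0.01 * 2**i for i in range(n_sets))
        else:
            intervals = tuple(inter_pulse_interval * 2**i for i in range(n_sets))
    intervals = tuple(float(v) for v in intervals)
    for iv in intervals:
        if iv <= pulse_width:
            raise ValueError("inter-pulse interval must exceed the pulse width")

    epochs = []
    for iv in intervals:
        total = pre + 2 * iv + pulse_width + post
        n = int(round(total * fs))
        current = np.zeros(n)
        onsets = [pre + m * iv for m in range(3)]
        for t_on in onsets:
            i0 = int(round(t_on * fs))
            i1 = int(round((t_on + pulse_width) * fs))
            current[i0:i1] = amplitude
        epochs.append(
            StimulusEpoch(
                name="triple_short_square",
                current=current,
                fs=fs,
                base_amplitude=amplitude,
                meta={"interval_s": iv, "onsets_s": onsets, "width_s": pulse_width},
            )
        )
    return epochs


def assemble_noise_protocol(
    threshold_amplitude: float,
    duration: float = 3.0,
    fs: float = 10_000.0,
    seed: int = 0,
    fractions: tuple[float, ...] = (0.75, 1.0, 1.25),
    gap: float = 5.0,
    concatenate: bool = False,
) -> list[StimulusEpoch] | StimulusEpoch:
    """Noise epochs at 75/100/125 % of a threshold amplitude.

    The same seeded waveform shape is scaled to each base amplitude (the
    experimental protocol scales one noise realization); epochs are separated
    by ``gap`` seconds of zero current when ``concatenate`` is True.
    """
    epochs = []
    for frac in fractions:
        ep = make_pink_noise(threshold_amplitude * frac, duration, fs, seed)
        ep.meta["fraction_of_threshold"] = frac
        epochs.append(ep)
    if not concatenate:
        return epochs
    n_gap = int(round(gap * fs))
    pieces: list[np.ndarray] = []
    for i, ep in enumerate(epochs):
        if i:
            pieces.append(np.zeros(n_gap))
        pieces.append(ep.current)
    return StimulusEpoch(
        name="noise_protocol",
        current=np.concatenate(pieces),
        fs=fs,
        base_amplitude=threshold_amplitude,
        seed=seed,
        meta={"fractions": fractions, "gap_s": gap, "epoch_s": duration},
    )
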