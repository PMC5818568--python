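"""Ground-truth GLIF populations and protocol-complete synthetic recordings.

The synthesizer emulates the standardized current-clamp protocol used to fit
and test GLIF models, so every pipeline stage can be exercised end-to-end on
cells whose parameters are known exactly:

* two seeds of band-limited pink noise ("noise1" for training, "noise2" for
  hold-out testing), each repeated, at 75/100/125 % of the cell's long-pulse
  rheobase, with a rest period before the epoch;
* a ladder of 3 ms short squares bracketing the instantaneous threshold;
* a 1 s sub-threshold long square for the intrinsic-noise estimate;
* triple short squares at several inter-pulse intervals;
* optionally, 1 s current steps (hyperpolarizing -10..-90 pA and a
  depolarizing ladder) for electrophysiological feature extraction.

Measurement model: intrinsic membrane noise is injected into the integration
as an AR(1)-consistent voltage kick with a chosen stationary sd, so repeated
sweeps have jittered spike times and the long-square noise estimator recovers
the sd; a smaller additive band-limited recording noise (noise_sd / 8,
~kHz bandwidth) sits on top of the trace, so regressions on recorded voltages
face realistic residuals.  A stereotyped spike waveform (rise to a peak, fall to a trough,
relaxation to the model's reset voltage) with seeded per-spike shape jitter
is pasted over each spike-cut window; the underlying GLIF dynamics are
untouched outside the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GLIFParameters, simulate
from .stimulus import (
    SHORT_SQUARE_WIDTH,
    StimulusEpoch,
    make_pink_noise,
    make_square_pulse,
    make_triple_short_square,
)
from .sweeps import Sweep

__all__ = [
    "Archetype",
    "SyntheticCell",
    "DEFAULT_ARCHETYPES",
    "sample_population",
    "synthesize_sweeps",
    "paste_spike_waveforms",
]

#: Default recording sampling rate (Hz).
DEFAULT_FS = 10_000.0

#: Default intrinsic-noise stationary sd (volts).
DEFAULT_NOISE_SD = 0.2e-3


@dataclass(frozen=True)
class Archetype:
    """A cell archetype: per-parameter Gaussian spec over GLIF parameters.

    ``means``/``sds`` are keyed by GLIFParameters field names (SI units);
    ``k`` (the after-spike-current rate pair) is drawn without noise since
    rates come from a discrete library.  For planted-partition fixtures,
    distinct archetypes should differ in at least two parameter means by at
    least two pooled sd.
    """

    name: str
    level: int
    means: dict[str, float]
    sds: dict[str, float]
    k: tuple[float, float] = (100.0, 10.0)
    excitability: str = "regular"

    def sample(self, rng: np.random.Generator) -> GLIFParameters:
        draw = {}
        for key, mu in self.means.items():
            sd = self.sds.get(key, 0.0)
            val = rng.normal(mu, sd) if sd > 0 else mu
            # keep scale parameters physical
            if key in ("C", "R", "spike_cut", "b_s", "b_v") and val <= 0:
                val = max(val, 0.1 * abs(mu))
            draw[key] = val
        d1 = draw.pop("delta_I_1", 0.0)
        d2 = draw.pop("delta_I_2", 0.0)
        theta = draw.pop("theta_inf")
        e_l = draw.pop("E_L")
        if theta <= e_l:  # pragma: no cover - archetypes keep wide margins
            theta = e_l + 1e-3
        return GLIFParameters(
            level=self.level,
            E_L=e_l,
            theta_inf=theta,
            delta_I=(d1, d2),
            k=self.k,
            **draw,
        )


def _arch(name, level, k, excitability, **mean_sd) -> Archetype:
    means = {key: ms[0] for key, ms in mean_sd.items()}
    sds = {key: ms[1] for key, ms in mean_sd.items()}
    return Archetype(name=name, level=level, means=means, sds=sds, k=k, excitability=excitability)


#: Four well-separated archetype profiles (level-3 mechanisms and above).
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    _arch(
        "fast_spiking",
        3,
        (333.0, 33.3),
        "fast",
        C=(60e-12, 4e-12),
        R=(150e6, 10e6),
        E_L=(-72e-3, 1.2e-3),
        theta_inf=(-48e-3, 1.2e-3),
        spike_cut=(1.5e-3, 0.15e-3),
        delta_I_1=(-12e-12, 1.2e-12),
        delta_I_2=(-2e-12, 0.3e-12),
    ),
    _arch(
        "adapting_excitatory",
        3,
        (100.0, 10.0),
        "adapting",
        C=(200e-12, 12e-12),
        R=(120e6, 8e6),
        E_L=(-76e-3, 1.2e-3),
        theta_inf=(-44e-3, 1.2e-3),
        spike_cut=(5e-3, 0.4e-3),
        delta_I_1=(-40e-12, 3e-12),
        delta_I_2=(-8e-12, 0.8e-12),
    ),
    _arch(
        "bursting",
        3,
        (333.0, 33.3),
        "bursting",
        C=(120e-12, 8e-12),
        R=(250e6, 15e6),
        E_L=(-68e-3, 1.2e-3),
        theta_inf=(-42e-3, 1.2e-3),
        spike_cut=(3e-3, 0.25e-3),
        delta_I_1=(15e-12, 1.5e-12),
        delta_I_2=(-6e-12, 0.6e-12),
    ),
    _arch(
        "delayed",
        3,
        (100.0, 10.0),
        "delayed",
        C=(150e-12, 10e-12),
        R=(80e6, 5e6),
        E_L=(-80e-3, 1.2e-3),
        theta_inf=(-50e-3, 1.2e-3),
        spike_cut=(4e-3, 0.3e-3),
        delta_I_1=(-20e-12, 2e-12),
        delta_I_2=(4e-12, 0.5e-12),
    ),
)


@dataclass
class SyntheticCell:
    """Ground-truth parameters plus (after synthesis) the full sweep set."""

    params: GLIFParameters
    seed: int
    noise_sd: float = DEFAULT_NOISE_SD
    fs: float = DEFAULT_FS
    archetype: str | None = None
    measurement_noise_sd: float | None = None  # defaults to noise_sd / 8
    sweeps: dict[str, list[Sweep]] = field(default_factory=dict)

    @property
    def recording_noise_sd(self) -> float:
        """Additive band-limited recording noise on top of the intrinsic noise.

        Kept well below the intrinsic scale so the total stays within the
        nominal noise budget of the protocol.
        """
        if self.measurement_noise_sd is None:
            return self.noise_sd / 8.0
        return self.measurement_noise_sd

    @property
    def rheobase(self) -> float:
        """Long-pulse rheobase (theta_inf - E_L)/R in amperes."""
        p = self.params
        return (p.theta_inf - p.E_L) / p.R

    @property
    def short_square_rheobase(self) -> float:
        """Amplitude for a 3 ms pulse to just reach threshold from rest."""
        p = self.params
        reach = -np.expm1(-SHORT_SQUARE_WIDTH / p.tau_m)
        return (p.theta_inf - p.E_L) / (p.R * reach)


def sample_population(
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES,
    n_per_archetype: int = 10,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    fs: float = DEFAULT_FS,
) -> list[SyntheticCell]:
    """Draw a reproducible synthetic population (no sweeps synthesized yet)."""
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be at least 1")
    rng = np.random.default_rng(seed)
    cells = []
    for arch in archetypes:
        if not isinstance(arch, Archetype):
            raise TypeError("archetypes must be Archetype instances")
        for _ in range(n_per_archetype):
            params = arch.sample(rng)
            cells.append(
                SyntheticCell(
                    params=params,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise_sd=noise_sd,
                    fs=fs,
                    archetype=arch.name,
                )
            )
    return cells


def paste_spike_waveforms(
    voltage: np.ndarray,
    spike_indices: np.ndarray,
    n_cut: int,
    fs: float,
    rng: np.random.Generator,
    peak_height: float = 40e-3,
    trough_drop: float = 10e-3,
    shape_jitter_sd: float = 3e-3,
) -> np.ndarray:
    """Overwrite each spike-cut window with a stereotyped spike waveform.

    The waveform rises from the threshold-crossing voltage to a peak
    (~``peak_height`` above it) in ~0.1 ms — an action-potential-like
    upstroke of several hundred V/s, well clear of passive charging slopes —
    falls to a fast trough below the reset voltage over ~0.4 ms, then relaxes
    linearly toward the reset voltage at the end of the window.  Peak and
    trough carry seeded per-spike jitter: real spike shapes vary nonlinearly
    from spike to spike, and this variability is what makes the spike-cut
    length identifiable from the pre/post-spike regression.
    """
    v = voltage.copy()
    n = v.size
    for i in np.asarray(spike_indices, dtype=int):
        j = min(i + n_cut, n - 1)
        w = j - i
        if w < 2:
            continue
        v_cross = voltage[i]
        v_reset = voltage[j]
        n_rise = max(1, min(int(round(0.1e-3 * fs)), w // 3))
        n_fall = max(1, min(int(round(0.4e-3 * fs)), max(1, w // 3)))
        peak = v_cross + peak_height + rng.normal(0.0, shape_jitter_sd)
        trough = min(v_reset, v_cross) - trough_drop + rng.normal(0.0, shape_jitter_sd / 2)
        knots_x = [0, n_rise, min(n_rise + n_fall, w), w]
        knots_y = [v_cross, peak, trough, v_reset]
        v[i:j] = np.interp(np.arange(w), knots_x, knots_y)
    return v


def _ar1_noise(
    n: int,
    sd: float,
    fs: float,
    rng: np.random.Generator,
    tau: float = 1e-4,
) -> np.ndarray:
    """Band-limited recording noise: AR(1) with ~0.1 ms correlation time.

    Patch-clamp rigs low-pass the signal (Bessel filters in the kHz range);
    unfiltered white noise at the sample rate would put unphysical power into
    dV/dt and defeat slope-based spike detection.
    """
    a = np.exp(-1.0 / (fs * tau))
    kicks = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
    out = np.empty(n)
    x = 0.0
    for i in range(n):
        x = a * x + kicks[i]
        out[i] = x
    return out


def _render(
    cell: SyntheticCell,
    epoch: StimulusEpoch,
    kind: str,
    rng: np.random.Generator,
    shape_rng: np.random.Generator,
    extra_meta: dict | None = None,
) -> Sweep:
    """Simulate the ground-truth model over an epoch and dress the trace."""
    res = simulate(
        cell.params,
        epoch,
        noise_sd=cell.noise_sd,
        rng=rng,
    )
    fs = epoch.fs
    n_cut = max(1, int(round(cell.params.spike_cut * fs)))
    v = paste_spike_waveforms(res.voltage, res.spike_indices, n_cut, fs, shape_rng)
    if cell.recording_noise_sd > 0:
        v = v + _ar1_noise(v.size, cell.recording_noise_sd, fs, rng)
    meta = {
        "kind": kind,
        "true_spike_idx": res.spike_indices.tolist(),
        "n_cut": n_cut,
        **(epoch.meta or {}),
        **(extra_meta or {}),
    }
    return Sweep(fs=fs, current=epoch.current, voltage=v, name=kind, meta=meta)


def _with_rest(epoch: StimulusEpoch, rest: float, tail: float) -> StimulusEpoch:
    """Pad an epoch with zero-current rest before and after the stimulus."""
    n_pre = int(round(rest * epoch.fs))
    n_post = int(round(tail * epoch.fs))
    current = np.concatenate([np.zeros(n_pre), epoch.current, np.zeros(n_post)])
    meta = dict(epoch.meta)
    meta["stim_window"] = [n_pre, n_pre + epoch.n_samples]
    return StimulusEpoch(
        name=epoch.name,
        current=current,
        fs=epoch.fs,
        base_amplitude=epoch.base_amplitude,
        seed=epoch.seed,
        meta=meta,
    )


def synthesize_sweeps(
    cell: SyntheticCell,
    noise_duration: float = 3.0,
    n_noise_repeats: int = 2,
    noise_fractions: tuple[float, ...] = (0.75, 1.0, 1.25),
    noise1_seed: int = 101,
    noise2_seed: int = 202,
    rest: float = 0.5,
    triple_intervals: tuple[float, ...] = (0.01, 0.02, 0.04),
    triple_amplitude_factor: float = 1.5,
    include_steps: bool = False,
    max_amplitude_retries: int = 3,
    pulse_fs: float = 100_000.0,
) -> SyntheticCell:
    """Synthesize the full protocol for a cell; returns the cell with sweeps.

    The supra-threshold noise epoch must evoke spikes (the after-spike-current
    and threshold fits need them); if it does not, its amplitude is raised by
    25 % steps with a warning, up to ``max_amplitude_retries`` times.

    Short-square and triple-short-square sweeps are rendered at ``pulse_fs``
    (threshold-probing protocols are acquired at high rates experimentally;
    the fast crossings would otherwise be quantized to the sample grid),
    while noise and step sweeps use the cell's recording rate.
    """
    fs = cell.fs
    rng = np.random.default_rng(cell.seed)
    shape_rng = np.random.default_rng(cell.seed + 1)
    rheo = cell.rheobase
    sweeps: dict[str, list[Sweep]] = {}

    # --- pink-noise training (noise1) and hold-out (noise2) epochs -------
    for label, stim_seed in (("noise1", noise1_seed), ("noise2", noise2_seed)):
        group: list[Sweep] = []
        for frac in noise_fractions:
            amp = rheo * frac
            epoch = _with_rest(
                make_pink_noise(amp, noise_duration, fs, stim_seed), rest, 0.2
            )
            epoch.meta["fraction_of_threshold"] = frac
            retries = 0
            while True:
                repeats = [
                    _render(
                        cell,
                        epoch,
                        label,
                        rng,
                        shape_rng,
                        {"repeat": r, "fraction_of_threshold": frac},
                    )
                    for r in range(n_noise_repeats)
                ]
                if frac <= 1.0 or any(len(s.meta["true_spike_idx"]) for s in repeats):
                    break
                retries += 1
                if retries > max_amplitude_retries:
                    break
                warnings.warn(
                    f"supra-threshold noise epoch evoked no spikes; raising "
                    f"amplitude (retry {retries})",
                    stacklevel=2,
                )
                amp *= 1.25
                epoch = _with_rest(
                    make_pink_noise(amp, noise_duration, fs, stim_seed), rest, 0.2
                )
                epoch.meta["fraction_of_threshold"] = frac
            group.extend(repeats)
        sweeps[label] = group

    # --- short-square threshold ladder -----------------------------------
    ss_rheo = cell.short_square_rheobase
    ladder = np.linspace(0.8, 1.6, 9) * ss_rheo
    sweeps["short_square"] = [
        _render(
            cell,
            make_square_pulse(a, SHORT_SQUARE_WIDTH, 0.1, 0.25, pulse_fs, name="short_square"),
            "short_square",
            rng,
            shape_rng,
            {"amplitude_A": float(a)},
        )
        for a in ladder
    ]

    # --- sub-threshold long square (intrinsic-noise estimate) -------------
    amp = 0.9 * rheo
    for _ in range(max_amplitude_retries + 1):
        ls = _render(
            cell,
            make_square_pulse(amp, 1.0, 0.2, 1.4, fs, name="long_square"),
            "long_square",
            rng,
            shape_rng,
            {"amplitude_A": float(amp)},
        )
        if not ls.meta["true_spike_idx"]:
            break
        amp *= 0.85
        warnings.warn("sub-threshold long square evoked spikes; lowering amplitude", stacklevel=2)
    sweeps["long_square"] = [ls]

    # --- triple short squares ---------------------------------------------
    sweeps["triple"] = [
        _render(cell, ep, "triple", rng, shape_rng)
        for ep in make_triple_short_square(
            triple_amplitude_factor * ss_rheo,
            fs=pulse_fs,
            intervals=triple_intervals,
        )
    ]

    # --- one-second current steps for feature extraction ------------------
    if include_steps:
        step_amps = [a * 1e-12 for a in (-10, -30, -50, -70, -90)]
        step_amps += [f * rheo for f in (0.75, 1.0, 1.25, 1.5, 2.0)]
        sweeps["steps"] = [
            _render(
                cell,
                make_square_pulse(a, 1.0, 0.25, 1.5, fs, name="step"),
                "step",
                rng,
                shape_rng,
                {"amplitude_A": float(a), "onset_s": 0.25, "width_s": 1.0},
            )
            for a in step_amps
        ]

    cell.sweeps = sweeps
    return cell
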