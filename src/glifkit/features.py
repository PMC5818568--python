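"""Intrinsic electrophysiology features from one-second current steps.

Fourteen features summarize a cell's sub- and supra-threshold behavior for
feature-based clustering: membrane time constant, input resistance, resting
potential, sag (from hyperpolarizing steps); threshold current, spike
threshold/peak/fast-trough/trough voltages and upstroke:downstroke ratios
(from spiking responses to long and short squares); and f-I curve slope,
first-spike latency and maximum burst index (from the depolarizing step
family).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import curve_fit

from .fitting import InsufficientDataError, detect_spikes
from .sweeps import Sweep

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "subthreshold_features",
    "spike_shape_features",
    "firing_pattern_features",
    "extract_features",
]


@dataclass
class FeatureVector:
    tau_m: float = np.nan  # seconds
    R_i: float = np.nan  # ohms
    V_rest: float = np.nan  # volts
    I_thresh: float = np.nan  # amperes
    V_thresh: float = np.nan  # volts
    V_peak: float = np.nan  # volts
    V_fasttrough: float = np.nan  # volts
    V_trough: float = np.nan  # volts
    updownstroke_long: float = np.nan
    updownstroke_short: float = np.nan
    sag: float = np.nan
    fI_slope: float = np.nan  # Hz per ampere
    latency: float = np.nan  # seconds
    max_burst_index: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))


def _step_window(sweep: Sweep) -> tuple[int, int, float]:
    """(onset sample, offset sample, amplitude) of a square step sweep."""
    meta = sweep.meta
    fs = sweep.fs
    if "onset_s" in meta and "width_s" in meta:
        i0 = int(round(meta["onset_s"] * fs))
        i1 = i0 + int(round(meta["width_s"] * fs))
    else:
        nz = np.flatnonzero(sweep.current != 0)
        if nz.size == 0:
            return 0, sweep.n_samples, 0.0
        i0, i1 = int(nz[0]), int(nz[-1]) + 1
    amp = float(meta.get("amplitude_A", sweep.current[i0]))
    return i0, i1, amp


def subthreshold_features(
    hyperpolarizing_sweeps: list[Sweep],
    min_tau_deflection: float = 3e-3,
) -> tuple[float, float, float, float]:
    """(tau_m, R_i, V_rest, sag) from hyperpolarizing one-second steps.

    tau_m averages single-exponential fits from 10 % of the maximum voltage
    deflection to the maximum deflection; R_i is the slope of peak deflection
    versus step amplitude; V_rest the pre-stimulus mean; sag is computed on
    the step whose minimum is closest to -100 mV as
    (minimum - steady) / (minimum - baseline).  Steps deflecting less than
    ``min_tau_deflection`` are too noise-dominated for a stable exponential
    fit and are skipped for tau_m (they still enter R_i).
    """
    steps = [s for s in hyperpolarizing_sweeps if _step_window(s)[2] < 0]
    if len(steps) < 2:
        raise InsufficientDataError("sub-threshold features require >= 2 hyperpolarizing steps")

    taus, deflections, amps, rests = [], [], [], []
    sag_candidates = []
    for sweep in steps:
        i0, i1, amp = _step_window(sweep)
        v = sweep.voltage
        fs = sweep.fs
        base = float(v[:i0].mean()) if i0 else float(v[0])
        seg = v[i0:i1]
        # locate the extremum on a lightly smoothed copy so recording noise
        # does not pull it into the steady-state plateau
        w = max(1, int(round(1e-3 * fs)))
        smooth = np.convolve(seg, np.ones(w) / w, mode="same")
        min_idx = int(np.argmin(smooth))
        v_min = float(smooth[min_idx])
        defl = v_min - base
        steady = float(seg[-max(1, int(0.1 * seg.size)) :].mean())
        deflections.append(defl)
        amps.append(amp)
        rests.append(base)
        sag_candidates.append((abs(v_min + 100e-3), v_min, steady, base))

        if abs(defl) < min_tau_deflection:
            continue
        # single-exponential fit from the 10 %-deflection crossing over the
        # transient, with the asymptote anchored at the measured steady
        # state (a free asymptote trades off against tau under correlated
        # recording noise); the window ends shortly after the deflection is
        # essentially complete
        crossed = np.flatnonzero(smooth[: min_idx + 1] - base <= 0.1 * defl)
        full = np.flatnonzero(smooth[: min_idx + 1] - base <= 0.95 * defl)
        if crossed.size == 0 or full.size == 0:
            continue
        j0, j1 = int(crossed[0]), int(full[0])
        if j1 - j0 < 5:
            continue
        j1 = min(j0 + 2 * (j1 - j0), seg.size)
        t = np.arange(j1 - j0) / fs
        y = seg[j0:j1]
        try:
            popt, _ = curve_fit(
                lambda tt, b, tau: steady + b * np.exp(-tt / tau),
                t,
                y,
                p0=(base - steady, max((j1 - j0) / (4 * fs), 1e-3)),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        if 1e-4 < popt[1] < 1.0:
            taus.append(popt[1])

    slope = np.polyfit(amps, deflections, 1)[0]
    _, v_min, steady, base = min(sag_candidates)
    denom = v_min - base
    sag = float((v_min - steady) / denom) if abs(denom) > 1e-9 else 0.0
    tau_m = float(np.mean(taus)) if taus else np.nan
    return tau_m, float(slope), float(np.mean(rests)), max(sag, 0.0)


def _per_spike_shape(sweep: Sweep) -> list[dict]:
    """Per-spike shape measurements on one spiking sweep."""
    anns = detect_spikes(sweep)
    v = sweep.voltage
    fs = sweep.fs
    dv = np.diff(v) * fs
    out = []
    for i, ann in enumerate(anns):
        onset, peak = ann.spike_index, ann.peak_index
        nxt = anns[i + 1].spike_index if i + 1 < len(anns) else v.size
        fast_end = min(peak + int(round(5e-3 * fs)), v.size)
        up = float(dv[onset:peak].max()) if peak > onset else np.nan
        down_seg = dv[peak : min(fast_end, dv.size)]
        down = float(down_seg.min()) if down_seg.size else np.nan
        out.append(
            {
                "V_thresh": ann.threshold_voltage,
                "V_peak": float(v[peak]),
                "V_fasttrough": float(v[peak + 1 : fast_end].min()) if fast_end > peak + 1 else np.nan,
                "V_trough": float(v[peak + 1 : nxt].min()) if nxt > peak + 1 else np.nan,
                "updownstroke": abs(up) / abs(down) if down and np.isfinite(down) and down != 0 else np.nan,
            }
        )
    return out


def spike_shape_features(
    long_square_sweeps: list[Sweep],
    short_square_sweeps: list[Sweep] | None = None,
) -> tuple[float, float, float, float, float, float, float]:
    """(I_thresh, V_thresh, V_peak, V_fasttrough, V_trough, up:down long, up:down short).

    I_thresh is the minimal one-second step amplitude evoking at least one
    spike; the per-spike voltage measures are averaged over all spikes of
    the spiking long-square sweeps.
    """
    spiking = []
    for sweep in long_square_sweeps:
        _, _, amp = _step_window(sweep)
        if amp <= 0:
            continue
        shapes = _per_spike_shape(sweep)
        if shapes:
            spiking.append((amp, shapes))
    if not spiking:
        raise InsufficientDataError("spike-shape features require a spiking long-square sweep")
    i_thresh = min(a for a, _ in spiking)
    pooled = [d for _, shapes in spiking for d in shapes]

    def mean_of(key):
        vals = [d[key] for d in pooled if np.isfinite(d[key])]
        return float(np.mean(vals)) if vals else np.nan

    ud_short = np.nan
    if short_square_sweeps:
        short_pool = [d for s in short_square_sweeps for d in _per_spike_shape(s)]
        vals = [d["updownstroke"] for d in short_pool if np.isfinite(d["updownstroke"])]
        if vals:
            ud_short = float(np.mean(vals))
    return (
        float(i_thresh),
        mean_of("V_thresh"),
        mean_of("V_peak"),
        mean_of("V_fasttrough"),
        mean_of("V_trough"),
        mean_of("updownstroke"),
        ud_short,
    )


def _burst_index(sweep: Sweep) -> float:
    """Burst index from the change of post-spike voltage trajectory.

    Each inter-spike interval is classed "direct" (membrane potential rising
    through the first quarter of the interval after the spike cut) or
    "delay" (hyperpolarizing first).  When both classes occur, the burst is
    the maximal run of direct intervals and the index is (max in-burst
    instantaneous rate - max out-of-burst rate) / their sum; 0 otherwise.
    """
    anns = detect_spikes(sweep)
    if len(anns) < 3:
        return 0.0
    v = sweep.voltage
    fs = sweep.fs
    onsets = np.array([a.spike_index for a in anns])
    isis = np.diff(onsets) / fs
    ifr = 1.0 / isis  # assigned to the second spike of each pair
    classes = []
    for i in range(len(anns) - 1):
        start = anns[i].cut_window[1]
        end = onsets[i + 1]
        quarter = start + max(2, (end - start) // 4)
        if quarter >= end:
            classes.append("direct")
            continue
        seg = v[start:quarter]
        classes.append("delay" if seg[-1] < seg[0] else "direct")
    classes = np.array(classes)
    if len(set(classes)) < 2:
        return 0.0
    in_burst = classes == "direct"
    f_in = ifr[in_burst].max()
    f_out = ifr[~in_burst].max()
    total = f_in + f_out
    return float((f_in - f_out) / total) if total > 0 else 0.0


def firing_pattern_features(
    long_square_sweeps: list[Sweep],
) -> tuple[float, float, float]:
    """(fI_slope, latency, max_burst_index) from depolarizing steps.

    Firing rate is the spike count over the one-second step; the f-I slope is
    a linear fit over all supra-threshold amplitudes, latency comes from the
    lowest supra-threshold sweep, and the burst index is the maximum over
    supra-threshold sweeps.
    """
    points = []  # (amplitude, rate, latency, burst)
    for sweep in long_square_sweeps:
        i0, i1, amp = _step_window(sweep)
        if amp <= 0:
            continue
        anns = detect_spikes(sweep)
        in_step = [a for a in anns if i0 <= a.spike_index < i1]
        if not in_step:
            continue
        width = (i1 - i0) / sweep.fs
        rate = len(in_step) / width
        lat = (in_step[0].spike_index - i0) / sweep.fs
        points.append((amp, rate, lat, _burst_index(sweep)))
    if not points:
        raise InsufficientDataError("firing-pattern features require a spiking step")
    points.sort()
    latency = points[0][2]
    burst = max(p[3] for p in points)
    if len(points) >= 2:
        amps = np.array([p[0] for p in points])
        rates = np.array([p[1] for p in points])
        slope = float(np.polyfit(amps, rates, 1)[0])
    else:
        slope = np.nan
    return slope, float(latency), float(burst)


def extract_features(
    step_sweeps: list[Sweep],
    short_square_sweeps: list[Sweep] | None = None,
) -> FeatureVector:
    """Full 14-feature vector from a family of one-second step sweeps."""
    hyper = [s for s in step_sweeps if _step_window(s)[2] < 0]
    depol = [s for s in step_sweeps if _step_window(s)[2] > 0]
    fv = FeatureVector()
    if len(hyper) >= 2:
        fv.tau_m, fv.R_i, fv.V_rest, fv.sag = subthreshold_features(hyper)
    try:
        (
            fv.I_thresh,
            fv.V_thresh,
            fv.V_peak,
            fv.V_fasttrough,
            fv.V_trough,
            fv.updownstroke_long,
            fv.updownstroke_short,
        ) = spike_shape_features(depol, short_square_sweeps)
        fv.fI_slope, fv.latency, fv.max_burst_index = firing_pattern_features(depol)
    except InsufficientDataError:
        pass
    return fv
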