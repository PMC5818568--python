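"""Spike-time explained variance, sub-threshold voltage error, exclusions.

Model performance is scored by how much of the temporal variance of the
data's spike times the model explains at a time resolution delta_t
(10 ms by default).  Spike trains are binned into counts; for two trains a
and b the pairwise explained variance is

    pwEV(a, b) = (var a + var b - var(a - b)) / (var a + var b)
               = 2 cov(a, b) / (var a + var b),

which is 1 exactly when the binned vectors are identical (and non-constant).
Because a model cannot be expected to explain the data better than the data
explains itself, the reported metric is the ratio of the mean model-vs-data
pwEV to the mean data-vs-data pwEV across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EVReport",
    "ExclusionDecision",
    "ParameterBounds",
    "bin_spike_train",
    "pairwise_explained_variance",
    "explained_variance_ratio",
    "subthreshold_voltage_error",
    "apply_exclusion_criteria",
    "DEFAULT_DELTA_T",
]

DEFAULT_DELTA_T = 0.01  # seconds


def bin_spike_train(
    spike_times: np.ndarray, delta_t: float, duration: float
) -> np.ndarray:
    """Spike counts per half-open bin [i delta_t, (i+1) delta_t).

    A spike exactly on a bin edge belongs to the right bin; the vector sums
    to the number of spikes inside [0, duration).
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    n_bins = int(np.ceil(duration / delta_t - 1e-12))
    counts = np.zeros(max(n_bins, 1), dtype=float)
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= 0) & (t < duration)]
    if t.size:
        idx = np.floor(t / delta_t).astype(int)
        np.add.at(counts, np.minimum(idx, counts.size - 1), 1.0)
    return counts


def _pw_ev(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var()
    vb = b.var()
    if va + vb == 0:
        return np.nan
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(2.0 * cov / (va + vb))


def pairwise_explained_variance(
    a: np.ndarray,
    b: np.ndarray,
    delta_t: float = DEFAULT_DELTA_T,
    duration: float | None = None,
) -> float:
    """pwEV between two spike trains (times in seconds) or binned vectors.

    If ``duration`` is given the inputs are treated as spike times and binned
    at ``delta_t``; otherwise they must already be count vectors of equal
    length.  Returns NaN when both vectors are constant (undefined).
    """
    if duration is not None:
        a = bin_spike_train(a, delta_t, duration)
        b = bin_spike_train(b, delta_t, duration)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("binned spike vectors must have equal length")
    return _pw_ev(a, b)


@dataclass
class EVReport:
    delta_t: float
    pairwise_model_data: float
    data_data: float
    ratio: float
    flags: list[str] = field(default_factory=list)


def explained_variance_ratio(
    model: np.ndarray,
    data_repeats: list[np.ndarray],
    duration: float | None = None,
    delta_t: float = DEFAULT_DELTA_T,
) -> EVReport:
    """Explained-variance ratio of one model train against data repeats.

    ``model`` and each entry of ``data_repeats`` are spike-time arrays (if
    ``duration`` is given) or pre-binned count vectors.  The numerator is the
    mean pwEV of the model with each repeat; the denominator the mean pwEV
    over all unordered repeat pairs.
    """
    if len(data_repeats) < 2:
        raise ValueError("data explained variance requires at least 2 repeats")
    if duration is not None:
        model = bin_spike_train(model, delta_t, duration)
        data_repeats = [bin_spike_train(r, delta_t, duration) for r in data_repeats]
    model = np.asarray(model, dtype=float)
    data_repeats = [np.asarray(r, dtype=float) for r in data_repeats]

    flags: list[str] = []
    md = [_pw_ev(model, r) for r in data_repeats]
    if np.all(np.isnan(md)):
        flags.append("model-vs-data pwEV undefined (constant vectors)")
        pairwise_model_data = np.nan
    else:
        pairwise_model_data = float(np.nanmean(md))

    dd = [
        _pw_ev(data_repeats[i], data_repeats[j])
        for i in range(len(data_repeats))
        for j in range(i + 1, len(data_repeats))
    ]
    if np.all(np.isnan(dd)):
        flags.append("data-vs-data pwEV undefined (constant vectors)")
        data_data = np.nan
    else:
        data_data = float(np.nanmean(dd))

    if not np.isfinite(data_data) or data_data <= 0:
        flags.append("ratio undefined: data-data explained variance <= 0")
        ratio = np.nan
    elif not np.isfinite(pairwise_model_data):
        ratio = np.nan
    else:
        ratio = pairwise_model_data / data_data
    return EVReport(
        delta_t=delta_t,
        pairwise_model_data=pairwise_model_data,
        data_data=data_data,
        ratio=ratio,
        flags=flags,
    )


def subthreshold_voltage_error(
    model_trace: np.ndarray,
    data_trace: np.ndarray,
    exclude_windows: list[tuple[int, int]] | None = None,
) -> float:
    """RMSE (volts) between traces outside all spike-cut windows."""
    model_trace = np.asarray(model_trace, dtype=float)
    data_trace = np.asarray(data_trace, dtype=float)
    if model_trace.shape != data_trace.shape:
        raise ValueError("traces must have equal length")
    mask = np.ones(model_trace.size, dtype=bool)
    for s, e in exclude_windows or []:
        mask[max(0, int(s)) : min(mask.size, int(e))] = False
    if not mask.any():
        raise ValueError("no sub-threshold samples remain outside spike windows")
    diff = model_trace[mask] - data_trace[mask]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass(frozen=True)
class ParameterBounds:
    """Biological-plausibility bounds used by the exclusion rule."""

    C: tuple[float, float] = (1e-12, 1000e-12)  # farads
    R: tuple[float, float] = (10e6, 3000e6)  # ohms
    theta_minus_el: tuple[float, float] = (1e-3, 60e-3)  # volts


@dataclass
class ExclusionDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)


#: Minimum training (noise 1) explained-variance ratio to retain a model.
EV_RATIO_THRESHOLD = 0.20


def apply_exclusion_criteria(
    params,
    ev_ratio_noise1: float,
    bounds: ParameterBounds = ParameterBounds(),
) -> ExclusionDecision:
    """Drop models with training EV ratio < 20 % or unrealistic parameters."""
    reasons = []
    if not np.isfinite(ev_ratio_noise1) or ev_ratio_noise1 < EV_RATIO_THRESHOLD:
        reasons.append("EV ratio < 20% on noise 1")
    checks = (
        ("C", params.C, bounds.C),
        ("R", params.R, bounds.R),
        ("theta_inf - E_L", params.theta_inf - params.E_L, bounds.theta_minus_el),
    )
    for name, value, (lo, hi) in checks:
        if not (lo <= value <= hi):
            reasons.append(f"unrealistic parameter: {name} = {value:.3g} outside [{lo:.3g}, {hi:.3g}]")
    return ExclusionDecision(keep=not reasons, reasons=reasons)
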