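"""Stage-2 optimization of the instantaneous threshold Theta_inf.

After the linear stage-1 fits, the one remaining free parameter —
Theta_inf, the overall excitability of the model — is refined to maximize
the likelihood of the recorded spike times under a forced-spike paradigm:

* the model is integrated along the training stimulus with its resets
  imposed at the *data* spike times (its own crossings do not reset), which
  makes the membrane-voltage trajectory independent of the threshold and the
  problem convex in the voltage gaps;
* at each data spike the gap between model voltage and total threshold is
  recorded, and between data spikes the largest gap is recorded;
* the objective (MLIN: maximum likelihood based on internal noise) scores
  the gaps against the intrinsic membrane noise scale sigma estimated from
  a sub-threshold long square: a Gaussian term sum gap_i^2 / (2 sigma^2)
  demands the voltage reach threshold exactly at each data spike, and a
  survival term -log Phi(-max_gap / sigma) per inter-spike interval demands
  it stay below threshold in between;
* Nelder-Mead minimizes the objective over Theta_inf alone.

Because the forced-spike voltage trace does not depend on Theta_inf, a
change of threshold shifts every gap by the opposite amount; the forced
simulation therefore runs once per sweep and the optimizer works on the
shifted-gap objective exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.signal import detrend

from ._kernels import glif_forced
from .core import GLIFParameters
from .fitting import SpikeAnnotation, detect_spikes
from .sweeps import Sweep

__all__ = [
    "InternalNoiseModel",
    "ForcedSpikeTrace",
    "estimate_internal_noise",
    "forced_spike_simulation",
    "mlin_objective",
    "optimize_theta_inf",
]

#: Sigma floor (volts) substituted when the noise estimate is degenerate.
SIGMA_FLOOR = 10e-6


@dataclass
class InternalNoiseModel:
    """Scale of intrinsic membrane-potential noise near threshold."""

    sigma: float  # volts
    estimation_window: tuple[int, int] = (0, 0)
    degenerate: bool = False


@dataclass
class ForcedSpikeTrace:
    """Model trajectory with resets imposed at the data spike times."""

    gaps: np.ndarray  # volts; V_model - threshold at each data spike
    between_max_gaps: np.ndarray  # volts; max gap per inter-spike interval
    voltage: np.ndarray
    threshold: np.ndarray
    spike_indices: np.ndarray
    fs: float


def estimate_internal_noise(
    long_square_sweep: Sweep,
    steady_fraction: float = 0.5,
) -> InternalNoiseModel:
    """Estimate sigma from the steady-state part of a sub-threshold pulse.

    Uses the last ``steady_fraction`` of the pulse, removes a linear trend,
    and takes the residual standard deviation.  A sweep containing spikes is
    rejected; a noiseless trace yields a floor value flagged as degenerate.
    """
    if detect_spikes(long_square_sweep):
        raise ValueError("internal-noise sweep must be sub-threshold (no spikes)")
    v = long_square_sweep.voltage
    fs = long_square_sweep.fs
    meta = long_square_sweep.meta
    if "stim_window" in meta:
        lo, hi = (int(x) for x in meta["stim_window"])
    elif "onset_s" in meta and "width_s" in meta:
        lo = int(round(meta["onset_s"] * fs))
        hi = lo + int(round(meta["width_s"] * fs))
    else:
        lo, hi = 0, v.size
    start = hi - int(round((hi - lo) * steady_fraction))
    seg = v[start:hi]
    if seg.size < 10:
        raise ValueError("steady-state window too short for a noise estimate")
    sigma = float(np.std(detrend(seg)))
    degenerate = sigma < SIGMA_FLOOR
    return InternalNoiseModel(
        sigma=max(sigma, SIGMA_FLOOR) if degenerate else sigma,
        estimation_window=(start, hi),
        degenerate=degenerate,
    )


def forced_spike_simulation(
    params: GLIFParameters,
    stimulus: Sweep | np.ndarray,
    data_spike_indices: np.ndarray,
    fs: float | None = None,
) -> ForcedSpikeTrace:
    """Integrate the model with resets imposed at the data spike times.

    Records gap_i = V_model(t_i) - (Theta_inf + Theta_s + Theta_v)(t_i) at
    each data spike, and the maximum gap over every inter-spike interval
    (refractory fills excluded).
    """
    if isinstance(stimulus, Sweep):
        current = stimulus.current
        fs = stimulus.fs
    else:
        current = np.asarray(stimulus, dtype=float)
        if fs is None:
            raise ValueError("fs required for raw current arrays")
    idx = np.asarray(
        sorted(int(i) for i in np.asarray(data_spike_indices).ravel()), dtype=np.int64
    )
    if idx.size and (idx[0] < 0 or idx[-1] >= current.size):
        raise ValueError("data spikes must lie within the stimulus duration")

    p = params.effective()
    h = 1.0 / fs
    n_ref = max(1, int(round(p.spike_cut * fs)))
    V, TH, gaps, in_ref = glif_forced(
        np.ascontiguousarray(current, dtype=float),
        h,
        p.C,
        p.R,
        p.E_L,
        p.theta_inf,
        n_ref,
        p.f_v,
        p.delta_V,
        p.b_s,
        p.delta_theta_s,
        p.k[0],
        p.k[1],
        p.delta_I[0],
        p.delta_I[1],
        p.a_v,
        p.b_v,
        p.E_L,
        0.0,
        0.0,
        0.0,
        0.0,
        np.zeros(current.size),
        idx.astype(np.int64),
    )
    diff = V - TH
    free = in_ref == 0
    bounds = np.concatenate([[0], idx, [current.size]])
    between = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = diff[a:b][free[a:b]]
        if seg.size:
            between.append(float(seg.max()))
    return ForcedSpikeTrace(
        gaps=gaps,
        between_max_gaps=np.asarray(between),
        voltage=V,
        threshold=TH,
        spike_indices=idx,
        fs=fs,
    )


def mlin_objective(
    gaps: np.ndarray | ForcedSpikeTrace,
    between_max_gaps: np.ndarray | None = None,
    noise: InternalNoiseModel | float = None,
) -> float:
    """Negative log-likelihood of the gap pattern under the noise model.

    ``sum gap_i^2 / (2 sigma^2) - sum log Phi(-max_gap_j / sigma)``:
    the first term is the log-density (up to a constant) of the voltage
    reaching threshold exactly at each data spike; the second penalizes any
    inter-spike interval whose maximum gap approaches or exceeds zero.
    Deterministic, and strictly increasing in each |gap_i|.
    """
    if isinstance(gaps, ForcedSpikeTrace):
        trace = gaps
        if between_max_gaps is None:
            between_max_gaps = trace.between_max_gaps
        gaps = trace.gaps
    sigma = noise.sigma if isinstance(noise, InternalNoiseModel) else float(noise)
    if sigma is None or sigma <= 0:
        raise ValueError("degenerate noise model: sigma must be positive")
    gaps = np.asarray(gaps, dtype=float)
    bet = np.asarray(between_max_gaps, dtype=float) if between_max_gaps is not None else np.empty(0)
    at_spike = float((gaps**2).sum()) / (2.0 * sigma**2)
    survival = -float(log_ndtr(-bet / sigma).sum()) if bet.size else 0.0
    return at_spike + survival


@dataclass
class OptimizationTrace:
    iterations: list = field(default_factory=list)  # (n_eval, theta_inf, objective)
    converged: bool = True
    theta_init: float = 0.0
    theta_opt: float = 0.0


def optimize_theta_inf(
    params: GLIFParameters,
    training_sweeps: list[Sweep],
    noise: InternalNoiseModel,
    annotations: list[list[SpikeAnnotation]] | None = None,
    xatol: float = 1e-4,
    frtol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[GLIFParameters, OptimizationTrace]:
    """Nelder-Mead refinement of Theta_inf against the MLIN objective.

    Only Theta_inf changes; every other parameter is left untouched.  The
    objective is summed over all training sweeps (and repeats).  On simplex
    collapse without convergence the best value so far is returned with a
    warning.
    """
    if annotations is None:
        annotations = [detect_spikes(s) for s in training_sweeps]
    traces = []
    for sweep, anns in zip(training_sweeps, annotations):
        idx = np.array([a.spike_index for a in anns], dtype=np.int64)
        traces.append(forced_spike_simulation(params, sweep, idx))

    theta0 = params.theta_inf
    log: list = []

    def objective(x: np.ndarray) -> float:
        shift = float(x[0]) - theta0  # raising Theta_inf lowers every gap
        total = 0.0
        for tr in traces:
            total += mlin_objective(tr.gaps - shift, tr.between_max_gaps - shift, noise)
        log.append((len(log), float(x[0]), total))
        return total

    f0 = objective(np.array([theta0]))
    res = minimize(
        objective,
        x0=np.array([theta0]),
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            "fatol": frtol * max(abs(f0), 1.0),
            "maxiter": max_iter,
            "initial_simplex": np.array([[theta0], [theta0 + 2e-3]]),
        },
    )
    if not res.success:
        warnings.warn(
            "Nelder-Mead did not converge; returning best Theta_inf so far",
            stacklevel=2,
        )
    best_theta = float(res.x[0])
    trace = OptimizationTrace(
        iterations=log,
        converged=bool(res.success),
        theta_init=theta0,
        theta_opt=best_theta,
    )
    return dataclasses.replace(params, theta_inf=best_theta), trace
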