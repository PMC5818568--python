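"""Stage-1 linear parameter extraction from training sweeps.

Every GLIF parameter is fit directly from the data with linear methods:

* ``E_L`` — mean membrane potential at rest before the training noise;
* ``Theta_inf`` (initial value) — spike-onset voltage of the lowest-amplitude
  spiking short-square sweep;
* ``delta_t``, ``f_v``, ``delta_V`` — from a pre/post-spike voltage
  regression: for each candidate post-spike offset up to 10 ms, the voltage
  after the spike is regressed on the voltage at spike onset across all
  pooled spikes; the offset minimizing the squared residuals is the spike
  cut length, the slope and intercept give the voltage reset rule;
* ``R``, ``C`` — least squares on C dV/dt = I_e - (V - E_L)/R over
  sub-threshold samples;
* ``delta_I_j``, ``k_j``, ``R_ASC`` — linear regression of dV/dt on
  stereotyped post-spike exponential regressors for every pair from a
  discrete library of decay rates; the pair with minimal residual sum of
  squares wins;
* ``b_s``, ``delta_Theta_s`` — decaying-exponential fit to the threshold
  elevation of subsequent spikes in triple-short-square sweeps;
* ``a_v``, ``b_v`` — least squares of observed spike-onset thresholds
  against the voltage-dependent threshold component integrated along the
  recorded voltage (linear in a_v; 1-D search over b_v).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._kernels import exp_regressor, voltage_threshold_filter
from .core import GLIFParameters, LEVEL_MECHANISMS
from .sweeps import Sweep

__all__ = [
    "SpikeAnnotation",
    "SpikeCutFit",
    "ASCFit",
    "ThresholdSpikeFit",
    "ThresholdVoltageFit",
    "InsufficientDataError",
    "DegenerateInputError",
    "detect_spikes",
    "fit_spike_cut_and_reset",
    "fit_resting_potential",
    "fit_membrane_rc",
    "fit_after_spike_currents",
    "fit_spike_threshold_dynamics",
    "fit_voltage_threshold_dynamics",
    "fit_instantaneous_threshold_init",
    "fit_cell",
    "FitResult",
    "DEFAULT_K_LIBRARY",
]

#: Default after-spike-current decay-rate library (1/s): 1 ms to 100 ms scales.
DEFAULT_K_LIBRARY = (1000.0, 333.0, 100.0, 33.3, 10.0)

#: Maximum spike-cut length considered (seconds).
MAX_SPIKE_CUT = 10e-3


class InsufficientDataError(ValueError):
    """Raised when a fit lacks the data it requires (the message names it)."""


class DegenerateInputError(ValueError):
    """Raised when a regression design is singular."""


@dataclass
class SpikeAnnotation:
    """One detected spike: onset sample, onset voltage, peak, cut window."""

    spike_index: int  # onset sample (dV/dt criterion)
    threshold_voltage: float  # volts; sub-sample-corrected crossing estimate
    peak_index: int
    cut_window: tuple[int, int]  # [start, end) samples
    onset_voltage: float = np.nan  # volts; raw sampled value at the onset


@dataclass
class SpikeCutFit:
    spike_cut: float  # seconds
    f_v: float
    delta_V: float  # volts
    standard_error: float  # volts; spike reproducibility
    n_spikes: int = 0
    ssr_by_offset: np.ndarray | None = None


@dataclass
class ASCFit:
    delta_I: tuple[float, float]  # amperes (fast, slow)
    k: tuple[float, float]  # 1/s (fast, slow)
    R_asc: float  # ohms
    C_asc: float  # farads (capacitance refit jointly with the currents)
    rss: float
    rss_by_pair: dict = field(default_factory=dict)

    @property
    def total_charges(self) -> tuple[float, float]:
        return (self.delta_I[0] / self.k[0], self.delta_I[1] / self.k[1])


@dataclass
class ThresholdSpikeFit:
    b_s: float  # 1/s
    delta_theta_s: float  # volts
    identifiable: bool
    rss: float


@dataclass
class ThresholdVoltageFit:
    a_v: float  # 1/s
    b_v: float  # 1/s
    identifiable: bool
    rss: float


# --------------------------------------------------------------------------
# spike detection
# --------------------------------------------------------------------------


def detect_spikes(
    sweep: Sweep,
    dvdt_fraction: float = 0.05,
    min_dvdt: float = 20.0,
    max_cut: float = MAX_SPIKE_CUT,
    min_height: float = 10e-3,
    min_peak_dvdt: float = 100.0,
) -> list[SpikeAnnotation]:
    """Detect spikes and annotate onsets by the 5 %-of-max-dV/dt criterion.

    Candidate upstrokes are contiguous runs where dV/dt exceeds an absolute
    floor (``min_dvdt``, V/s); an event qualifies as a spike only if its
    maximum dV/dt reaches ``min_peak_dvdt`` (action-potential upstrokes are
    hundreds of V/s; passive charging transients are tens at most) and the
    voltage climbs at least ``min_height`` from onset to peak.  Within each
    event the onset is the sample closest to the peak where dV/dt last
    dropped below ``dvdt_fraction`` of the event's maximum dV/dt.  Returns
    ordered, non-overlapping annotations; a trace with no fast upstrokes
    yields an empty list.
    """
    v = sweep.voltage
    n = v.size
    if n < 2:
        raise InsufficientDataError("sweep must contain at least 2 samples")
    fs = sweep.fs
    dv = np.diff(v) * fs

    fast = dv > min_dvdt
    if not fast.any():
        return []
    idx = np.flatnonzero(fast)
    # split into events at gaps > 1 ms
    gap = max(1, int(round(1e-3 * fs)))
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])

    annotations: list[SpikeAnnotation] = []
    prev_end = 0
    for s_i, e_i in zip(starts, ends):
        run_start, run_end = idx[s_i], idx[e_i]
        # peak: max voltage from the upstroke to shortly after it
        look_end = min(run_end + gap + 1, n)
        peak = run_start + int(np.argmax(v[run_start : look_end + 1]))
        back_limit = max(prev_end, peak - gap)
        if peak <= back_limit:
            continue
        max_dv = float(dv[back_limit:peak].max())
        if max_dv < min_peak_dvdt:
            continue
        thr = dvdt_fraction * max_dv
        # walk back from the peak through the upstroke: the onset is the
        # first sample (closest to the peak) whose preceding slope drops
        # below the 5 % criterion — isolated noise excursions further back
        # cannot drag the onset away from the upstroke
        onset = peak
        while onset > back_limit and dv[onset - 1] >= thr:
            onset -= 1
        if onset == peak:
            onset = run_start
        if float(v[peak]) - float(v[onset]) < min_height:
            # stimulus edges plus recording noise can nudge dV/dt over the
            # floor; a real action potential rises tens of mV
            prev_end = peak + 1
            continue
        # the sampled onset voltage overshoots the true crossing by up to one
        # pre-spike slope step; subtract half a step for the threshold estimate
        pre_slope = max(float(dv[onset - 1]), 0.0) if onset > 0 else 0.0
        annotations.append(
            SpikeAnnotation(
                spike_index=onset,
                threshold_voltage=float(v[onset]) - 0.5 * pre_slope / fs,
                peak_index=peak,
                cut_window=(onset, min(onset + int(round(max_cut * fs)), n)),
                onset_voltage=float(v[onset]),
            )
        )
        prev_end = peak + 1

    # truncate cut windows at the next onset
    for a, b in zip(annotations[:-1], annotations[1:]):
        a.cut_window = (a.cut_window[0], min(a.cut_window[1], b.spike_index))
    return annotations


# --------------------------------------------------------------------------
# resting potential, membrane R and C
# --------------------------------------------------------------------------


def fit_resting_potential(pre_stimulus_segments: list[np.ndarray]) -> float:
    """Mean of the concatenated rest segments (volts)."""
    segs = [np.asarray(s, dtype=float) for s in pre_stimulus_segments if np.size(s)]
    if not segs:
        raise InsufficientDataError("resting-potential fit requires non-empty rest segments")
    return float(np.concatenate(segs).mean())


def fit_membrane_rc(
    subthreshold_sweep: Sweep,
    E_L: float,
    exclude_windows: list[tuple[int, int]] | None = None,
) -> tuple[float, float, float]:
    """Fit (R, C) by least squares on C dV/dt = I_e - (V - E_L)/R.

    The relation is solved with dV/dt as the regression *response*
    (dV/dt = I_e/C - (V - E_L)/(R C)): measurement noise lives in the
    voltage derivative, and putting it in the response keeps the estimates
    unbiased, whereas using dV/dt as a regressor would attenuate C.
    Returns ``(R, C, tau)`` with tau = R*C.  ``exclude_windows`` are sample
    ranges (e.g. spike-cut windows) masked out of the regression.
    """
    v = subthreshold_sweep.voltage
    i_e = subthreshold_sweep.current
    fs = subthreshold_sweep.fs
    dv = np.diff(v) * fs
    mask = np.ones(dv.size, dtype=bool)
    for s, e in exclude_windows or []:
        mask[max(0, s - 1) : min(dv.size, e)] = False
    x1 = i_e[:-1][mask]
    x2 = (v[:-1] - E_L)[mask]
    y = dv[mask]
    coef, rank = _scaled_lstsq(np.column_stack([x1, x2]), y)
    if x1.size < 2 or rank < 2:
        raise DegenerateInputError("membrane R/C regression design is singular")
    inv_C, neg_inv_RC = coef
    if inv_C <= 0 or neg_inv_RC >= 0:
        raise DegenerateInputError("membrane R/C regression produced non-physical values")
    C = 1.0 / inv_C
    R = inv_C / -neg_inv_RC
    return float(R), float(C), float(R * C)


# --------------------------------------------------------------------------
# spike cut length and voltage reset rule
# --------------------------------------------------------------------------


def fit_spike_cut_and_reset(
    sweeps: list[Sweep],
    annotations: list[list[SpikeAnnotation]],
    E_L: float,
    max_cut: float = MAX_SPIKE_CUT,
    min_spikes: int = 5,
) -> SpikeCutFit:
    """Spike cut length plus voltage reset rule from pooled noise spikes.

    For every candidate post-spike offset on a one-sample grid up to
    ``max_cut``, the voltage at (onset + offset) is regressed on the voltage
    at onset across all pooled spikes; the offset minimizing the summed
    squared residuals (ties toward shorter) is the spike cut length delta_t.
    The regression slope is f_v and the intercept maps to delta_V via
    V+ = E_L + f_v (V- - E_L) - delta_V.  The residual standard error at the
    chosen offset is reported as a spike-reproducibility measure.
    """
    fs = sweeps[0].fs
    n_max = max(2, int(round(max_cut * fs)))

    v_before, v_after, limits = [], [], []
    for sweep, anns in zip(sweeps, annotations):
        v = sweep.voltage
        for i, ann in enumerate(anns):
            onset = ann.spike_index
            next_onset = anns[i + 1].spike_index if i + 1 < len(anns) else v.size
            limit = min(next_onset - onset, v.size - onset)
            if limit < 2:
                continue
            v_before.append(ann.onset_voltage)
            v_after.append(v[onset : onset + min(limit, n_max + 1)])
            limits.append(limit)
    n_spikes = len(v_before)
    if n_spikes < min_spikes:
        raise InsufficientDataError(
            f"spike-cut fit requires at least {min_spikes} pooled spikes, got {n_spikes}"
        )
    v_before = np.asarray(v_before)
    limits = np.asarray(limits)

    offsets = np.arange(1, n_max + 1)
    common = limits > offsets[-1]
    # Use spikes valid at every offset when enough of them exist, so summed
    # SSRs are comparable across offsets; otherwise fall back to per-offset
    # mean squared residuals over whichever spikes each offset retains.
    use_common = int(common.sum()) >= min_spikes

    best = None
    ssr_by_offset = np.full(offsets.size, np.nan)
    for oi, off in enumerate(offsets):
        if use_common:
            sel = common
        else:
            sel = limits > off
            if int(sel.sum()) < min_spikes:
                continue
        xb = v_before[sel]
        ya = np.array([v_after[j][off] for j in np.flatnonzero(sel)])
        slope, intercept, ssr = _simple_regression(xb, ya)
        score = ssr if use_common else ssr / xb.size
        ssr_by_offset[oi] = score
        if best is None or score < best[0] - 1e-30:
            dof = max(1, xb.size - 2)
            best = (score, off, slope, intercept, np.sqrt(ssr / dof))
    if best is None:
        raise InsufficientDataError("no post-spike offset retained enough spikes")
    _, off, slope, intercept, stderr = best
    return SpikeCutFit(
        spike_cut=off / fs,
        f_v=float(slope),
        delta_V=float(E_L * (1.0 - slope) - intercept),
        standard_error=float(stderr),
        n_spikes=n_spikes,
        ssr_by_offset=ssr_by_offset,
    )


def _scaled_lstsq(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Least squares with unit-norm column scaling.

    Raw physical columns span ~10 orders of magnitude (amperes next to unit
    regressors), which defeats rank tolerance checks; scaling each column to
    unit norm makes the conditioning test meaningful.  Returns the
    coefficients on the original scale and the numerical rank.
    """
    norms = np.linalg.norm(design, axis=0)
    ok = norms > 0
    if not ok.all():
        return np.zeros(design.shape[1]), int(ok.sum())
    scaled = design / norms
    coef, _, rank, _ = np.linalg.lstsq(scaled, y, rcond=None)
    return coef / norms, int(rank)


def _simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope/intercept/SSR of y on x; intercept-only when x is degenerate."""
    vx = x.var()
    if vx < 1e-18:  # all onsets identical (e.g. fixed-threshold models)
        slope = 0.0
        intercept = y.mean()
    else:
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float((resid**2).sum())


# --------------------------------------------------------------------------
# after-spike currents
# --------------------------------------------------------------------------


def fit_after_spike_currents(
    suprathreshold_sweeps: list[Sweep],
    annotations: list[list[SpikeAnnotation]],
    E_L: float,
    spike_cut: float,
    k_library: tuple[float, ...] = DEFAULT_K_LIBRARY,
    pre_pad: float = 0.5e-3,
) -> ASCFit:
    """Fit after-spike current amplitudes, rate pair, R_ASC, and C_ASC.

    For every unordered pair of rates from ``k_library``, dV/dt is regressed
    on the injected current, unit exponential regressors driven at each
    spike's reset sample (end of the spike-cut window), and -(V - E_L), over
    spike-cut-removed inter-spike samples pooled across sweeps; the rate
    pair minimizing the residual sum of squares wins (fast rate first).
    The current coefficient is 1/C, so capacitance and resistance are refit
    jointly with the currents and the amplitudes stay internally consistent
    with them (keeping dV/dt on the response side leaves the estimates
    unbiased under voltage measurement noise).
    """
    ks = tuple(sorted(set(float(k) for k in k_library), reverse=True))
    if len(ks) < 2:
        raise InsufficientDataError("k_library must contain at least 2 distinct rates")

    ys, icols, vcols, regs = [], [], [], {k: [] for k in ks}
    n_segments = 0
    for sweep, anns in zip(suprathreshold_sweeps, annotations):
        if not anns:
            continue
        v = sweep.voltage
        i_e = sweep.current
        fs = sweep.fs
        h = 1.0 / fs
        n = v.size
        n_cut = max(1, int(round(spike_cut * fs)))
        n_pre = int(round(pre_pad * fs))

        frozen = np.zeros(n, dtype=np.uint8)
        reset_idx = []
        for ann in anns:
            onset = ann.spike_index
            frozen[onset : min(onset + n_cut, n)] = 1
            if onset + n_cut < n:
                reset_idx.append(onset + n_cut)
        reset_idx = np.asarray(sorted(reset_idx), dtype=np.int64)
        n_segments += len(reset_idx)

        mask = np.ones(n - 1, dtype=bool)
        for ann in anns:
            onset = ann.spike_index
            mask[max(0, onset - n_pre - 1) : min(n - 1, onset + n_cut)] = False
        lo, hi = sweep.meta.get("stim_window", (0, n))
        keep = np.zeros(n - 1, dtype=bool)
        keep[int(lo) : int(hi) - 1] = True
        mask &= keep
        if not mask.any():
            continue

        dv = np.diff(v) * fs
        ys.append(dv[mask])
        icols.append(i_e[:-1][mask])
        vcols.append((v[:-1] - E_L)[mask])
        for k in ks:
            r = exp_regressor(n, np.exp(-k * h), reset_idx, frozen)
            regs[k].append(r[:-1][mask])

    if n_segments < 2:
        raise InsufficientDataError(
            "after-spike-current fit requires at least 2 inter-spike segments"
        )
    y = np.concatenate(ys)
    icol = np.concatenate(icols)
    vcol = np.concatenate(vcols)
    regs = {k: np.concatenate(cols) for k, cols in regs.items()}

    best = None
    rss_by_pair = {}
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            k1, k2 = ks[a], ks[b]  # k1 > k2: fast first
            design = np.column_stack([icol, regs[k1], regs[k2], -vcol])
            coef, rank = _scaled_lstsq(design, y)
            if rank < 4:
                continue
            rss = float(((design @ coef - y) ** 2).sum())
            rss_by_pair[(k1, k2)] = rss
            if best is None or rss < best[0]:
                best = (rss, (k1, k2), coef)
    if best is None:
        raise DegenerateInputError("all rate pairs gave singular designs")
    rss, (k1, k2), coef = best
    inv_C, b1, b2, inv_RC = coef
    if inv_C <= 0:
        raise DegenerateInputError("after-spike-current fit gave non-positive capacitance")
    C_asc = 1.0 / inv_C
    R_asc = inv_C / inv_RC if inv_RC > 0 else np.nan
    return ASCFit(
        delta_I=(float(b1 * C_asc), float(b2 * C_asc)),
        k=(k1, k2),
        R_asc=float(R_asc),
        C_asc=float(C_asc),
        rss=rss,
        rss_by_pair=rss_by_pair,
    )


# --------------------------------------------------------------------------
# threshold dynamics
# --------------------------------------------------------------------------


def _decay_times(onsets_t: np.ndarray, spike_cut: float) -> np.ndarray:
    """Effective decay time from each earlier spike's reset to each later onset.

    Decay is suspended during refractory windows, so the elapsed decay time
    from spike l's reset to spike m's onset is t_m - t_l - (m - l) * delta_t.
    Returns a (m, l) lower-triangular matrix (nan above diagonal).
    """
    m = onsets_t.size
    out = np.full((m, m), np.nan)
    for i in range(m):
        for l in range(i):
            out[i, l] = onsets_t[i] - onsets_t[l] - (i - l) * spike_cut
    return out


def fit_spike_threshold_dynamics(
    triple_sweeps: list[Sweep],
    annotations: list[list[SpikeAnnotation]],
    spike_cut: float,
    b_bounds: tuple[float, float] = (1.0, 2000.0),
    amplitude_floor: float = 0.2e-3,
    theta_v_params: tuple[float, float, float] | None = None,
) -> ThresholdSpikeFit:
    """Fit (b_s, delta_Theta_s) from triple-short-square threshold elevations.

    Within each sweep, the threshold (onset voltage) of each subsequent spike
    is elevated relative to the first by the accumulated spike-induced
    component sum_l delta_Theta_s exp(-b_s dt_l).  The amplitude is linear
    given b_s; b_s comes from a bounded 1-D search.  If the recovered
    amplitude is below ``amplitude_floor`` the rate is unidentifiable and the
    fit is flagged.

    ``theta_v_params`` — optional (a_v, b_v, E_L): when a voltage-dependent
    threshold estimate is available, its contribution along each triple sweep
    is subtracted from the observed elevations before fitting, since brief
    pulse-driven depolarizations do raise the threshold slightly through that
    mechanism as well.
    """
    elevations, contrib_times = [], []
    for sweep, anns in zip(triple_sweeps, annotations):
        if len(anns) < 2:
            continue
        fs = sweep.fs
        t = np.array([a.spike_index for a in anns]) / fs
        th = np.array([a.threshold_voltage for a in anns]).astype(float)
        if theta_v_params is not None:
            a_v, b_v, e_l = theta_v_params
            n = sweep.voltage.size
            n_cut = max(1, int(round(spike_cut * fs)))
            frozen = np.zeros(n, dtype=np.uint8)
            for ann in anns:
                frozen[ann.spike_index : min(ann.spike_index + n_cut, n)] = 1
            g = voltage_threshold_filter(sweep.voltage, e_l, b_v, 1.0 / fs, frozen)
            th = th - a_v * np.array([g[a.spike_index] for a in anns])
        dt_mat = _decay_times(t, spike_cut)
        for i in range(1, len(anns)):
            elevations.append(th[i] - th[0])
            contrib_times.append(dt_mat[i, :i].copy())
    if not elevations:
        raise InsufficientDataError(
            "threshold-dynamics fit requires subsequent spikes in triple sweeps"
        )
    e = np.asarray(elevations)

    def rss_for(log_b: float):
        b = np.exp(log_b)
        g = np.array([np.exp(-b * ct).sum() for ct in contrib_times])
        denom = (g**2).sum()
        amp = (e * g).sum() / denom if denom > 0 else 0.0
        return float(((e - amp * g) ** 2).sum()), amp, b

    res = minimize_scalar(
        lambda lb: rss_for(lb)[0],
        bounds=(np.log(b_bounds[0]), np.log(b_bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rss, amp, b = rss_for(res.x)
    identifiable = abs(amp) >= amplitude_floor
    return ThresholdSpikeFit(
        b_s=float(b), delta_theta_s=float(amp), identifiable=identifiable, rss=rss
    )


def fit_voltage_threshold_dynamics(
    suprathreshold_sweeps: list[Sweep],
    annotations: list[list[SpikeAnnotation]],
    params_so_far: GLIFParameters,
    b_bounds: tuple[float, float] = (1.0, 1000.0),
    min_spikes: int = 10,
    coupling_floor: float = 0.5,
) -> ThresholdVoltageFit:
    """Fit (a_v, b_v) of the voltage-dependent threshold component.

    Observed spike-onset thresholds are modeled as Theta_inf + Theta_s(t) +
    a_v g_{b_v}(t), where g integrates d g/dt = (V - E_L) - b_v g along the
    recorded voltage (frozen inside spike-cut windows).  a_v is solved in
    closed form for each b_v; b_v comes from a bounded 1-D search.  A
    constant-voltage history leaves g ~ 0 and the pair unidentifiable.
    """
    p = params_so_far
    resid, filters = [], []  # residual thresholds and per-spike g samples
    n_total = 0
    for sweep, anns in zip(suprathreshold_sweeps, annotations):
        if len(anns) == 0:
            continue
        n = sweep.voltage.size
        fs = sweep.fs
        n_cut = max(1, int(round(p.spike_cut * fs)))
        frozen = np.zeros(n, dtype=np.uint8)
        for ann in anns:
            frozen[ann.spike_index : min(ann.spike_index + n_cut, n)] = 1
        onsets_t = np.array([a.spike_index for a in anns]) / fs
        dt_mat = _decay_times(onsets_t, p.spike_cut)
        for i, ann in enumerate(anns):
            theta_s = p.delta_theta_s * np.exp(-p.b_s * dt_mat[i, :i]).sum() if i else 0.0
            resid.append(ann.threshold_voltage - p.theta_inf - theta_s)
            n_total += 1
        filters.append((sweep, frozen, [a.spike_index for a in anns]))
    if n_total < min_spikes:
        raise InsufficientDataError(
            f"voltage-threshold fit requires at least {min_spikes} spikes, got {n_total}"
        )
    r = np.asarray(resid)

    def solve_for(log_b: float):
        b = np.exp(log_b)
        gs = []
        for sweep, frozen, onsets in filters:
            g = voltage_threshold_filter(
                sweep.voltage, p.E_L, b, 1.0 / sweep.fs, frozen
            )
            gs.extend(g[i] for i in onsets)
        g = np.asarray(gs)
        denom = (g**2).sum()
        if denom < 1e-18:
            return float((r**2).sum()), 0.0, b, False
        a = (r * g).sum() / denom
        return float(((r - a * g) ** 2).sum()), a, b, True

    res = minimize_scalar(
        lambda lb: solve_for(lb)[0],
        bounds=(np.log(b_bounds[0]), np.log(b_bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rss, a_v, b_v, ok = solve_for(res.x)
    identifiable = ok and abs(a_v) >= coupling_floor
    return ThresholdVoltageFit(
        a_v=float(a_v), b_v=float(b_v), identifiable=identifiable, rss=rss
    )


def fit_instantaneous_threshold_init(
    short_square_sweeps: list[Sweep],
    annotations: list[list[SpikeAnnotation]] | None = None,
) -> float:
    """Initial Theta_inf: onset voltage of the lowest-amplitude spiking sweep.

    If several sweeps share the minimal spiking amplitude their onset
    voltages are averaged.
    """
    if annotations is None:
        annotations = [detect_spikes(s) for s in short_square_sweeps]
    spiking = [
        (s.meta.get("amplitude_A", float(np.max(np.abs(s.current)))), anns[0].threshold_voltage)
        for s, anns in zip(short_square_sweeps, annotations)
        if anns
    ]
    if not spiking:
        raise InsufficientDataError("no short-square sweep evoked a spike")
    amps = np.array([a for a, _ in spiking])
    lowest = amps.min()
    # relative tie test: amplitudes are ~1e-9 A, so any absolute tolerance
    # comparable to np.isclose defaults would declare everything tied
    onsets = [v for a, v in spiking if a <= lowest * (1 + 1e-9)]
    return float(np.mean(onsets))


# --------------------------------------------------------------------------
# full stage-1 orchestration
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    params: GLIFParameters
    report: dict


def fit_cell(
    sweeps: dict[str, list[Sweep]],
    level: int,
    k_library: tuple[float, ...] = DEFAULT_K_LIBRARY,
    dvdt_fraction: float = 0.05,
) -> FitResult:
    """Run the complete stage-1 fit for one cell at one model level.

    ``sweeps`` maps protocol keys (as produced by the synthesizer or sweep
    reader) to sweep lists: ``noise1`` (training noise, with rest prefix),
    ``short_square`` (threshold ladder), and, for the levels that need them,
    ``triple`` (spike-threshold dynamics).  Raises
    :class:`InsufficientDataError` naming any missing requirement.
    """
    mech = LEVEL_MECHANISMS.get(level)
    if mech is None:
        raise ValueError(f"level must be 1..5, got {level}")
    if "noise1" not in sweeps or not sweeps["noise1"]:
        raise InsufficientDataError("stage-1 fit requires training noise sweeps (noise1)")
    if "short_square" not in sweeps or not sweeps["short_square"]:
        raise InsufficientDataError("stage-1 fit requires short-square sweeps")
    if "reset" in mech and not sweeps.get("triple"):
        raise InsufficientDataError("missing triple short square")

    noise1 = sweeps["noise1"]
    fs = noise1[0].fs
    anns1 = [detect_spikes(s, dvdt_fraction) for s in noise1]
    report: dict = {"level": level, "fs": fs, "n_spikes_noise1": sum(len(a) for a in anns1)}

    # resting potential from pre-stimulus rest of the training noise sweeps
    rest_segs = []
    for s in noise1:
        lo, _ = s.meta.get("stim_window", (0, 0))
        if lo:
            rest_segs.append(s.voltage[: int(lo)])
    E_L = fit_resting_potential(rest_segs)

    # spike cut length + reset rule from all pooled noise spikes
    cut = fit_spike_cut_and_reset(noise1, anns1, E_L)
    n_cut = max(1, int(round(cut.spike_cut * fs)))

    # R, C from the sub-threshold noise epoch (lowest amplitude), masking
    # any spikes it happens to contain
    sub_idx = int(
        np.argmin([s.meta.get("fraction_of_threshold", np.inf) for s in noise1])
    )
    sub_sweep = noise1[sub_idx]
    # after-spike currents outlast the cut window (slowest library rate is
    # 10 1/s), so mask a generous post-spike stretch in the R/C regression
    sub_windows = [
        (a.spike_index - int(2e-3 * fs), a.spike_index + n_cut + int(150e-3 * fs))
        for a in anns1[sub_idx]
    ]
    R, C, tau = fit_membrane_rc(sub_sweep, E_L, exclude_windows=sub_windows)
    report["tau_m"] = tau

    theta_inf = fit_instantaneous_threshold_init(sweeps["short_square"])

    supra = [
        (s, a)
        for s, a in zip(noise1, anns1)
        if s.meta.get("fraction_of_threshold", 1.0) >= 1.0 and a
    ]
    supra_sweeps = [s for s, _ in supra]
    supra_anns = [a for _, a in supra]

    kwargs: dict = {}
    R_model = R
    if "asc" in mech:
        asc = fit_after_spike_currents(
            supra_sweeps, supra_anns, E_L, cut.spike_cut, k_library
        )
        kwargs.update(delta_I=asc.delta_I, k=asc.k)
        if np.isfinite(asc.R_asc) and asc.R_asc > 0:
            R_model = asc.R_asc
        report["asc_rss"] = asc.rss
        report["total_charges_C"] = asc.total_charges
    if "reset" in mech:
        anns_t = [detect_spikes(s, dvdt_fraction) for s in sweeps["triple"]]
        ts = fit_spike_threshold_dynamics(sweeps["triple"], anns_t, cut.spike_cut)
        kwargs.update(b_s=ts.b_s, delta_theta_s=ts.delta_theta_s, f_v=cut.f_v, delta_V=cut.delta_V)
        report["threshold_spike_identifiable"] = ts.identifiable

    params = GLIFParameters(
        level=level,
        C=C,
        R=R_model,
        E_L=E_L,
        theta_inf=theta_inf,
        spike_cut=cut.spike_cut,
        R_is_R_ASC="asc" in mech,
        **kwargs,
    )

    if "vth" in mech:
        # the spike- and voltage-dependent threshold components contaminate
        # each other's observations, so alternate the two fits briefly
        anns_t = [detect_spikes(s, dvdt_fraction) for s in sweeps["triple"]]
        tv = fit_voltage_threshold_dynamics(supra_sweeps, supra_anns, params)
        for _ in range(2):
            ts = fit_spike_threshold_dynamics(
                sweeps["triple"],
                anns_t,
                cut.spike_cut,
                theta_v_params=(tv.a_v, tv.b_v, E_L),
            )
            params = dataclasses.replace(
                params, b_s=ts.b_s, delta_theta_s=ts.delta_theta_s
            )
            tv = fit_voltage_threshold_dynamics(supra_sweeps, supra_anns, params)
        params = dataclasses.replace(params, a_v=tv.a_v, b_v=tv.b_v)
        report["threshold_spike_identifiable"] = ts.identifiable
        report["threshold_voltage_identifiable"] = tv.identifiable

    report.update(
        E_L=E_L,
        R=R_model,
        C=C,
        theta_inf_init=theta_inf,
        spike_cut=cut.spike_cut,
        f_v=cut.f_v,
        delta_V=cut.delta_V,
        spike_cut_standard_error=cut.standard_error,
    )
    return FitResult(params=params, report=report)
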