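"""Numba inner loops for GLIF integration.

Forward Euler is used for the membrane potential V and the voltage-dependent
threshold component Theta_v (which are coupled through V); the autonomous
decays of Theta_s and the two after-spike currents use exact exponential
factors per step.  During the refractory gap after a spike the state is
frozen and the voltage/threshold traces are filled with their values at the
crossing sample; the reset map is applied when integration resumes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glif_run", "glif_forced", "exp_regressor", "voltage_threshold_filter"]


@njit(cache=True)
def glif_run(
    I_e,
    h,
    C,
    R,
    E_L,
    th_inf,
    n_ref,
    f_v,
    dV,
    b_s,
    dThs,
    k1,
    k2,
    dI1,
    dI2,
    a_v,
    b_v,
    v0,
    ths0,
    i10,
    i20,
    thv0,
    noise,
):
    n = I_e.size
    V = np.empty(n)
    TH = np.empty(n)
    THS = np.empty(n)
    A1 = np.empty(n)
    A2 = np.empty(n)
    THV = np.empty(n)
    spikes = np.empty(n, np.int64)
    n_sp = 0

    e_bs = np.exp(-b_s * h)
    e_k1 = np.exp(-k1 * h)
    e_k2 = np.exp(-k2 * h)

    v = v0
    ths = ths0
    a1 = i10
    a2 = i20
    thv = thv0

    i = 0
    while i < n:
        th = th_inf + ths + thv
        if v > th:
            spikes[n_sp] = i
            n_sp += 1
            j = min(i + n_ref, n)
            for m in range(i, j):
                V[m] = v
                TH[m] = th
                THS[m] = ths
                A1[m] = a1
                A2[m] = a2
                THV[m] = thv
            # reset map (f_j = 1 for the after-spike currents)
            v = E_L + f_v * (v - E_L) - dV
            ths = ths + dThs
            a1 = a1 + dI1
            a2 = a2 + dI2
            i = j
            continue
        V[i] = v
        TH[i] = th
        THS[i] = ths
        A1[i] = a1
        A2[i] = a2
        THV[i] = thv
        dv = h / C * (I_e[i] + a1 + a2 - (v - E_L) / R)
        thv = thv + h * (a_v * (v - E_L) - b_v * thv)
        v = v + dv + noise[i]
        ths *= e_bs
        a1 *= e_k1
        a2 *= e_k2
        i += 1

    return V, TH, THS, A1, A2, THV, spikes[:n_sp]


@njit(cache=True)
def glif_forced(
    I_e,
    h,
    C,
    R,
    E_L,
    th_inf,
    n_ref,
    f_v,
    dV,
    b_s,
    dThs,
    k1,
    k2,
    dI1,
    dI2,
    a_v,
    b_v,
    v0,
    ths0,
    i10,
    i20,
    thv0,
    noise,
    forced_idx,
):
    """Integrate with resets imposed at ``forced_idx``; own crossings ignored.

    Returns voltage and threshold traces plus the voltage-to-threshold gap at
    each forced spike sample (model V minus total threshold, both pre-reset),
    and a mask marking samples inside refractory fills (excluded from
    between-spike statistics).
    """
    n = I_e.size
    V = np.empty(n)
    TH = np.empty(n)
    gaps = np.empty(forced_idx.size)
    in_ref = np.zeros(n, np.uint8)

    e_bs = np.exp(-b_s * h)
    e_k1 = np.exp(-k1 * h)
    e_k2 = np.exp(-k2 * h)

    v = v0
    ths = ths0
    a1 = i10
    a2 = i20
    thv = thv0

    nf = forced_idx.size
    f = 0
    i = 0
    while i < n:
        th = th_inf + ths + thv
        if f < nf and i == forced_idx[f]:
            gaps[f] = v - th
            f += 1
            j = min(i + n_ref, n)
            for m in range(i, j):
                V[m] = v
                TH[m] = th
                in_ref[m] = 1
            v = E_L + f_v * (v - E_L) - dV
            ths = ths + dThs
            a1 = a1 + dI1
            a2 = a2 + dI2
            i = j
            continue
        V[i] = v
        TH[i] = th
        dv = h / C * (I_e[i] + a1 + a2 - (v - E_L) / R)
        thv = thv + h * (a_v * (v - E_L) - b_v * thv)
        v = v + dv + noise[i]
        ths *= e_bs
        a1 *= e_k1
        a2 *= e_k2
        i += 1

    return V, TH, gaps, in_ref


@njit(cache=True)
def voltage_threshold_filter(V, E_L, b_v, h, frozen):
    """Integrate dg/dt = (V - E_L) - b_v g along a recorded voltage trace.

    Theta_v for coupling a_v is ``a_v * g`` (the filter is linear in a_v).
    Frozen (refractory/spike-cut) samples do not advance the filter, matching
    the simulator's freeze-during-refractory convention.
    """
    n = V.size
    g = np.empty(n)
    x = 0.0
    for i in range(n):
        g[i] = x
        if not frozen[i]:
            x = x + h * ((V[i] - E_L) - b_v * x)
    return g


@njit(cache=True)
def exp_regressor(n, decay, reset_idx, frozen):
    """Unit-amplitude exponential basis driven at reset samples.

    r jumps by one at each entry of ``reset_idx`` and decays by ``decay`` per
    sample outside frozen (refractory) samples, matching the simulator's
    freeze-during-refractory convention.
    """
    r = np.zeros(n)
    x = 0.0
    j = 0
    for i in range(n):
        if j < reset_idx.size and i == reset_idx[j]:
            x += 1.0
            j += 1
        r[i] = x
        if not frozen[i]:
            x *= decay
    return r
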