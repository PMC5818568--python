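"""GLIF model family: parameters, state, and simulation (levels 1-5).

The generalized leaky integrate-and-fire family nests five models of
increasing complexity.  Between spikes the state evolves linearly:

    C dV/dt      = I_e(t) + sum_j I_j(t) - (V - E_L)/R
    dTheta_s/dt  = -b_s Theta_s
    dI_j/dt      = -k_j I_j                        (j = 1, 2)
    dTheta_v/dt  = a_v (V - E_L) - b_v Theta_v

A spike is generated at the first sample where
``V > Theta_inf + Theta_s + Theta_v``.  After a refractory gap of one spike
cut length ``delta_t`` (state frozen, no spikes possible) the state is reset:

    V       <- E_L + f_v (V- - E_L) - delta_V
    Theta_s <- Theta_s + delta_Theta_s
    I_j     <- f_j I_j + delta_I_j                 (f_j fixed to 1)
    Theta_v <- Theta_v (unchanged)

Mechanisms absent at a level are held at zero: level 1 is the classic LIF
with reset to rest; level 2 adds the voltage/threshold reset rules
(f_v, delta_V, b_s, delta_Theta_s); level 3 instead adds the two after-spike
currents; level 4 combines both; level 5 adds the voltage-dependent
threshold (a_v, b_v).

All quantities are strict SI (volts, amperes, seconds, farads, ohms, 1/s).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import glif_run
from .stimulus import StimulusEpoch

__all__ = [
    "GLIFParameters",
    "GLIFState",
    "SimulationResult",
    "step_state",
    "apply_reset",
    "simulate",
    "GLIFNumericalError",
]


class GLIFNumericalError(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


# Mechanisms active at each model level.
LEVEL_MECHANISMS = {
    1: frozenset(),
    2: frozenset({"reset"}),
    3: frozenset({"asc"}),
    4: frozenset({"reset", "asc"}),
    5: frozenset({"reset", "asc", "vth"}),
}


@dataclass(frozen=True)
class GLIFParameters:
    """Full GLIF parameter vector with model-level tag.

    Fields not used at the given ``level`` are ignored during simulation
    (treated as zero); ``effective()`` returns the level-consistent values.
    """

    level: int
    C: float  # farads
    R: float  # ohms (R_ASC when fit jointly with after-spike currents)
    E_L: float  # volts
    theta_inf: float  # volts
    spike_cut: float  # seconds (refractory period delta_t)
    f_v: float = 0.0
    delta_V: float = 0.0  # volts
    b_s: float = 0.0  # 1/s
    delta_theta_s: float = 0.0  # volts
    k: tuple[float, float] = (100.0, 10.0)  # 1/s
    delta_I: tuple[float, float] = (0.0, 0.0)  # amperes
    f_j: float = 1.0  # current fraction following spike; fixed to 1
    a_v: float = 0.0  # 1/s
    b_v: float = 0.0  # 1/s
    R_is_R_ASC: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVEL_MECHANISMS:
            raise ValueError(f"level must be 1..5, got {self.level}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.spike_cut < 0:
            raise ValueError("spike_cut must be non-negative")
        k1, k2 = self.k
        if k1 <= 0 or k2 <= 0 or k1 == k2:
            raise ValueError("k_1, k_2 must be positive and distinct")
        if self.theta_inf <= self.E_L:
            raise ValueError("theta_inf must exceed E_L")
        if self.f_j != 1.0:
            raise ValueError("f_j is fixed to 1")

    @property
    def mechanisms(self) -> frozenset[str]:
        return LEVEL_MECHANISMS[self.level]

    @property
    def tau_m(self) -> float:
        """Membrane time constant R*C in seconds."""
        return self.R * self.C

    @property
    def total_charges(self) -> tuple[float, float]:
        """After-spike current total charges Q_j = delta_I_j / k_j (coulombs)."""
        return (self.delta_I[0] / self.k[0], self.delta_I[1] / self.k[1])

    def effective(self) -> "GLIFParameters":
        """Parameters with mechanisms absent at this level zeroed out."""
        mech = self.mechanisms
        kw = {}
        if "reset" not in mech:
            kw.update(f_v=0.0, delta_V=0.0, b_s=0.0, delta_theta_s=0.0)
        if "asc" not in mech:
            kw.update(delta_I=(0.0, 0.0))
        if "vth" not in mech:
            kw.update(a_v=0.0, b_v=0.0)
        return replace(self, **kw) if kw else self

    # JSON round-trip (units encoded in key names) ------------------------

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "C_F": self.C,
            "R_Ohm": self.R,
            "E_L_V": self.E_L,
            "theta_inf_V": self.theta_inf,
            "spike_cut_s": self.spike_cut,
            "f_v": self.f_v,
            "delta_V_V": self.delta_V,
            "b_s_per_s": self.b_s,
            "delta_theta_s_V": self.delta_theta_s,
            "k_per_s": list(self.k),
            "delta_I_A": list(self.delta_I),
            "f_j": self.f_j,
            "a_v_per_s": self.a_v,
            "b_v_per_s": self.b_v,
            "R_is_R_ASC": self.R_is_R_ASC,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLIFParameters":
        return cls(
            level=int(d["level"]),
            C=d["C_F"],
            R=d["R_Ohm"],
            E_L=d["E_L_V"],
            theta_inf=d["theta_inf_V"],
            spike_cut=d["spike_cut_s"],
            f_v=d.get("f_v", 0.0),
            delta_V=d.get("delta_V_V", 0.0),
            b_s=d.get("b_s_per_s", 0.0),
            delta_theta_s=d.get("delta_theta_s_V", 0.0),
            k=tuple(d.get("k_per_s", (100.0, 10.0))),
            delta_I=tuple(d.get("delta_I_A", (0.0, 0.0))),
            f_j=d.get("f_j", 1.0),
            a_v=d.get("a_v_per_s", 0.0),
            b_v=d.get("b_v_per_s", 0.0),
            R_is_R_ASC=bool(d.get("R_is_R_ASC", False)),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "GLIFParameters":
        if hasattr(src, "read"):
            d = json.load(src)
        else:
            try:
                d = json.loads(src)
            except (json.JSONDecodeError, TypeError):
                with open(src) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class GLIFState:
    """Instantaneous values of the five state variables."""

    V: float
    theta_s: float = 0.0
    I_1: float = 0.0
    I_2: float = 0.0
    theta_v: float = 0.0
    t: float = 0.0

    @classmethod
    def at_rest(cls, params: GLIFParameters, t: float = 0.0) -> "GLIFState":
        return cls(V=params.E_L, t=t)

    def check_finite(self) -> None:
        for name in ("V", "theta_s", "I_1", "I_2", "theta_v"):
            if not np.isfinite(getattr(self, name)):
                raise GLIFNumericalError(f"state variable {name} is non-finite")


@dataclass
class SimulationResult:
    """Simulated voltage/threshold traces and spike times."""

    voltage: np.ndarray  # volts
    threshold: np.ndarray  # volts: Theta_inf + Theta_s + Theta_v per sample
    spike_indices: np.ndarray
    fs: float
    t0: float = 0.0
    states: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def spike_times(self) -> np.ndarray:
        """Spike times in seconds (left edge of the crossing sample)."""
        return self.t0 + self.spike_indices / self.fs

    @property
    def n_spikes(self) -> int:
        return int(self.spike_indices.size)

    @property
    def duration(self) -> float:
        return self.voltage.size / self.fs


def step_state(
    state: GLIFState, I_e: float, h: float, params: GLIFParameters
) -> GLIFState:
    """Advance the state one step of size ``h`` between spikes.

    Forward Euler for V and Theta_v; exact exponential decay for Theta_s and
    the after-spike currents.  Matches one iteration of the simulation loop.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    state.check_finite()
    p = params.effective()
    dv = h / p.C * (I_e + state.I_1 + state.I_2 - (state.V - p.E_L) / p.R)
    theta_v = state.theta_v + h * (p.a_v * (state.V - p.E_L) - p.b_v * state.theta_v)
    return GLIFState(
        V=state.V + dv,
        theta_s=state.theta_s * np.exp(-p.b_s * h),
        I_1=state.I_1 * np.exp(-p.k[0] * h),
        I_2=state.I_2 * np.exp(-p.k[1] * h),
        theta_v=theta_v,
        t=state.t + h,
    )


def apply_reset(state_at_spike: GLIFState, params: GLIFParameters) -> GLIFState:
    """Map the state just before a spike to the state after the refractory gap."""
    p = params.effective()
    return GLIFState(
        V=p.E_L + p.f_v * (state_at_spike.V - p.E_L) - p.delta_V,
        theta_s=state_at_spike.theta_s + p.delta_theta_s,
        I_1=p.f_j * state_at_spike.I_1 + p.delta_I[0],
        I_2=p.f_j * state_at_spike.I_2 + p.delta_I[1],
        theta_v=state_at_spike.theta_v,
        t=state_at_spike.t + p.spike_cut,
    )


def _refractory_samples(spike_cut: float, h: float) -> int:
    n_ref = int(round(spike_cut / h))
    if n_ref < 1:
        if spike_cut < h:
            warnings.warn(
                "spike cut length shorter than one sample; refractory rounded "
                "up to one sample",
                stacklevel=3,
            )
        n_ref = 1
    return n_ref


def simulate(
    params: GLIFParameters,
    stimulus: StimulusEpoch | np.ndarray,
    initial: GLIFState | None = None,
    fs: float | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    record_states: bool = False,
) -> SimulationResult:
    """Simulate a GLIF model over a stimulus epoch.

    Parameters
    ----------
    params
        Model parameters; mechanisms absent at ``params.level`` are held at 0.
    stimulus
        A :class:`StimulusEpoch`, or a raw current array (then ``fs`` is
        required), in amperes.
    initial
        Starting state; defaults to rest (V = E_L, all other variables 0).
    noise_sd
        Stationary standard deviation (volts) of intrinsic membrane noise,
        injected as an AR(1)-consistent per-step voltage kick whose scale is
        ``noise_sd * sqrt(1 - exp(-2 h / tau_m))``.  Zero disables noise.
    rng
        Seed or Generator for the noise (required if ``noise_sd > 0``).
    """
    if isinstance(stimulus, StimulusEpoch):
        current = stimulus.current
        fs = stimulus.fs
    else:
        current = np.ascontiguousarray(stimulus, dtype=float)
        if fs is None:
            raise ValueError("fs is required when stimulus is a raw array")
    if not np.all(np.isfinite(current)):
        raise ValueError("stimulus current contains non-finite values")

    h = 1.0 / fs
    p = params.effective()
    n_ref = _refractory_samples(p.spike_cut, h)
    if initial is None:
        initial = GLIFState.at_rest(params)
    initial.check_finite()

    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        step_sd = noise_sd * np.sqrt(-np.expm1(-2.0 * h / p.tau_m))
        noise = gen.normal(0.0, step_sd, size=current.size)
    else:
        noise = np.zeros(current.size)

    V, TH, THS, A1, A2, THV, spikes = glif_run(
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
        initial.V,
        initial.theta_s,
        initial.I_1,
        initial.I_2,
        initial.theta_v,
        noise,
    )
    for name, arr in (("V", V), ("Theta_s", THS), ("I_1", A1), ("I_2", A2), ("Theta_v", THV)):
        if not np.all(np.isfinite(arr)):
            raise GLIFNumericalError(f"state variable {name} became non-finite")

    states = (
        {"theta_s": THS, "I_1": A1, "I_2": A2, "theta_v": THV} if record_states else {}
    )
    return SimulationResult(
        voltage=V, threshold=TH, spike_indices=spikes, fs=fs, states=states
    )
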