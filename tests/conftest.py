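"""Shared fixtures: ground-truth cells synthesized once per session."""

from __future__ import annotations

import numpy as np
import pytest

from glifkit.core import GLIFParameters
from glifkit.synth import SyntheticCell, synthesize_sweeps

BASE = dict(C=150e-12, R=180e6, E_L=-75e-3, theta_inf=-45e-3, spike_cut=4e-3)
RESET = dict(f_v=0.4, delta_V=5e-3, b_s=50.0, delta_theta_s=5e-3)
ASC = dict(k=(100.0, 10.0), delta_I=(-25e-12, -6e-12))


def ground_truth(level: int, **overrides) -> GLIFParameters:
    kw = dict(BASE)
    if level in (2, 4, 5):
        kw.update(RESET)
    if level in (3, 4, 5):
        kw.update(ASC)
    if level == 5:
        kw.update(a_v=10.0, b_v=20.0)
    kw.update(overrides)
    return GLIFParameters(level=level, **kw)


def make_cell(level: int, noise_sd: float, seed: int = 7, **overrides) -> SyntheticCell:
    cell = SyntheticCell(params=ground_truth(level, **overrides), seed=seed, noise_sd=noise_sd)
    return synthesize_sweeps(cell)


@pytest.fixture(scope="session")
def cells_noiseless() -> dict[int, SyntheticCell]:
    """One noiseless ground-truth cell per model level."""
    return {level: make_cell(level, 0.0) for level in (1, 2, 3, 4, 5)}


@pytest.fixture(scope="session")
def cells_noisy() -> dict[int, SyntheticCell]:
    """One ground-truth cell per level at 0.2 mV intrinsic noise."""
    return {level: make_cell(level, 0.2e-3) for level in (1, 2, 3, 4, 5)}


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
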