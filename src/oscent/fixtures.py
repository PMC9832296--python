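"""Deterministic synthetic fixtures with known analytic metric values.

Used by the test-suite (and handy for sanity checks): small signals and
phase sets whose phase-coherence values are known in closed form, plus a
validated point on the deterministic Kim-Forger limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .models import KimForgerParams, ParameterError
from .simulate import limit_cycle_point

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "clean_sinusoid",
    "noisy_sinusoid",
    "antiphase_pair",
    "uniform_phases",
    "kf_limit_cycle_point",
)


@dataclass(frozen=True)
class Fixture:
    """A named synthetic input with its expected analytic outputs."""

    name: str
    params: Dict = field(default_factory=dict)
    data: Dict = field(default_factory=dict)
    expected: Dict = field(default_factory=dict)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build one of the named fixtures, deterministically from ``seed``."""
    if name == "clean_sinusoid":
        dt = 0.001
        t = np.arange(0, 5.0 + dt / 2, dt)
        x = np.sin(2 * np.pi * t)
        return Fixture(
            name=name, params={"dt": dt, "T": 1.0},
            data={"times": t, "x": x},
            expected={"peak_times": np.array([0.25, 1.25, 2.25, 3.25, 4.25]),
                      "pc": 1.0},
        )
    if name == "noisy_sinusoid":
        dt = 0.001
        t = np.arange(0, 5.0 + dt / 2, dt)
        rng = np.random.default_rng(seed)
        x = np.sin(2 * np.pi * t) + rng.normal(0.0, 0.05, size=t.size)
        return Fixture(
            name=name, params={"dt": dt, "T": 1.0, "noise_sd": 0.05, "seed": seed},
            data={"times": t, "x": x},
            expected={"clean_peak_times": np.array([0.25, 1.25, 2.25, 3.25, 4.25]),
                      "n_peaks": 5, "max_peak_error": 0.05},
        )
    if name == "antiphase_pair":
        # two oscillators peaking half a cycle apart, every cycle
        T = 1.0
        a = np.arange(5) * T + 0.25
        b = np.arange(5) * T + 0.75
        return Fixture(
            name=name, params={"T": T},
            data={"peak_times": [a, b]},
            expected={"ppc": 0.0},
        )
    if name == "uniform_phases":
        angles = np.array([0.0, 0.5, 1.0, 1.5]) * np.pi
        return Fixture(
            name=name, data={"angles": angles}, expected={"r": 0.0},
        )
    if name == "kf_limit_cycle_point":
        state = limit_cycle_point(KimForgerParams())
        return Fixture(
            name=name, params={"A": 0.1},
            data={"state": state},
            expected={"period": 1.0, "period_tol": 0.01},
        )
    raise ParameterError(
        f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
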