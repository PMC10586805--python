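"""Capacitor-switch circuit analog of habituation.

Habituation is pictured as electric charge: a battery V keeps a small
capacitor C1 topped up with charge Q1 = C1 V; every period T a switch dumps
that packet onto a large capacitor C2 (the C2 >> C1 idealization transfers
the full Q1 each time), from which it leaks through a resistor R with time
constant R C2.  The accumulated charge is a sum of decaying steps,

    Q2(t) = sum_n C1 V theta(t - nT) exp(-(t - nT) / (R C2)),

with C2 initially uncharged and theta(0) = 1 (a switch contributes at its
own instant).  The charge suppresses the probability of the observed
behavioral event:  F_event(t) = F0 exp(-Q2(t)).  Only the per-switch peak
values are comparable to behavioral peaks -- the circuit transfers its
whole ON/OFF cycle of habituation instantaneously, so it does not show the
within-pulse decline of reversal probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .population import fisher_compare

__all__ = [
    "CircuitParams",
    "CapacitorSwitchCircuit",
    "simulate_charge",
    "event_fraction",
    "peak_series",
    "compare_peaks",
]


@dataclass(frozen=True)
class CircuitParams:
    """Circuit element values (arbitrary consistent units).

    f0 is the event fraction at zero accumulated charge.
    """

    v: float = 1.0
    c1: float = 1.2
    c2: float = 160.0
    r: float = 1.0
    t_switch: float = 30.0
    f0: float = 0.55

    def __post_init__(self) -> None:
        for name in ("v", "c1", "c2", "r", "t_switch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must be a fraction")
        if self.c2 / self.c1 < 10:
            warnings.warn(
                "full-packet transfer assumes C2 >> C1; "
                f"C2/C1 = {self.c2 / self.c1:.1f} is below 10",
                stacklevel=2,
            )

    @property
    def q1(self) -> float:
        """Charge packet delivered per switch closing."""
        return self.c1 * self.v

    @property
    def rc2(self) -> float:
        """Leak time constant of the second capacitor."""
        return self.r * self.c2

    def to_dict(self) -> dict:
        return {
            "V": self.v,
            "C1": self.c1,
            "C2": self.c2,
            "R": self.r,
            "T_switch": self.t_switch,
            "F0": self.f0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(
            v=d["V"], c1=d["C1"], c2=d["C2"], r=d["R"],
            t_switch=d["T_switch"], f0=d.get("F0", 0.55),
        )

    @classmethod
    def from_json(cls, path) -> "CircuitParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


class CapacitorSwitchCircuit:
    """Simulate charge accumulation and the implied event fraction."""

    def __init__(self, params: CircuitParams):
        self.params = params

    def charge(self, t, left_limit: bool = False) -> np.ndarray:
        """Q2 at time(s) t by explicit term-by-term summation.

        With ``left_limit=True``, a time landing exactly on a switch instant
        is evaluated just before the transfer (the n-th term excluded).
        """
        p = self.params
        t = np.atleast_1d(np.asarray(t, dtype=float))
        n_max = int(np.floor(t.max() / p.t_switch)) if t.size and t.max() >= 0 else -1
        q = np.zeros_like(t)
        for n in range(n_max + 1):
            dt = t - n * p.t_switch
            active = dt > 0 if left_limit else dt >= 0
            q[active] += p.q1 * np.exp(-dt[active] / p.rc2)
        return q if q.size > 1 else q

    def peak_charge(self, n_switches: int) -> np.ndarray:
        """Q2 just after each switch closing, by the geometric closed form.

        Q2(nT+) = Q1 (1 - rho^(n+1)) / (1 - rho) with rho = exp(-T / R C2).
        """
        if n_switches < 1:
            raise ValueError("n_switches must be >= 1")
        p = self.params
        rho = np.exp(-p.t_switch / p.rc2)
        n = np.arange(n_switches)
        return p.q1 * (1 - rho ** (n + 1)) / (1 - rho)

    @property
    def saturation_charge(self) -> float:
        """Limit of the post-switch peak charge: Q1 / (1 - exp(-T/RC2))."""
        p = self.params
        return p.q1 / (1 - np.exp(-p.t_switch / p.rc2))

    def event_fraction(self, t, left_limit: bool = False) -> np.ndarray:
        """F(t) = F0 exp(-Q2(t))."""
        return self.params.f0 * np.exp(-self.charge(t, left_limit=left_limit))

    def peak_event_fractions(self, n_switches: int) -> np.ndarray:
        """Event fraction at each switch-closing instant (post-transfer)."""
        return self.params.f0 * np.exp(-self.peak_charge(n_switches))

    def to_frame(self, t):
        import pandas as pd

        t = np.asarray(t, dtype=float)
        return pd.DataFrame(
            {"t_s": t, "Q2": self.charge(t), "F": self.event_fraction(t)}
        )


# functional wrappers ---------------------------------------------------------


def simulate_charge(params: CircuitParams, t_grid, left_limit: bool = False) -> np.ndarray:
    return CapacitorSwitchCircuit(params).charge(t_grid, left_limit=left_limit)


def event_fraction(params: CircuitParams, t_grid, left_limit: bool = False) -> np.ndarray:
    return CapacitorSwitchCircuit(params).event_fraction(t_grid, left_limit=left_limit)


def peak_series(params: CircuitParams, n_switches: int) -> np.ndarray:
    return CapacitorSwitchCircuit(params).peak_event_fractions(n_switches)


def compare_peaks(
    model_peaks: Sequence[float],
    empirical_peaks: Sequence[float],
    n_per_peak: int,
) -> np.ndarray:
    """Per-peak two-sided Fisher's exact p-values.

    Both series are converted to counts out of ``n_per_peak`` animals; a
    high p means the circuit peak is statistically indistinguishable from
    the behavioral peak at that sample size.
    """
    model = np.asarray(model_peaks, dtype=float)
    emp = np.asarray(empirical_peaks, dtype=float)
    if model.shape != emp.shape:
        raise ValueError("peak series must have equal length")
    out = np.empty(len(model))
    for i, (a, b) in enumerate(zip(model, emp)):
        out[i] = fisher_compare(
            int(round(a * n_per_peak)), n_per_peak, int(round(b * n_per_peak)), n_per_peak
        )
    return out
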