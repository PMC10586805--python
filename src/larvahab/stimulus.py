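"""Vibration stimulus protocols.

A pulsed vertical-vibration stimulus is described by four parameters: the
sinusoid frequency ``f`` (Hz), the dimensionless peak acceleration
``Gamma = A * omega**2 / g`` (force-proportional intensity, in units of
gravity), and the pulse timing ``t_on`` / ``t_off`` (s).  Pulse ``n`` begins
at ``t_start + n * (t_on + t_off)``; the first pulse carries index 0.
ON intervals are half-open ``[onset, onset + t_on)`` so that instants are
never counted twice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "G_STANDARD",
    "StimulusProtocol",
    "amplitude_for_gamma",
    "gamma_for_amplitude",
]

#: Standard acceleration of gravity (m/s^2); only enters unit conversion.
G_STANDARD = 9.81


def amplitude_for_gamma(gamma: float, frequency_hz: float) -> float:
    """Peak displacement amplitude A (m) for a given peak acceleration.

    With ``z(t) = A sin(2 pi f t)`` the dimensionless peak acceleration is
    ``Gamma = A (2 pi f)^2 / g``, hence ``A = Gamma g / (2 pi f)^2``.

    Parameters
    ----------
    gamma : dimensionless peak acceleration, >= 0.
    frequency_hz : vibration frequency, > 0.
    """
    if frequency_hz <= 0:
        raise ValueError(f"frequency_hz must be positive, got {frequency_hz}")
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")
    omega = 2.0 * math.pi * frequency_hz
    return gamma * G_STANDARD / omega**2


def gamma_for_amplitude(amplitude_m: float, frequency_hz: float) -> float:
    """Inverse of :func:`amplitude_for_gamma`: Gamma = A (2 pi f)^2 / g."""
    if frequency_hz <= 0:
        raise ValueError(f"frequency_hz must be positive, got {frequency_hz}")
    if amplitude_m < 0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude_m}")
    omega = 2.0 * math.pi * frequency_hz
    return amplitude_m * omega**2 / G_STANDARD


@dataclass(frozen=True)
class StimulusProtocol:
    """A train of identical vibration pulses.

    Attributes
    ----------
    frequency_hz : sinusoid frequency f (Hz).
    gamma : dimensionless peak acceleration.
    t_on : pulse duration (s), > 0.
    t_off : gap between pulses (s), >= 0.
    n_pulses : number of pulses, >= 1.
    t_start : onset of the first pulse (s).
    """

    frequency_hz: float
    gamma: float
    t_on: float
    t_off: float
    n_pulses: int
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.t_on <= 0:
            raise ValueError("t_on must be positive")
        if self.t_off < 0:
            raise ValueError("t_off must be non-negative")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be at least 1")

    @property
    def period(self) -> float:
        """Cycle period T = t_on + t_off (s)."""
        return self.t_on + self.t_off

    @property
    def span(self) -> float:
        """Time from t_start to the end of the last ON interval (s)."""
        return (self.n_pulses - 1) * self.period + self.t_on

    @property
    def amplitude_m(self) -> float:
        """Peak displacement of the platform (m)."""
        return amplitude_for_gamma(self.gamma, self.frequency_hz)

    @classmethod
    def continuous(
        cls, frequency_hz: float, gamma: float, duration: float, t_start: float = 0.0
    ) -> "StimulusProtocol":
        """Continuous vibration: a single pulse spanning ``duration`` seconds."""
        return cls(frequency_hz, gamma, t_on=duration, t_off=0.0, n_pulses=1, t_start=t_start)

    def pulse_onsets(self) -> np.ndarray:
        """Onset times of every pulse, strictly increasing (s)."""
        return self.t_start + np.arange(self.n_pulses) * self.period

    def is_on(self, t):
        """Whether the stimulus is ON at time(s) ``t``.

        ON intervals are half-open, so ``is_on(onset) is True`` and
        ``is_on(onset + t_on) is False``.  Accepts scalars or arrays.
        """
        t = np.asarray(t, dtype=float)
        tau = t - self.t_start
        k = np.floor_divide(tau, self.period)
        phase = tau - k * self.period
        on = (tau >= 0) & (k < self.n_pulses) & (phase < self.t_on)
        return bool(on) if on.ndim == 0 else on

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "gamma": self.gamma,
            "t_on_s": self.t_on,
            "t_off_s": self.t_off,
            "n_pulses": self.n_pulses,
            "t_start_s": self.t_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            frequency_hz=d["frequency_hz"],
            gamma=d["gamma"],
            t_on=d["t_on_s"],
            t_off=d["t_off_s"],
            n_pulses=int(d["n_pulses"]),
            t_start=d.get("t_start_s", 0.0),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StimulusProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))
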