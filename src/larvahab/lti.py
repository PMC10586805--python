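"""Linear time-invariant impulse-response prediction (and its failure).

If vibration response were linear and time-invariant, the reversal fraction
under any stimulus S would follow from the impulse response h via discrete
convolution, R[t] = sum_tau S[tau] h[t - tau] (1-s steps by default).  The
impulse response is measured with very short vibration bursts separated by
long gaps; applying it to a continuous stimulus predicts a sustained
elevated reversal rate, whereas real (and synthetic) populations
de-sensitize back to baseline -- the divergence is the habituation
signature this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .population import FractionTimeSeries
from .stimulus import StimulusProtocol

__all__ = ["ImpulseResponse", "lti_predict", "extract_irf"]


@dataclass
class ImpulseResponse:
    """Discrete impulse response h on a uniform grid."""

    h: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("h must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.h)) * self.dt


def lti_predict(h: ImpulseResponse, stimulus, dt: Optional[float] = None) -> np.ndarray:
    """Causal discrete convolution R = S * h.

    ``stimulus`` is a discrete series on the same grid spacing as ``h``
    (pass ``dt`` to assert the match).  Returns the full convolution, of
    length ``len(S) + len(h) - 1``.
    """
    if dt is not None and not np.isclose(dt, h.dt):
        raise ValueError(f"stimulus dt={dt} does not match impulse response dt={h.dt}")
    s = np.asarray(stimulus, dtype=float)
    if s.size == 0 or h.h.size == 0:
        return np.zeros(max(s.size + h.h.size - 1, 0))
    return np.convolve(s, h.h)


def extract_irf(
    ts: FractionTimeSeries,
    protocol: StimulusProtocol,
    baseline: Optional[float] = None,
    truncate: bool = True,
) -> ImpulseResponse:
    """Average the baseline-subtracted reversal response over impulse pulses.

    The protocol should deliver near-delta bursts (t_on no longer than one
    bin) separated by long gaps.  Segments following each pulse onset are
    aligned, averaged, and (by default) truncated where the mean response
    first returns to within one SEM of baseline after its peak.  The
    baseline is estimated from the last quarter of each inter-pulse gap
    when not supplied.
    """
    if protocol.t_on > ts.dt * (1 + 1e-9):
        raise ValueError("impulse extraction needs t_on <= one bin")
    onsets = protocol.pulse_onsets() - protocol.t_start  # ts.t is since first onset
    seg_len = int(np.floor(protocol.period / ts.dt)) if protocol.n_pulses > 1 else len(ts.t)
    segments = []
    t0 = 0.0
    for onset in onsets:
        sel = np.where(ts.t >= onset)[0]
        if len(sel) == 0:
            continue
        seg = ts.f_rev[sel[0] : sel[0] + seg_len]
        if len(seg) == seg_len:
            if not segments:
                t0 = float(ts.t[sel[0]] - onset)  # bin-center offset from onset
            segments.append(seg)
    if not segments:
        raise ValueError("no post-impulse data to average")
    mean = np.mean(segments, axis=0)

    if baseline is None:
        tail = max(seg_len // 4, 1)
        baseline = float(np.mean([seg[-tail:] for seg in segments]))
    h = mean - baseline

    if truncate and len(h) > 1:
        n_per_bin = float(np.mean(ts.n)) * len(segments)
        p = np.clip(baseline, 1e-12, 1 - 1e-12)
        sem = max(np.sqrt(p * (1 - p) / n_per_bin), 1e-4)
        peak = int(np.argmax(h))
        settled = np.where(h[peak:] <= sem)[0]
        if len(settled):
            h = h[: peak + settled[0] + 1]
    return ImpulseResponse(h=h, dt=ts.dt, t0=t0)
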