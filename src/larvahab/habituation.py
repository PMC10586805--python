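"""Habituation kinetics: de-/re-sensitization models, fits, and bootstrap.

During sustained vibration the reversal fraction decays exponentially from
its naive level toward baseline (de-sensitization, time constant tau_des).
While the stimulus is off, sensitivity recovers exponentially
(re-sensitization, time constant tau_res), and the recovery accelerates with
pulse number: tau_res is a schedule tau_res(n), dropping below one second
after a few pulses.  The pulse-train prediction combines both:

    F_rev(t) = F0_rev * [1 - exp(-T_OFF / tau_res(n-1))] * exp(-(t - nT)/tau_des)

while the stimulus is ON following pulse n (recovery factor 1 for the first
pulse), and 0 while it is OFF -- it is a reversal-event probability, not an
instantaneous behavioral state.

Fitting follows the study's procedure: least squares of y0 + A exp(-t/tau)
with y0 fixed to the baseline fraction, and a parametric bootstrap for the
uncertainty -- each data point resampled from a Gaussian centered on its
mean with its SEM as width, the fit repeated (1000 times by default), and
the standard deviation of the fitted constants reported as the uncertainty.
Fit comparisons use an SD-based z statistic on the bootstrap sets so the
number of bootstrap resamples does not affect significance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .behavior import BehaviorLabel, ResponseRecord
from .stimulus import StimulusProtocol

__all__ = [
    "TauResSchedule",
    "HabituationParams",
    "WILDTYPE_PARAMS",
    "desensitization_curve",
    "resensitization_curve",
    "recovery_factor",
    "predict_pulse_train",
    "ExponentialDecayModel",
    "ExponentialFitResults",
    "fit_exponential",
    "compare_fits",
    "RecoveryModel",
    "RecoveryFitResults",
    "RatioCurve",
    "recovery_ratio_curve",
    "fit_resensitization",
]


@dataclass(frozen=True)
class TauResSchedule:
    """Pulse-indexed re-sensitization time constants tau_res(n) (s).

    ``values[n]`` applies to the recovery following pulse ``n``; indices past
    the end use ``tail``.  The default wild-type schedule keeps the slow
    first-recovery constant for the first two gaps and then collapses to a
    sub-second tail, matching the observed near-instant recovery by the
    fourth pulse.
    """

    values: Tuple[float, ...]
    tail: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values) or self.tail <= 0:
            raise ValueError("all re-sensitization time constants must be positive")

    def __call__(self, n: int) -> float:
        if n < 0:
            raise ValueError("tau_res index must be >= 0")
        return self.values[n] if n < len(self.values) else self.tail

    @classmethod
    def standard(cls, tau_res_0: float, tail: float = 0.8) -> "TauResSchedule":
        return cls(values=(tau_res_0, tau_res_0), tail=tail)


@dataclass(frozen=True)
class HabituationParams:
    """Parameters of the reversal habituation model.

    f0_rev
        Naive (fully sensitized) reversal fraction at pulse onset for the
        reference strong stimulus; just over half of wild-type animals
        reverse at f=500 Hz, Gamma=2.
    tau_des
        De-sensitization time constant (s).
    tau_res
        Re-sensitization schedule tau_res(n).
    baseline_rev
        Spontaneous reversal fraction with no stimulus.
    """

    f0_rev: float = 0.55
    tau_des: float = 18.9
    tau_res: TauResSchedule = field(default_factory=lambda: TauResSchedule.standard(5.3))
    baseline_rev: float = 0.03

    def __post_init__(self) -> None:
        if self.tau_des <= 0:
            raise ValueError("tau_des must be positive")
        for name in ("f0_rev", "baseline_rev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")


WILDTYPE_PARAMS = HabituationParams()


def desensitization_curve(params: HabituationParams, t, offset: bool = False):
    """Reversal fraction t seconds into a sustained stimulus.

    ``F0_rev * exp(-t / tau_des)``, or the offset form
    ``baseline + (F0_rev - baseline) * exp(-t / tau_des)`` used for fitting
    with the baseline as fixed y0.
    """
    t = np.asarray(t, dtype=float)
    decay = np.exp(-t / params.tau_des)
    if offset:
        return params.baseline_rev + (params.f0_rev - params.baseline_rev) * decay
    return params.f0_rev * decay


def recovery_factor(params: HabituationParams, t_off: float, pulse_n: int) -> float:
    """Fraction of sensitivity recovered before pulse ``pulse_n``.

    The first pulse meets a naive animal (factor 1); pulse n >= 1 recovers
    ``1 - exp(-t_off / tau_res(n-1))`` during the preceding gap.
    """
    if pulse_n == 0:
        return 1.0
    if t_off < 0:
        raise ValueError("t_off must be non-negative")
    return 1.0 - float(np.exp(-t_off / params.tau_res(pulse_n - 1)))


def resensitization_curve(params: HabituationParams, t_off, pulse_n: int, absolute: bool = False):
    """Recovery of reversal sensitivity after pulse ``pulse_n - 1``.

    ``1 - exp(-t_off / tau_res(pulse_n - 1))``; with ``absolute=True`` the
    curve is scaled by F0_rev to give the recovered reversal fraction.
    """
    if pulse_n < 1:
        raise ValueError("resensitization applies to pulses >= 1")
    t_off = np.asarray(t_off, dtype=float)
    if np.any(t_off < 0):
        raise ValueError("t_off must be non-negative")
    rec = 1.0 - np.exp(-t_off / params.tau_res(pulse_n - 1))
    return params.f0_rev * rec if absolute else rec


def predict_pulse_train(
    params: HabituationParams, protocol: StimulusProtocol, dt: float = 1.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Reversal-event probability over a pulse train.

    Returns ``(t, f_rev)`` on a uniform grid starting at the first pulse
    onset.  During the ON window of pulse n the probability is
    ``F0_rev * r_n * exp(-(t - t_n)/tau_des)`` with r_n the recovery factor;
    it is zero while the stimulus is OFF.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(protocol.t_start, protocol.t_start + protocol.span + dt / 2, dt)
    f = np.zeros_like(t)
    for n, onset in enumerate(protocol.pulse_onsets()):
        r = recovery_factor(params, protocol.t_off, n)
        in_on = (t >= onset) & (t < onset + protocol.t_on)
        f[in_on] = params.f0_rev * r * np.exp(-(t[in_on] - onset) / params.tau_des)
    return t, f


# ---------------------------------------------------------------------------
# Exponential-decay fitting with parametric bootstrap
# ---------------------------------------------------------------------------


def _lsq_decay(t, y, sem, y0, tau_bounds, amp_bounds, tau_init=10.0, n_animals=None):
    """Least squares of y0 + A exp(-t/tau); returns (A, tau, ok).

    When ``n_animals`` is given, binomial weights are taken from the
    *fitted* curve in a second pass (IRLS); weights read off the observed
    points would correlate with the noise and bias the time constant low.
    """
    a0 = float(np.clip(y[0] - y0, amp_bounds[0] + 1e-9, amp_bounds[1] - 1e-9))
    tau0 = float(np.clip(tau_init, tau_bounds[0] * 1.01, tau_bounds[1] * 0.99))
    bounds = ([amp_bounds[0], tau_bounds[0]], [amp_bounds[1], tau_bounds[1]])

    def _solve(w):
        def resid(p):
            a, tau = p
            r = y0 + a * np.exp(-t / tau) - y
            return r * w if w is not None else r

        res = optimize.least_squares(resid, x0=[a0, tau0], bounds=bounds)
        return float(res.x[0]), float(res.x[1]), bool(res.success)

    if n_animals is not None:
        a, tau, ok = _solve(None)
        p_fit = np.clip(y0 + a * np.exp(-t / tau), 1e-4, 1 - 1e-4)
        w = 1.0 / np.sqrt(p_fit * (1 - p_fit) / n_animals)
        return _solve(w)
    if sem is not None and np.any(sem > 0):
        return _solve(1.0 / np.maximum(sem, 1e-6))
    return _solve(None)


@dataclass
class ExponentialFitResults:
    """Results of an exponential habituation fit.

    ``tau``/``amplitude`` are the point estimates of ``y0 + A exp(-t/tau)``
    with ``y0`` held fixed at the supplied baseline; ``sd_tau`` is the
    parametric-bootstrap standard deviation and ``bootstrap_taus`` the full
    set of resampled fits (used by :func:`compare_fits`).
    """

    tau: float
    amplitude: float
    y0: float
    sd_tau: float
    sd_amplitude: float
    bootstrap_taus: np.ndarray
    n_boot: int
    seed: Optional[int]
    converged: bool
    model: "ExponentialDecayModel" = field(repr=False, default=None)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.y0 + self.amplitude * np.exp(-t / self.tau)

    def compare(self, other) -> Tuple[float, float]:
        return compare_fits(self, other)

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau,
            "sd_tau_s": self.sd_tau,
            "amplitude": self.amplitude,
            "y0": self.y0,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        lines = [
            "Exponential habituation fit: y0 + A exp(-t/tau)",
            "-" * 48,
            f"tau        {self.tau:10.3f} s   (bootstrap sd {self.sd_tau:.3f})",
            f"A          {self.amplitude:10.4f}     (bootstrap sd {self.sd_amplitude:.4f})",
            f"y0 (fixed) {self.y0:10.4f}",
            f"n_boot     {self.n_boot:10d}",
            f"converged  {str(self.converged):>10}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data (with SEM bars when available) and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        if m is not None:
            if m.sem is not None:
                ax.errorbar(m.t, m.f, yerr=m.sem, fmt="o", ms=3, label="data")
            else:
                ax.plot(m.t, m.f, "o", ms=3, label="data")
            tt = np.linspace(m.t.min(), m.t.max(), 200)
            ax.plot(tt, self.predict(tt), "-", label=f"fit (tau={self.tau:.1f} s)")
        ax.set_xlabel("time since stimulus onset (s)")
        ax.set_ylabel("F_REV")
        ax.legend()
        return ax


class ExponentialDecayModel:
    """De-/re-sensitization exponential model for a fraction time series.

    Parameters
    ----------
    t, f : time points (s) and measured fractions.
    sem : per-point standard errors (optional; enables weighting and a
        nonzero bootstrap spread).
    y0 : fixed offset -- the baseline fraction the decay relaxes to.
    n_animals : animals per point; when known, the fit uses binomial
        weights from the fitted curve (IRLS) instead of the observed SEMs.
    """

    def __init__(self, t, f, sem=None, y0: float = 0.0, n_animals=None):
        self.t = np.asarray(t, dtype=float)
        self.f = np.asarray(f, dtype=float)
        self.sem = None if sem is None else np.asarray(sem, dtype=float)
        self.n_animals = n_animals
        if self.sem is None and n_animals is not None:
            # binomial SEM from the animal count (add-half, never zero)
            n = np.broadcast_to(np.asarray(n_animals, dtype=float), self.f.shape)
            p = (self.f * n + 0.5) / (n + 1.0)
            self.sem = np.sqrt(p * (1 - p) / n)
        self.y0 = float(y0)
        if self.t.shape != self.f.shape:
            raise ValueError("t and f must have the same shape")
        if self.sem is not None and self.sem.shape != self.t.shape:
            raise ValueError("sem must match t in shape")
        if self.sem is not None and np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")
        if len(self.t) < 4:
            raise ValueError("need at least 4 points for an exponential fit")

    @classmethod
    def from_timeseries(cls, ts, y0: Optional[float] = None) -> "ExponentialDecayModel":
        """Build from an object exposing t, f_rev, sem_rev (e.g. a binned
        count series); ``y0`` defaults to the series' recorded baseline."""
        sem = getattr(ts, "sem_rev", None)
        n_animals = getattr(ts, "n_active", getattr(ts, "n", None))
        if y0 is None:
            y0 = getattr(ts, "baseline_rev", 0.0)
        return cls(ts.t, ts.f_rev, sem=sem, y0=y0, n_animals=n_animals)

    def fit(
        self,
        n_boot: int = 1000,
        seed: Optional[int] = None,
        tau_bounds: Tuple[float, float] = (0.1, 300.0),
        amp_bounds: Tuple[float, float] = (0.0, 1.0),
        tau_init: float = 10.0,
    ) -> ExponentialFitResults:
        """Point fit plus parametric bootstrap of the uncertainty.

        Each bootstrap replicate redraws every data point from a Gaussian
        centered at the observed value with the point's SEM as width
        (negative draws clipped to zero), refits, and the standard deviation
        of the resampled time constants is reported as ``sd_tau``.  All-zero
        SEMs give identical replicates and ``sd_tau = 0``.
        """
        a, tau, ok = _lsq_decay(
            self.t, self.f, self.sem, self.y0, tau_bounds, amp_bounds, tau_init,
            n_animals=self.n_animals,
        )
        if not ok:
            raise RuntimeError(
                f"exponential fit did not converge (tau={tau}, A={a}, "
                f"n={len(self.t)} points)"
            )
        rng = np.random.default_rng(seed)
        if n_boot <= 0 or self.sem is None or not np.any(self.sem > 0):
            taus = np.full(max(n_boot, 1), tau)
            sd_tau = 0.0
            sd_amp = 0.0
        else:
            taus = np.empty(n_boot)
            amps = np.empty(n_boot)
            for b in range(n_boot):
                y = rng.normal(self.f, self.sem)
                np.clip(y, 0.0, None, out=y)
                amps[b], taus[b], _ = _lsq_decay(
                    self.t, y, self.sem, self.y0, tau_bounds, amp_bounds, tau_init,
                    n_animals=self.n_animals,
                )
            sd_tau = float(np.std(taus))
            sd_amp = float(np.std(amps))
        return ExponentialFitResults(
            tau=tau,
            amplitude=a,
            y0=self.y0,
            sd_tau=sd_tau,
            sd_amplitude=sd_amp,
            bootstrap_taus=taus,
            n_boot=n_boot,
            seed=seed,
            converged=ok,
            model=self,
        )


def fit_exponential(
    t, f, sem=None, y0: float = 0.0, n_boot: int = 1000, seed: Optional[int] = None
) -> ExponentialFitResults:
    """Convenience wrapper: fit y0 + A exp(-t/tau) with fixed y0."""
    return ExponentialDecayModel(t, f, sem=sem, y0=y0).fit(n_boot=n_boot, seed=seed)


def compare_fits(fit_a, fit_b) -> Tuple[float, float]:
    """Two-sided comparison of two fitted time constants.

    Uses the bootstrap sets: ``z = (tau_A - tau_B) / sqrt(sd_A^2 + sd_B^2)``
    with the standard deviations of the bootstrap sets in the denominator,
    so the statistic does not grow with the number of bootstrap resamples.
    Returns ``(z, p)`` with p from the t distribution on the pooled degrees
    of freedom.
    """
    for f in (fit_a, fit_b):
        if getattr(f, "bootstrap_taus", None) is None or len(f.bootstrap_taus) == 0:
            raise ValueError("both fits must carry bootstrap sets")
    a = np.asarray(fit_a.bootstrap_taus, dtype=float)
    b = np.asarray(fit_b.bootstrap_taus, dtype=float)
    denom = float(np.sqrt(np.var(a) + np.var(b)))
    diff = float(np.mean(a) - np.mean(b))
    if denom == 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        return z, 1.0 if diff == 0 else 0.0
    z = diff / denom
    df = len(a) + len(b) - 2
    p = 2.0 * float(stats.t.sf(abs(z), df))
    return z, min(p, 1.0)


# ---------------------------------------------------------------------------
# Re-sensitization ratio analysis
# ---------------------------------------------------------------------------


@dataclass
class RatioCurve:
    """Recovery ratios F_n,REV / F_{n-1},REV over a family of OFF times."""

    pulse_n: int
    t_off: np.ndarray
    ratio: np.ndarray
    sem: np.ndarray
    n_prev: np.ndarray  # reversing animals at pulse n-1 per condition

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pulse_n": self.pulse_n,
                "t_off_s": self.t_off,
                "ratio": self.ratio,
                "sem": self.sem,
                "n_prev": self.n_prev,
            }
        )


def recovery_ratio_curve(
    records_by_toff: Mapping[float, Sequence[ResponseRecord]],
    pulse_n: int,
    min_count: int = 3,
) -> RatioCurve:
    """Per-condition ratio of consecutive reversal fractions.

    For each OFF time the ratio ``F_n,REV / F_{n-1},REV`` reduces to the
    count ratio ``k_n / k_{n-1}`` over the same animals.  Conditions with
    fewer than ``min_count`` reversing animals at pulse n-1 carry too little
    information and are dropped (ratio undefined when the denominator is 0).
    SEMs are binomial, with an Agresti-style half-count guard so boundary
    ratios keep a nonzero width.
    """
    if pulse_n < 1:
        raise ValueError("ratios need pulse_n >= 1")
    t_offs, ratios, sems, ns = [], [], [], []
    for t_off in sorted(records_by_toff):
        records = records_by_toff[t_off]
        prev_rev = {
            r.larva_id for r in records if r.pulse_n == pulse_n - 1 and r.label is BehaviorLabel.REV
        }
        curr_rev = {
            r.larva_id for r in records if r.pulse_n == pulse_n and r.label is BehaviorLabel.REV
        }
        k_prev = len(prev_rev)
        if k_prev < max(min_count, 1):
            continue
        k = len(curr_rev)
        q = k / k_prev
        q_tilde = (k + 0.5) / (k_prev + 1.0)
        sem = float(np.sqrt(q_tilde * (1 - q_tilde) / k_prev))
        t_offs.append(float(t_off))
        ratios.append(q)
        sems.append(sem)
        ns.append(k_prev)
    if not t_offs:
        raise ValueError("no condition retained enough reversing animals for a ratio")
    return RatioCurve(
        pulse_n=pulse_n,
        t_off=np.array(t_offs),
        ratio=np.array(ratios),
        sem=np.array(sems),
        n_prev=np.array(ns),
    )


@dataclass
class RecoveryFitResults:
    """Fit of A (1 - exp(-t_off / tau)) to a recovery-ratio curve."""

    tau: float
    amplitude: float
    amplitude_fixed: bool
    sd_tau: float
    bootstrap_taus: np.ndarray
    n_boot: int
    seed: Optional[int]
    converged: bool

    def predict(self, t_off) -> np.ndarray:
        t_off = np.asarray(t_off, dtype=float)
        return self.amplitude * (1.0 - np.exp(-t_off / self.tau))

    def compare(self, other) -> Tuple[float, float]:
        return compare_fits(self, other)

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau,
            "sd_tau_s": self.sd_tau,
            "amplitude": self.amplitude,
            "amplitude_fixed": self.amplitude_fixed,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "converged": self.converged,
        }

    def summary(self) -> str:
        fixed = " (fixed)" if self.amplitude_fixed else ""
        return "\n".join(
            [
                "Re-sensitization fit: A (1 - exp(-t_off/tau))",
                "-" * 48,
                f"tau      {self.tau:10.3f} s   (bootstrap sd {self.sd_tau:.3f})",
                f"A        {self.amplitude:10.4f}{fixed}",
                f"n_boot   {self.n_boot:10d}",
            ]
        )


class RecoveryModel:
    """Saturating-exponential model of sensitivity recovery vs OFF time.

    Fits ``ratio(t_off) = A (1 - exp(-t_off / tau))``.  The free amplitude
    absorbs incomplete recovery of the reference pulse and the
    individual-level repeat attenuation, so the fitted asymptote provides
    the normalization; pass ``fix_amplitude`` to normalize by an externally
    estimated plateau instead.

    When per-condition counts are supplied (``n_prev`` reversing animals at
    the reference pulse, of which ``ratio * n_prev`` reversed again) the fit
    maximizes the conditional binomial likelihood, which avoids the bias of
    noise-estimated weights; otherwise it falls back to SEM-weighted least
    squares.  The bootstrap matches the route: binomial count resampling
    around the fitted curve, or Gaussian resampling of each point by its
    SEM.
    """

    def __init__(self, t_off, ratio, sem=None, n_prev=None):
        self.t_off = np.asarray(t_off, dtype=float)
        self.ratio = np.asarray(ratio, dtype=float)
        self.sem = None if sem is None else np.asarray(sem, dtype=float)
        self.n_prev = None if n_prev is None else np.asarray(n_prev, dtype=int)
        if len(self.t_off) < 2:
            raise ValueError("need at least 2 OFF times to fit a recovery curve")

    @classmethod
    def from_curve(cls, curve: RatioCurve) -> "RecoveryModel":
        return cls(curve.t_off, curve.ratio, sem=curve.sem, n_prev=curve.n_prev)

    def _fit_wls(self, y, fix_amplitude, tau_bounds, amp_bounds, tau_init):
        w = None
        if self.sem is not None and np.any(self.sem > 0):
            w = 1.0 / np.maximum(self.sem, 1e-6)

        if fix_amplitude is not None:

            def resid(p):
                r = fix_amplitude * (1 - np.exp(-self.t_off / p[0])) - y
                return r * w if w is not None else r

            res = optimize.least_squares(
                resid, x0=[tau_init], bounds=([tau_bounds[0]], [tau_bounds[1]])
            )
            return fix_amplitude, float(res.x[0]), bool(res.success)

        def resid(p):
            a, tau = p
            r = a * (1 - np.exp(-self.t_off / tau)) - y
            return r * w if w is not None else r

        a0 = float(np.clip(np.max(y), amp_bounds[0] * 2, amp_bounds[1] * 0.99))
        res = optimize.least_squares(
            resid,
            x0=[a0, tau_init],
            bounds=([amp_bounds[0], tau_bounds[0]], [amp_bounds[1], tau_bounds[1]]),
        )
        return float(res.x[0]), float(res.x[1]), bool(res.success)

    def _fit_mle(self, k, fix_amplitude, tau_bounds, amp_bounds, tau_init):
        n = self.n_prev
        t = self.t_off

        def nll(p):
            if fix_amplitude is not None:
                a, tau = fix_amplitude, p[0]
            else:
                a, tau = p
            q = np.clip(a * (1 - np.exp(-t / tau)), 1e-9, 1 - 1e-9)
            return -np.sum(k * np.log(q) + (n - k) * np.log(1 - q))

        if fix_amplitude is not None:
            res = optimize.minimize(
                nll, x0=[tau_init], bounds=[tau_bounds], method="L-BFGS-B"
            )
            return fix_amplitude, float(res.x[0]), bool(res.success)
        a0 = float(np.clip(np.max(k / np.maximum(n, 1)), 0.05, min(amp_bounds[1], 0.999)))
        res = optimize.minimize(
            nll,
            x0=[a0, tau_init],
            bounds=[(1e-3, min(amp_bounds[1], 0.9999)), tau_bounds],
            method="L-BFGS-B",
        )
        return float(res.x[0]), float(res.x[1]), bool(res.success)

    def fit(
        self,
        n_boot: int = 1000,
        seed: Optional[int] = None,
        tau_bounds: Tuple[float, float] = (0.01, 300.0),
        amp_bounds: Tuple[float, float] = (1e-6, 1.2),
        fix_amplitude: Optional[float] = None,
        tau_init: float = 5.0,
    ) -> RecoveryFitResults:
        use_mle = self.n_prev is not None
        if use_mle:
            k_obs = np.round(self.ratio * self.n_prev).astype(int)
            amp, tau, ok = self._fit_mle(
                k_obs, fix_amplitude, tau_bounds, amp_bounds, tau_init
            )
        else:
            amp, tau, ok = self._fit_wls(
                self.ratio, fix_amplitude, tau_bounds, amp_bounds, tau_init
            )
        if not ok:
            raise RuntimeError("recovery fit did not converge")

        rng = np.random.default_rng(seed)
        taus = np.empty(max(n_boot, 0))
        if use_mle:
            q_hat = np.clip(amp * (1 - np.exp(-self.t_off / tau)), 1e-9, 1 - 1e-9)
            for b in range(n_boot):
                k = rng.binomial(self.n_prev, q_hat)
                _, taus[b], _ = self._fit_mle(
                    k, fix_amplitude, tau_bounds, amp_bounds, tau_init
                )
            sd_tau = float(np.std(taus)) if n_boot else 0.0
        elif self.sem is None or not np.any(self.sem > 0):
            taus = np.full(max(n_boot, 1), tau)
            sd_tau = 0.0
        else:
            for b in range(n_boot):
                y = rng.normal(self.ratio, self.sem)
                np.clip(y, 0.0, None, out=y)
                _, taus[b], _ = self._fit_wls(
                    y, fix_amplitude, tau_bounds, amp_bounds, tau_init
                )
            sd_tau = float(np.std(taus)) if n_boot else 0.0
        return RecoveryFitResults(
            tau=tau,
            amplitude=amp,
            amplitude_fixed=fix_amplitude is not None,
            sd_tau=sd_tau,
            bootstrap_taus=taus if n_boot else np.full(1, tau),
            n_boot=n_boot,
            seed=seed,
            converged=ok,
        )


def fit_resensitization(
    records_by_toff: Mapping[float, Sequence[ResponseRecord]],
    pulse_n: int,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    min_count: int = 3,
) -> RecoveryFitResults:
    """Ratio curve plus recovery fit in one call; returns the fitted
    tau_res for the recovery preceding pulse ``pulse_n``."""
    curve = recovery_ratio_curve(records_by_toff, pulse_n, min_count=min_count)
    return RecoveryModel.from_curve(curve).fit(n_boot=n_boot, seed=seed)
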