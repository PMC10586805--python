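"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the study's recordings:

``generate_response_records``
    Per-larva, per-pulse behavior labels.  The first pulse draws from the
    naive response fractions (scaled by a stimulus-strength sensitivity
    factor and floored at the spontaneous baselines); subsequent pulses
    evolve each larva's label through a one-way transition kernel whose
    REV->REV entry is modulated by the re-sensitization recovery factor
    ``1 - exp(-T_OFF / tau_res(n-1))``.  Weaker behaviors never transition
    back into reverse crawling, so habituation is strictly one-way at the
    individual level while the population reversal fraction still carries
    the OFF-time dependence the ratio analysis fits.

``generate_count_timeseries``
    Binned binomial counts of reversing/stopped larvae around a
    deterministic population-rate curve: at each pulse onset the reversal
    rate jumps to its (recovery-scaled) peak and then relaxes exponentially
    toward baseline with the de-sensitization time constant, continuing to
    relax through OFF periods (turning the stimulus off does not itself
    perturb the reversal fraction).

``generate_trajectories``
    Geometric 2D paths realizing a list of response records: constant-speed
    forward runs, stops of sub-threshold speed, pauses/turns distinguished
    by the resumed heading, and reversals as sustained motion opposing the
    head vector -- exactly the features the classifier keys on, sampled at
    the recording frame rate.

All three are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .behavior import LABEL_ORDER, BehaviorLabel, ResponseRecord, Trajectory
from .habituation import HabituationParams, TauResSchedule, recovery_factor
from .stimulus import StimulusProtocol

__all__ = [
    "STRAIN_PRESETS",
    "StrainPreset",
    "TransitionKernel",
    "GeneratorConfig",
    "CountTimeSeries",
    "sensitivity_factor",
    "generate_response_records",
    "generate_count_timeseries",
    "generate_trajectories",
]


@dataclass(frozen=True)
class StrainPreset:
    """Published habituation constants for one genotype."""

    name: str
    tau_des: float
    tau_res_0: float

    def __post_init__(self) -> None:
        if self.tau_des <= 0 or self.tau_res_0 <= 0:
            raise ValueError("time constants must be positive")


#: De-/re-sensitization time constants (s) per strain: wild type plus the
#: three memory-deficient mutants (rutabaga, dunce, calmodulin-null).
STRAIN_PRESETS: Dict[str, StrainPreset] = {
    "wildtype": StrainPreset("wildtype", tau_des=18.9, tau_res_0=5.3),
    "rut": StrainPreset("rut", tau_des=5.2, tau_res_0=3.6),
    "dnc": StrainPreset("dnc", tau_des=14.3, tau_res_0=9.8),
    "cam0": StrainPreset("cam0", tau_des=25.6, tau_res_0=6.5),
}


_LABEL_INDEX = {lab: i for i, lab in enumerate(LABEL_ORDER)}
_I_CONT, _I_PAUSE, _I_TURN, _I_REV = (
    _LABEL_INDEX[BehaviorLabel.CONT],
    _LABEL_INDEX[BehaviorLabel.PAUSE],
    _LABEL_INDEX[BehaviorLabel.TURN],
    _LABEL_INDEX[BehaviorLabel.REV],
)


def _default_kernel_matrix() -> np.ndarray:
    # rows/cols ordered CONT, PAUSE, TURN, REV; rows sum to 1.
    m = np.zeros((4, 4))
    m[_I_CONT, _I_CONT] = 1.0  # continuation is absorbing
    m[_I_PAUSE, _I_PAUSE] = 0.50
    m[_I_PAUSE, _I_CONT] = 0.50
    m[_I_TURN, _I_TURN] = 0.55
    m[_I_TURN, _I_PAUSE] = 0.25
    m[_I_TURN, _I_CONT] = 0.20
    m[_I_REV, _I_REV] = 0.85
    m[_I_REV, _I_TURN] = 0.10
    m[_I_REV, _I_PAUSE] = 0.03
    m[_I_REV, _I_CONT] = 0.02
    return m


@dataclass(frozen=True)
class TransitionKernel:
    """Lag-1 one-way kernel for individual behavior sequences.

    The matrix gives P(label at pulse n+1 | label at pulse n) at full
    recovery.  Entries into REV from weaker behaviors must be zero (the
    one-way property); the REV->REV entry is additionally multiplied by the
    recovery factor for the gap preceding each pulse, the deficit being
    redistributed over the REV row's weaker outcomes in proportion to their
    base weights.
    """

    matrix: np.ndarray = field(default_factory=_default_kernel_matrix)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("kernel must be 4x4")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("kernel rows must be non-negative and sum to 1")
        for i, lab in enumerate(LABEL_ORDER):
            if lab is not BehaviorLabel.REV and m[i, _I_REV] != 0:
                raise ValueError("entries into REV from weaker behaviors must be zero")
        object.__setattr__(self, "matrix", m)

    @property
    def rev_repeat(self) -> float:
        return float(self.matrix[_I_REV, _I_REV])

    def row_with_recovery(self, from_index: int, recovery: float) -> np.ndarray:
        """Transition row for a given prior label and recovery factor."""
        row = self.matrix[from_index].copy()
        if from_index != _I_REV or recovery >= 1.0:
            return row
        stay = row[_I_REV] * recovery
        deficit = row[_I_REV] - stay
        row[_I_REV] = stay
        others = row.copy()
        others[_I_REV] = 0.0
        weight = others.sum()
        if weight > 0:
            row += others / weight * deficit
        else:
            row[_I_CONT] += deficit
        return row


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the synthetic generators need, seed included.

    ``baseline_rev``/``baseline_stop`` are the no-stimulus behavior
    fractions; ``f0_rev``/``f0_stop`` the naive fractions at the reference
    strong stimulus (f = 500 Hz, Gamma = 2).  The sensitivity factor --
    a product of logistic thresholds in Gamma and log-frequency, normalized
    to 1 at the reference condition -- interpolates between them, giving
    the sharp reversal threshold seen across the stimulus-intensity plane.
    """

    habituation: HabituationParams = field(default_factory=HabituationParams)
    kernel: TransitionKernel = field(default_factory=TransitionKernel)
    baseline_stop: float = 0.24
    f0_stop: float = 0.90
    pause_share: float = 0.35  # pause fraction of non-REV stops (rest are turns)
    n_larvae: int = 100
    seed: int = 0
    dt: float = 1.0
    strain_name: str = "wildtype"
    gamma_half: float = 1.0
    gamma_width: float = 0.15
    f_half_hz: float = 150.0
    log_f_width: float = 0.3
    reference_condition: Tuple[float, float] = (500.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("baseline_stop", "f0_stop", "pause_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.habituation.baseline_rev > self.baseline_stop:
            raise ValueError("baseline_rev must not exceed baseline_stop")
        if self.habituation.f0_rev > self.f0_stop:
            raise ValueError("f0_rev must not exceed f0_stop")
        if self.n_larvae < 0:
            raise ValueError("n_larvae must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def baseline_rev(self) -> float:
        return self.habituation.baseline_rev

    @classmethod
    def from_preset(cls, strain: str, **overrides) -> "GeneratorConfig":
        """Config with a strain's published time constants."""
        preset = STRAIN_PRESETS[strain]
        hab = HabituationParams(
            tau_des=preset.tau_des,
            tau_res=TauResSchedule.standard(preset.tau_res_0),
        )
        return cls(habituation=hab, strain_name=strain, **overrides)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        hab = self.habituation
        return {
            "strain_name": self.strain_name,
            "n_larvae": self.n_larvae,
            "seed": self.seed,
            "dt_s": self.dt,
            "baseline_rev": hab.baseline_rev,
            "baseline_stop": self.baseline_stop,
            "f0_rev": hab.f0_rev,
            "f0_stop": self.f0_stop,
            "pause_share": self.pause_share,
            "tau_des_s": hab.tau_des,
            "tau_res_s": list(hab.tau_res.values),
            "tau_res_tail_s": hab.tau_res.tail,
            "kernel": self.kernel.matrix.tolist(),
            "gamma_half": self.gamma_half,
            "gamma_width": self.gamma_width,
            "f_half_hz": self.f_half_hz,
            "log_f_width": self.log_f_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        if "seed" not in d:
            raise ValueError("generator config requires an explicit seed")
        hab = HabituationParams(
            f0_rev=d.get("f0_rev", 0.55),
            tau_des=d.get("tau_des_s", 18.9),
            tau_res=TauResSchedule(
                values=tuple(d.get("tau_res_s", (5.3, 5.3))),
                tail=d.get("tau_res_tail_s", 0.8),
            ),
            baseline_rev=d.get("baseline_rev", 0.03),
        )
        kernel = (
            TransitionKernel(np.asarray(d["kernel"], dtype=float))
            if "kernel" in d
            else TransitionKernel()
        )
        return cls(
            habituation=hab,
            kernel=kernel,
            baseline_stop=d.get("baseline_stop", 0.24),
            f0_stop=d.get("f0_stop", 0.90),
            pause_share=d.get("pause_share", 0.35),
            n_larvae=int(d.get("n_larvae", 100)),
            seed=int(d["seed"]),
            dt=d.get("dt_s", 1.0),
            strain_name=d.get("strain_name", "wildtype"),
            gamma_half=d.get("gamma_half", 1.0),
            gamma_width=d.get("gamma_width", 0.15),
            f_half_hz=d.get("f_half_hz", 150.0),
            log_f_width=d.get("log_f_width", 0.3),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sensitivity_factor(config: GeneratorConfig, frequency_hz: float, gamma: float) -> float:
    """Stimulus-strength scaling in [0, 1], 1 at the reference condition.

    Product of a logistic threshold in peak acceleration and one in
    log-frequency; at Gamma = 0 it is effectively zero, so generated
    responses sit at the spontaneous baselines.
    """

    def _raw(f: float, g: float) -> float:
        sg = 1.0 / (1.0 + math.exp(-(g - config.gamma_half) / config.gamma_width))
        sf = 1.0 / (
            1.0
            + math.exp(
                -(math.log(max(f, 1e-9)) - math.log(config.f_half_hz)) / config.log_f_width
            )
        )
        return sg * sf

    ref_f, ref_g = config.reference_condition
    return min(_raw(frequency_hz, gamma) / _raw(ref_f, ref_g), 1.0)


def _pulse0_probs(config: GeneratorConfig, s: float) -> Tuple[float, float]:
    """(P(REV), P(any stop)) at the first pulse for sensitivity s."""
    hab = config.habituation
    p_rev = hab.baseline_rev + s * (hab.f0_rev - hab.baseline_rev)
    p_stop = config.baseline_stop + s * (config.f0_stop - config.baseline_stop)
    for name, p in (("P(REV)", p_rev), ("P(STOP)", p_stop)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"composed {name} = {p} outside [0, 1]")
    if p_rev > p_stop:
        raise ValueError("composed P(REV) exceeds P(STOP)")
    return p_rev, p_stop


def _sample_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Categorical draw per row of a (n, 4) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    return (u[:, None] > cum).sum(axis=1)


def generate_response_records(
    config: GeneratorConfig,
    protocol: StimulusProtocol,
    seed: Optional[int] = None,
    window_s: float = 3.0,
    gaps: Optional[Sequence[float]] = None,
) -> List[ResponseRecord]:
    """Draw one behavior label per larva per pulse.

    Pulse 0 uses the sensitivity-scaled naive fractions; each later pulse
    advances every larva through the transition kernel with the REV->REV
    entry scaled by that gap's recovery factor.  ``gaps`` optionally gives
    per-gap OFF times (length ``n_pulses - 1``) for experiment designs that
    vary only one inter-pulse interval; the protocol's uniform ``t_off``
    applies otherwise.  Deterministic for a fixed seed (``config.seed``
    unless overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_larvae
    if n == 0:
        return []
    s = sensitivity_factor(config, protocol.frequency_hz, protocol.gamma)
    p_rev, p_stop = _pulse0_probs(config, s)
    if gaps is not None:
        gaps = [float(g) for g in gaps]
        if len(gaps) != protocol.n_pulses - 1:
            raise ValueError("gaps must have length n_pulses - 1")
        onsets = protocol.t_start + np.concatenate(
            [[0.0], np.cumsum(protocol.t_on + np.asarray(gaps))]
        )
    else:
        onsets = protocol.pulse_onsets()

    # pulse 0: REV / (PAUSE|TURN) / CONT composition
    u = rng.random(n)
    labels = np.full(n, _I_CONT, dtype=np.int64)
    labels[u < p_rev] = _I_REV
    mid = (u >= p_rev) & (u < p_stop)
    pause = rng.random(n) < config.pause_share
    labels[mid & pause] = _I_PAUSE
    labels[mid & ~pause] = _I_TURN

    ids = [f"larva{i:05d}" for i in range(n)]
    records: List[ResponseRecord] = []

    def _emit(pulse_n: int, lab_idx: np.ndarray) -> None:
        onset = float(onsets[pulse_n])
        for i in range(n):
            records.append(
                ResponseRecord(
                    ids[i], pulse_n, LABEL_ORDER[lab_idx[i]], (onset, onset + window_s)
                )
            )

    _emit(0, labels)
    for pulse_n in range(1, protocol.n_pulses):
        gap = gaps[pulse_n - 1] if gaps is not None else protocol.t_off
        r = recovery_factor(config.habituation, gap, pulse_n)
        rows = np.stack([config.kernel.row_with_recovery(i, r) for i in range(4)])
        labels = _sample_rows(rng, rows[labels])
        _emit(pulse_n, labels)
    return records


@dataclass
class CountTimeSeries:
    """Binned reversing/stopped counts with the underlying expectation.

    ``t`` holds bin centers in seconds since the first pulse onset;
    ``expected_rev``/``expected_stop`` are the deterministic population-rate
    curves the binomial draws were taken around (useful for zero-noise
    tests).
    """

    t: np.ndarray
    dt: float
    n_active: np.ndarray
    n_rev: np.ndarray
    n_stop: np.ndarray
    expected_rev: np.ndarray
    expected_stop: np.ndarray
    baseline_rev: float
    baseline_stop: float

    @property
    def f_rev(self) -> np.ndarray:
        return self.n_rev / self.n_active

    @property
    def f_stop(self) -> np.ndarray:
        return self.n_stop / self.n_active

    @property
    def sem_rev(self) -> np.ndarray:
        # add-half counts keep the SEM nonzero at empty bins
        p = (self.n_rev + 0.5) / (self.n_active + 1.0)
        return np.sqrt(p * (1 - p) / self.n_active)

    @property
    def sem_stop(self) -> np.ndarray:
        p = (self.n_stop + 0.5) / (self.n_active + 1.0)
        return np.sqrt(p * (1 - p) / self.n_active)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "n_active": self.n_active,
                "n_rev": self.n_rev,
                "n_stop": self.n_stop,
                "f_rev": self.f_rev,
                "f_stop": self.f_stop,
                "expected_rev": self.expected_rev,
                "expected_stop": self.expected_stop,
            }
        )


def generate_count_timeseries(
    config: GeneratorConfig,
    protocol: StimulusProtocol,
    duration: float,
    seed: Optional[int] = None,
) -> CountTimeSeries:
    """Binomial per-bin counts around the population habituation curve.

    The reversal rate peaks at each pulse onset at
    ``baseline + s (F0_rev - baseline) r_n`` (r_n the recovery factor for
    the preceding gap) and relaxes exponentially toward baseline with
    tau_des, continuing through OFF periods.  The stop rate follows the same
    kinetics between its own baseline and naive levels.
    """
    if config.dt <= 0:
        raise ValueError("dt must be positive")
    if duration < protocol.span:
        raise ValueError("duration must cover the protocol span")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hab = config.habituation
    s = sensitivity_factor(config, protocol.frequency_hz, protocol.gamma)
    dt = config.dt
    n_bins = int(round(duration / dt))
    t_rel = (np.arange(n_bins) + 0.5) * dt  # centers, since first onset
    t_abs = protocol.t_start + t_rel

    onsets = protocol.pulse_onsets()
    recov = np.array(
        [recovery_factor(hab, protocol.t_off, n) for n in range(protocol.n_pulses)]
    )
    idx = np.searchsorted(onsets, t_abs, side="right") - 1  # last onset <= t
    exp_rev = np.full(n_bins, hab.baseline_rev)
    exp_stop = np.full(n_bins, config.baseline_stop)
    seen = idx >= 0
    dt_since = t_abs[seen] - onsets[idx[seen]]
    decay = np.exp(-dt_since / hab.tau_des) * recov[idx[seen]]
    exp_rev[seen] += s * (hab.f0_rev - hab.baseline_rev) * decay
    exp_stop[seen] += s * (config.f0_stop - config.baseline_stop) * decay

    n = config.n_larvae
    n_rev = rng.binomial(n, exp_rev)
    # keep stops coherent: every reversing larva is stopped
    p_extra = np.clip((exp_stop - exp_rev) / np.clip(1 - exp_rev, 1e-12, None), 0, 1)
    n_stop = n_rev + rng.binomial(n - n_rev, p_extra)
    return CountTimeSeries(
        t=t_rel,
        dt=dt,
        n_active=np.full(n_bins, n),
        n_rev=n_rev,
        n_stop=n_stop,
        expected_rev=exp_rev,
        expected_stop=exp_stop,
        baseline_rev=hab.baseline_rev,
        baseline_stop=config.baseline_stop,
    )


# ---------------------------------------------------------------------------
# Geometric trajectory realization
# ---------------------------------------------------------------------------


def _rotate(theta: float) -> np.ndarray:
    return np.array([math.cos(theta), math.sin(theta)])


def generate_trajectories(
    records: Sequence[ResponseRecord],
    protocol: StimulusProtocol,
    seed: int,
    speed: float = 0.5,
    fps: float = 15.0,
    stop_duration: float = 1.2,
    rev_stop_duration: float = 1.0,
    rev_duration: float = 1.5,
    rev_speed: float = 0.3,
    event_delay: float = 0.3,
    margin: float = 5.0,
) -> List[Trajectory]:
    """Piecewise 2D paths realizing per-pulse behavior scripts.

    Forward runs move at ``speed`` mm/s along the head vector.  PAUSE is a
    stop resumed with a heading change below 30 degrees, TURN with a change
    in (30, 150] degrees, REV a stop followed by ``rev_duration`` seconds of
    motion opposing the head vector.  Events begin ``event_delay`` seconds
    after the pulse onset.  Sampled at ``fps`` frames/s.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(seed)
    onsets = protocol.pulse_onsets()
    by_larva: Dict[str, List[ResponseRecord]] = {}
    for r in records:
        by_larva.setdefault(r.larva_id, []).append(r)

    t_begin = float(min(0.0, protocol.t_start) - margin)
    t_end = float(onsets[-1] + protocol.t_on + margin)
    frame_t = np.arange(t_begin, t_end, 1.0 / fps)

    out: List[Trajectory] = []
    for larva_id in sorted(by_larva):
        recs = sorted(by_larva[larva_id], key=lambda r: r.pulse_n)
        theta = rng.uniform(0, 2 * math.pi)
        x0 = rng.uniform(-50, 50)
        y0 = rng.uniform(-50, 50)

        # breakpoints: (t, vx, vy, hx, hy) applying from t onward
        segments: List[Tuple[float, float, float, float, float]] = []

        def _run(t: float) -> None:
            h = _rotate(theta)
            segments.append((t, speed * h[0], speed * h[1], h[0], h[1]))

        _run(t_begin)
        for rec in recs:
            if rec.label is None or rec.label is BehaviorLabel.CONT:
                continue
            t_ev = float(onsets[rec.pulse_n]) + event_delay
            h = _rotate(theta)
            if rec.label is BehaviorLabel.REV:
                segments.append((t_ev, 0.0, 0.0, h[0], h[1]))
                segments.append(
                    (
                        t_ev + rev_stop_duration,
                        -rev_speed * h[0],
                        -rev_speed * h[1],
                        h[0],
                        h[1],
                    )
                )
                _run(t_ev + rev_stop_duration + rev_duration)
            else:
                segments.append((t_ev, 0.0, 0.0, h[0], h[1]))
                if rec.label is BehaviorLabel.TURN:
                    dtheta = math.radians(rng.uniform(30.0, 150.0))
                else:  # PAUSE: resumed heading change below the 30 deg bound
                    dtheta = math.radians(rng.uniform(0.0, 30.0) * 0.999)
                theta += dtheta * rng.choice([-1.0, 1.0])
                _run(t_ev + stop_duration)

        break_ts = np.array([s[0] for s in segments])
        seg_idx = np.clip(np.searchsorted(break_ts, frame_t, side="right") - 1, 0, None)
        seg = np.array([s[1:] for s in segments])
        vx, vy, hx, hy = (seg[seg_idx, k] for k in range(4))
        dtf = 1.0 / fps
        x = x0 + np.concatenate([[0.0], np.cumsum(vx[:-1] * dtf)])
        y = y0 + np.concatenate([[0.0], np.cumsum(vy[:-1] * dtf)])
        out.append(
            Trajectory(
                larva_id=larva_id,
                t=frame_t.copy(),
                x=x,
                y=y,
                head=np.column_stack([hx, hy]),
            )
        )
    return out
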