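"""Population-level response fractions and comparisons.

The central population quantity is the fraction of active larvae deploying
each behavior in the response window of pulse n:

    F_n,ACTION = N_ACTION / N,    F_CONT + F_PAUSE + F_TURN + F_REV = 1,
    F_STOP = F_PAUSE + F_TURN + F_REV.

N counts larvae with a resolved label for that pulse; missing/unresolved
windows are excluded.  Pairwise condition comparisons use two-sided
Fisher's exact tests on reversal counts, reported unadjusted at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import LABEL_ORDER, BehaviorLabel, ResponseRecord

__all__ = [
    "PopulationFractions",
    "FractionTimeSeries",
    "response_fractions",
    "fraction_timeseries",
    "fisher_compare",
    "condition_grid",
]


@dataclass(frozen=True)
class PopulationFractions:
    """Behavior fractions at one pulse, computed from exact counts."""

    pulse_n: int
    n: int
    counts: Dict[BehaviorLabel, int]

    @property
    def f_cont(self) -> float:
        return self.counts[BehaviorLabel.CONT] / self.n

    @property
    def f_pause(self) -> float:
        return self.counts[BehaviorLabel.PAUSE] / self.n

    @property
    def f_turn(self) -> float:
        return self.counts[BehaviorLabel.TURN] / self.n

    @property
    def f_rev(self) -> float:
        return self.counts[BehaviorLabel.REV] / self.n

    @property
    def f_stop(self) -> float:
        """Any avoidance behavior: pause + turn + reversal."""
        return (
            self.counts[BehaviorLabel.PAUSE]
            + self.counts[BehaviorLabel.TURN]
            + self.counts[BehaviorLabel.REV]
        ) / self.n

    def as_fractions(self) -> Dict[str, Fraction]:
        """Exact rational fractions (counts over N)."""
        return {lab.value: Fraction(self.counts[lab], self.n) for lab in LABEL_ORDER}

    def to_dict(self) -> dict:
        return {
            "pulse_n": self.pulse_n,
            "N": self.n,
            "F_cont": self.f_cont,
            "F_pause": self.f_pause,
            "F_turn": self.f_turn,
            "F_rev": self.f_rev,
            "F_stop": self.f_stop,
        }


def response_fractions(
    records: Sequence[ResponseRecord], pulse_n: int
) -> PopulationFractions:
    """Fractions of active larvae per behavior at pulse ``pulse_n``.

    Raises if no larva has a resolved label at that pulse (N = 0 leaves the
    fractions undefined).
    """
    counts = {lab: 0 for lab in LABEL_ORDER}
    n = 0
    for r in records:
        if r.pulse_n == pulse_n and r.label is not None:
            counts[r.label] += 1
            n += 1
    if n == 0:
        raise ValueError(f"no resolved responses at pulse {pulse_n}; fractions undefined")
    return PopulationFractions(pulse_n=pulse_n, n=n, counts=counts)


@dataclass
class FractionTimeSeries:
    """Binned instantaneous-state fractions.

    t are bin centers (s) on a uniform grid aligned so that t = 0 falls at
    the first pulse onset; f_rev / f_stop are the fractions of tracked
    larvae whose state in that bin is reversing / stopped.
    """

    t: np.ndarray
    f_rev: np.ndarray
    f_stop: np.ndarray
    n: np.ndarray
    dt: float

    @property
    def sem_rev(self) -> np.ndarray:
        """Binomial standard error per bin (add-half counts, never zero)."""
        n = np.maximum(self.n, 1)
        p = (self.f_rev * n + 0.5) / (n + 1.0)
        return np.sqrt(p * (1 - p) / n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "f_rev": self.f_rev, "f_stop": self.f_stop, "n": self.n}
        )


def fraction_timeseries(
    events_by_larva: Mapping[str, Sequence[Tuple[float, float, str]]],
    dt: float,
    t_range: Tuple[float, float],
    t_zero: float = 0.0,
) -> FractionTimeSeries:
    """Instantaneous-state fractions from per-larva state intervals.

    ``events_by_larva`` maps larva id to (t_start, t_end, kind) intervals
    with kind "rev" or "stop" (reversing counts as stopped for F_STOP).
    A larva's state in a bin is the strongest state overlapping the bin.
    Bins are centered on a grid with t = ``t_zero`` at a bin edge.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not events_by_larva:
        raise ValueError("no larvae supplied")
    t0, t1 = t_range
    edges = t_zero + np.arange(np.floor((t0 - t_zero) / dt), np.ceil((t1 - t_zero) / dt) + 1) * dt
    centers = (edges[:-1] + edges[1:]) / 2
    n_bins = len(centers)
    n_larvae = len(events_by_larva)
    rev = np.zeros(n_bins, dtype=int)
    stop = np.zeros(n_bins, dtype=int)
    for intervals in events_by_larva.values():
        rev_mask = np.zeros(n_bins, dtype=bool)
        stop_mask = np.zeros(n_bins, dtype=bool)
        for a, b, kind in intervals:
            lo = np.searchsorted(edges, a, side="right") - 1
            hi = np.searchsorted(edges, b, side="left")
            lo = max(lo, 0)
            hi = min(hi, n_bins)
            if hi <= lo:
                continue
            if kind == "rev":
                rev_mask[lo:hi] = True
            stop_mask[lo:hi] = True
        rev += rev_mask
        stop += stop_mask
    n = np.full(n_bins, n_larvae)
    return FractionTimeSeries(
        t=centers, f_rev=rev / n_larvae, f_stop=stop / n_larvae, n=n, dt=dt
    )


def fisher_compare(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[k1, n1-k1], [k2, n2-k2]]."""
    for k, n in ((k1, n1), (k2, n2)):
        if k < 0 or n < 0:
            raise ValueError("counts must be non-negative")
        if k > n:
            raise ValueError("k must not exceed n")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return float(p)


def condition_grid(
    results: Mapping[Tuple[float, float], Tuple[int, int]],
    baseline: Optional[Tuple[int, int]] = None,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Reversal summary over an (f, Gamma) condition grid.

    Parameters
    ----------
    results : maps (frequency_hz, gamma) to (k_rev, n) reversal counts for
        the first pulse.
    baseline : optional (k, n) no-stimulus counts each condition is
        compared against.
    alpha : significance threshold for flagging (unadjusted, two-sided).

    Returns
    -------
    (conditions, edges) : one DataFrame of per-condition fractions (with
        p vs baseline when supplied), one of pairwise comparisons between
        grid-adjacent conditions -- neighbors along the sorted frequency or
        the sorted Gamma axis.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 conditions")
    rows = []
    for (f, g), (k, n) in sorted(results.items()):
        row = {"f_hz": f, "gamma": g, "k_rev": k, "n": n, "f0_rev": k / n if n else np.nan}
        if baseline is not None:
            p = fisher_compare(k, n, baseline[0], baseline[1])
            row["p_vs_baseline"] = p
            row["above_baseline"] = p < alpha
        rows.append(row)
    conditions = pd.DataFrame(rows)

    freqs = sorted({f for f, _ in results})
    gammas = sorted({g for _, g in results})
    edges = []

    def _maybe_edge(c1, c2):
        if c1 in results and c2 in results:
            k1, n1 = results[c1]
            k2, n2 = results[c2]
            p = fisher_compare(k1, n1, k2, n2)
            edges.append(
                {
                    "f_hz_a": c1[0], "gamma_a": c1[1],
                    "f_hz_b": c2[0], "gamma_b": c2[1],
                    "p": p, "significant": p < alpha,
                }
            )

    for g in gammas:
        for fa, fb in zip(freqs[:-1], freqs[1:]):
            _maybe_edge((fa, g), (fb, g))
    for f in freqs:
        for ga, gb in zip(gammas[:-1], gammas[1:]):
            _maybe_edge((f, ga), (f, gb))
    return conditions, pd.DataFrame(edges)
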