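"""Individual-level behavioral transition matrices across pulses.

For each ordered pair of behaviors (X, Y), the lag-k matrix entry is the
percentage of (larva, pulse) occurrences of X at pulse n that were followed
by Y at pulse n + k, pooled over all starting pulses and larvae.  Rows sum
to 100% over observed from-behaviors; a row with no occurrences is
undefined (NaN).  Habituation being a one-way process shows up here as an
empty REV column off the diagonal (weaker behaviors essentially never
return to reverse crawling) and, at longer lags, as continuation being
absorbing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .behavior import LABEL_ORDER, BehaviorLabel, ResponseRecord

__all__ = ["TransitionMatrix", "transition_matrix", "one_way_violations"]


@dataclass
class TransitionMatrix:
    """4x4 behavioral transition percentages at a fixed pulse lag."""

    lag: int
    counts: np.ndarray  # (4, 4) integer transition counts
    n_transitions: int

    @property
    def labels(self) -> Tuple[BehaviorLabel, ...]:
        return LABEL_ORDER

    @property
    def percentages(self) -> np.ndarray:
        """Row percentages; rows with zero occurrences are NaN."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / row_sums
        pct[row_sums[:, 0] == 0] = np.nan
        return pct

    def entry(self, from_label: BehaviorLabel, to_label: BehaviorLabel) -> float:
        """Percentage for one ordered behavior pair."""
        i = LABEL_ORDER.index(from_label)
        j = LABEL_ORDER.index(to_label)
        return float(self.percentages[i, j])

    def to_frame(self) -> pd.DataFrame:
        names = [lab.value for lab in LABEL_ORDER]
        return pd.DataFrame(self.percentages, index=names, columns=names)

    def to_csv(self, path) -> None:
        """Labelled 4x4 percentages plus an n_transitions metadata row."""
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# lag={self.lag} n_transitions={self.n_transitions}\n")
            df.to_csv(fh)


def transition_matrix(
    records: Sequence[ResponseRecord], lag: int = 1, stratify_by_pulse: bool = False
):
    """Pool (pulse n, pulse n+lag) label pairs into a transition matrix.

    Missing labels break pairs (no imputation).  With
    ``stratify_by_pulse=True`` returns a dict mapping each starting pulse to
    its own matrix instead of pooling.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    by_larva: Dict[str, Dict[int, BehaviorLabel]] = defaultdict(dict)
    for r in records:
        if r.label is not None:
            by_larva[r.larva_id][r.pulse_n] = r.label
    index = {lab: i for i, lab in enumerate(LABEL_ORDER)}

    def _build(pairs) -> TransitionMatrix:
        counts = np.zeros((4, 4), dtype=int)
        for a, b in pairs:
            counts[index[a], index[b]] += 1
        return TransitionMatrix(lag=lag, counts=counts, n_transitions=int(counts.sum()))

    if stratify_by_pulse:
        pairs_by_n: Dict[int, List] = defaultdict(list)
        for labels in by_larva.values():
            for n, a in labels.items():
                b = labels.get(n + lag)
                if b is not None:
                    pairs_by_n[n].append((a, b))
        return {n: _build(p) for n, p in sorted(pairs_by_n.items())}

    pairs = []
    for labels in by_larva.values():
        for n, a in labels.items():
            b = labels.get(n + lag)
            if b is not None:
                pairs.append((a, b))
    if not pairs:
        raise ValueError("no valid transition pairs at this lag")
    return _build(pairs)


def one_way_violations(matrix: TransitionMatrix):
    """Transitions from any weaker behavior back into reverse crawling.

    Returns ``(count, entries)`` where count is the total number of observed
    non-REV -> REV transitions and entries lists the offending
    (from_label, count, percentage) tuples.
    """
    j_rev = LABEL_ORDER.index(BehaviorLabel.REV)
    pct = matrix.percentages
    total = 0
    entries = []
    for i, lab in enumerate(LABEL_ORDER):
        if lab is BehaviorLabel.REV:
            continue
        c = int(matrix.counts[i, j_rev])
        if c > 0:
            total += c
            entries.append((lab, c, float(pct[i, j_rev])))
    return total, entries
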