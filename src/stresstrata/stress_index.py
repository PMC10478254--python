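"""Quartile-weighted stress-response index for classifying control subjects.

Each index-panel gene is split into quartiles across the scored subjects
(the study computes quartiles within controls only). Genes that run high in
the high stress-response stratum score −3 / −1 / +1 / +3 for quartiles
1–4; genes that run high in the low stress-response stratum score the
reverse (+3 / +1 / −1 / −3). The per-gene scores sum to the stress-response
index: a positive index classifies the subject as a high stress responder
(HSR), negative as low (LSR), and exactly zero — which the scoring rule
leaves undefined — is reported as INDETERMINATE.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, ValidationError


class IndexDirection(str, enum.Enum):
    HIGH_IN_HSR = "HIGH_IN_HSR"
    HIGH_IN_LSR = "HIGH_IN_LSR"


@dataclass(frozen=True)
class IndexEntry:
    symbol: str
    direction: IndexDirection


class IndexPanel:
    """Genes entering the stress-response index, with their subgroup direction."""

    def __init__(self, entries: Sequence[IndexEntry]):
        entries = list(entries)
        if not entries:
            raise ValidationError("index panel must have at least one entry")
        seen: set[str] = set()
        for e in entries:
            key = e.symbol.strip().casefold()
            if key in seen:
                raise ValidationError(f"duplicate index-panel gene: {e.symbol!r}")
            seen.add(key)
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def flipped(self) -> "IndexPanel":
        swap = {
            IndexDirection.HIGH_IN_HSR: IndexDirection.HIGH_IN_LSR,
            IndexDirection.HIGH_IN_LSR: IndexDirection.HIGH_IN_HSR,
        }
        return IndexPanel([IndexEntry(e.symbol, swap[e.direction]) for e in self.entries])


def default_index_panel() -> IndexPanel:
    """The ten-gene index: six genes high in HSR, four high in LSR."""
    high_hsr = ["IL6", "IFNG", "SOD2", "NR3C1", "APOA1", "SLC6A4"]
    high_lsr = ["BDNF", "SYP", "DLG4", "SNCA"]
    return IndexPanel(
        [IndexEntry(g, IndexDirection.HIGH_IN_HSR) for g in high_hsr]
        + [IndexEntry(g, IndexDirection.HIGH_IN_LSR) for g in high_lsr]
    )


class StressClass(str, enum.Enum):
    HSR = "HSR"
    LSR = "LSR"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class StressIndex:
    """Per-subject index: integer score, per-gene quartiles, and class."""

    score: int
    quartile_detail: dict[str, int]
    stress_class: StressClass


def assign_quartiles(values: Sequence[float]) -> np.ndarray:
    """Assign quartiles 1–4 with interpolated (median-unbiased) cut points.

    Cut points Q1, Q2, Q3 come from linear interpolation between order
    statistics (the median-unbiased quantile rule); a value v maps to
    quartile 1 if v ≤ Q1, 2 if Q1 < v ≤ Q2, 3 if Q2 < v ≤ Q3, else 4.
    Closed-right intervals make values equal to a cut point deterministic.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to form quartiles")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: quartiles undefined")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="median_unbiased")
    out = np.full(v.shape, 4, dtype=int)
    out[v <= q3] = 3
    out[v <= q2] = 2
    out[v <= q1] = 1
    return out


_WEIGHTS = {
    IndexDirection.HIGH_IN_HSR: {1: -3, 2: -1, 3: 1, 4: 3},
    IndexDirection.HIGH_IN_LSR: {1: 3, 2: 1, 3: -1, 4: -3},
}


def classify_by_index(score: int) -> StressClass:
    """Positive score → HSR, negative → LSR, zero → INDETERMINATE (warned)."""
    if score > 0:
        return StressClass.HSR
    if score < 0:
        return StressClass.LSR
    warnings.warn("stress-response index is exactly 0: class indeterminate")
    return StressClass.INDETERMINATE


def stress_response_index(
    matrix: ExpressionMatrix,
    index_panel: IndexPanel,
    subjects: Sequence[str] | None = None,
) -> dict[str, StressIndex]:
    """Compute the stress-response index for each subject in ``subjects``.

    Quartiles are computed within the given subject subset only. Quartile
    failures (too few subjects, constant gene) propagate with the offending
    gene named.
    """
    subjects = list(subjects) if subjects is not None else matrix.sample_ids
    missing = [s for s in subjects if s not in matrix.values.columns]
    if missing:
        raise ValidationError(f"subjects not in expression matrix: {missing}")
    sub = matrix.values.loc[:, subjects]

    lookup = {g.strip().casefold(): g for g in matrix.gene_ids}
    scores = np.zeros(len(subjects), dtype=int)
    detail: dict[str, np.ndarray] = {}
    for entry in index_panel.entries:
        gene = lookup.get(entry.symbol.strip().casefold())
        if gene is None:
            raise ValidationError(f"index-panel gene missing from matrix: {entry.symbol}")
        try:
            quarts = assign_quartiles(sub.loc[gene].to_numpy())
        except ValueError as exc:
            raise ValueError(f"gene {entry.symbol}: {exc}") from exc
        detail[entry.symbol] = quarts
        w = _WEIGHTS[entry.direction]
        scores += np.array([w[q] for q in quarts])

    out: dict[str, StressIndex] = {}
    for i, s in enumerate(subjects):
        out[s] = StressIndex(
            score=int(scores[i]),
            quartile_detail={g: int(q[i]) for g, q in detail.items()},
            stress_class=classify_by_index(int(scores[i])),
        )
    return out
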