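"""Pattern statistics on 1-D arrays of cells.

Three readouts used to quantify notochord patterning:

* the positivity call — a cell is scored positive when its intensity reaches
  10% of the per-sample maximum;
* the adjacency statistic — the mean number of positive neighbors per
  positive cell (2 when every cell is positive, 0 for perfect alternation);
* the fate proportion — vacuolated cells over vacuolated plus sheath cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabelArray1D",
    "FateCounts",
    "UndefinedStatisticError",
    "positivity_call",
    "adjacency_statistic",
    "fate_proportion",
]

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input (e.g. no positive cells)."""


@dataclass(frozen=True)
class LabelArray1D:
    """Per-cell boolean labels with a boundary convention.

    ``circular`` closes the array into a ring (every cell has two
    neighbors); ``linear`` gives end cells a single neighbor.
    """

    labels: np.ndarray
    boundary: str = "circular"

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=bool)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must be a nonempty 1-D array")
        if self.boundary not in ("linear", "circular"):
            raise ValueError(f"boundary must be 'linear' or 'circular', got {self.boundary!r}")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class FateCounts:
    n_vacuolated: int
    n_sheath: int

    def __post_init__(self):
        if self.n_vacuolated < 0 or self.n_sheath < 0:
            raise ValueError("counts must be nonnegative")


def positivity_call(intensities, fraction: float = 0.10, boundary: str = "circular") -> LabelArray1D:
    """Call cells positive at >= ``fraction`` of the maximum intensity.

    Cells strictly below 10% of the per-sample maximum are negative, so a
    cell exactly at threshold is positive.  All-zero input yields all
    negatives with a logged warning.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("intensities must be a nonempty 1-D array")
    if np.any(x < 0):
        raise ValueError("intensities must be nonnegative")
    m = x.max()
    if m == 0:
        logger.warning("all intensities are zero; calling every cell negative")
        return LabelArray1D(np.zeros_like(x, dtype=bool), boundary)
    return LabelArray1D(x >= fraction * m, boundary)


def adjacency_statistic(labels: LabelArray1D) -> float:
    """Mean number of positive neighbors per positive cell, in [0, 2].

    Equals 2 on a ring where every cell is positive, and 0 when no positive
    cell touches another (perfect alternation).  On linear arrays, end cells
    contribute their single neighbor.
    """
    lab = labels.labels.astype(int)
    n = lab.size
    pos = lab.astype(bool)
    if not pos.any():
        raise UndefinedStatisticError("no positive cells: adjacency statistic undefined")
    if labels.boundary == "circular":
        nbr_count = np.roll(lab, 1) + np.roll(lab, -1)
        if n == 1:
            nbr_count = np.zeros(1, dtype=int)
    else:
        nbr_count = np.zeros(n, dtype=int)
        nbr_count[:-1] += lab[1:]
        nbr_count[1:] += lab[:-1]
    return float(nbr_count[pos].mean())


def fate_proportion(counts: FateCounts) -> float:
    """Vacuolated-cell proportion: n_vac / (n_vac + n_sheath)."""
    total = counts.n_vacuolated + counts.n_sheath
    if total < 1:
        raise UndefinedStatisticError("zero cells: fate proportion undefined")
    return counts.n_vacuolated / total
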