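"""From k cross-validation surfaces to one final suitability map.

Each run's continuous prediction is thresholded at the 10th-percentile
training presence value (so >= 90% of that run's training presences are
classified present), the k binary maps are summed, and cells where at least
``min_agree`` runs (all k by default) agree become the species' presence
area. The final map carries the cellwise mean probability of the k runs
inside that area and 0 outside; it is the pollinator source surface P_sm
for the service model.

Percentile convention: linear interpolation between order statistics, as in
the occurrences module (the original MaxEnt program's convention is
undocumented and may differ slightly). Comparison at the threshold is >=,
so presences equal to the threshold count as present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec
from .occurrences import OccurrenceGrid

__all__ = [
    "BinaryMap",
    "ConsensusMap",
    "training_presence_threshold",
    "consensus",
    "final_suitability",
    "capture_fraction",
]


@dataclass
class BinaryMap:
    values: np.ndarray  # {0,1}
    threshold: float
    spec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary map must contain only 0/1")


@dataclass
class ConsensusMap:
    counts: np.ndarray  # 0..k
    k: int
    spec: GridSpec


def training_presence_threshold(
    prediction: np.ndarray,
    training_presence_cells: np.ndarray,
    spec: GridSpec,
    percentile: float = 10.0,
) -> BinaryMap:
    """Binary map at the given percentile of predictions at training presences."""
    cells = np.asarray(training_presence_cells, dtype=int).reshape(-1, 2)
    if len(cells) == 0:
        raise ValueError("training presence cells must be non-empty")
    prediction = np.asarray(prediction, dtype=float)
    if np.ptp(prediction) == 0:
        warnings.warn("all predictions equal; thresholding yields an all-1 map")
    values = prediction[cells[:, 0], cells[:, 1]]
    thr = float(np.percentile(values, percentile))
    return BinaryMap((prediction >= thr).astype(np.uint8), thr, spec)


def consensus(
    binary_maps: list[BinaryMap], min_agree: int | None = None
) -> tuple[ConsensusMap, np.ndarray]:
    """Sum the run-level binary maps; presence mask where >= min_agree agree."""
    k = len(binary_maps)
    if k == 0:
        raise ValueError("no binary maps given")
    spec = binary_maps[0].spec
    if any(b.spec != spec for b in binary_maps):
        raise ValueError("binary maps do not share a grid")
    if min_agree is None:
        min_agree = k
    if not 1 <= min_agree <= k:
        raise ValueError(f"min_agree must be in [1, {k}], got {min_agree}")
    counts = np.sum([b.values for b in binary_maps], axis=0)
    return ConsensusMap(counts, k, spec), counts >= min_agree


def final_suitability(mean_prediction: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean run probability inside the consensus presence area, 0 outside (P_sm)."""
    mean_prediction = np.asarray(mean_prediction, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty consensus mask; final suitability is all zero")
    return np.where(mask, mean_prediction, 0.0)


def capture_fraction(final: np.ndarray, occurrences: OccurrenceGrid) -> float:
    """Fraction of observed occurrence cells falling in the final presence area."""
    if occurrences.n_occurrences == 0:
        raise ValueError("capture fraction undefined for zero occurrences")
    final = np.asarray(final, dtype=float)
    vals = final[occurrences.cells[:, 0], occurrences.cells[:, 1]]
    return float(np.mean(vals > 0))
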