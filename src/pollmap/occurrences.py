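"""Occurrence gridding, species profiles, and calibration-species selection.

Raw point records ("records") become deduplicated 1 km^2 presence cells
("occurrences"): records with spatial accuracy coarser than the grid cell are
dropped, and within a cell only one record of a species counts. Species
profiles summarize commonality and spatial extent — record/occurrence/year
counts, bounding box, and the longest distance within the third quartile of
pairwise distances (the third quartile rather than the maximum, to keep
outliers from inflating the extent). Calibration species are picked by
hierarchical clustering on these profile features; a modified prevalence
tau in {0.1, ..., 0.5} is assigned by commonality rank.

Percentile convention throughout: linear interpolation between order
statistics (numpy's default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering

from .grids import GridSpec

__all__ = [
    "OccurrenceGrid",
    "SpeciesProfile",
    "grid_records",
    "q3_longest_distance",
    "species_profile",
    "select_calibration_species",
    "assign_prevalence",
]

PREVALENCE_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class OccurrenceGrid:
    """Deduplicated presence cells of one species on a grid."""

    species_id: str
    cells: np.ndarray  # (n, 2) int, unique (row, col)
    spec: GridSpec

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        if len(self.cells) and len(np.unique(self.cells, axis=0)) != len(self.cells):
            raise ValueError("presence cells contain duplicates")
        if len(self.cells) and not self.spec.contains_cells(self.cells).all():
            raise ValueError("presence cells fall outside the grid")

    @property
    def n_occurrences(self) -> int:
        return len(self.cells)


@dataclass
class SpeciesProfile:
    species_id: str
    n_records: int
    n_occurrences: int
    n_years_nonzero: int
    bbox: tuple[float, float, float, float]  # (min_e, min_n, max_e, max_n) km
    q3_longest_distance: float
    prevalence_tau: float | None = field(default=None)

    def feature_vector(self) -> np.ndarray:
        min_e, min_n, max_e, max_n = self.bbox
        return np.array(
            [self.n_occurrences, min_e, max_e, min_n, max_n, self.q3_longest_distance],
            dtype=float,
        )


def grid_records(
    records: pd.DataFrame,
    spec: GridSpec,
    species_id: str | None = None,
    max_accuracy: float = 1000.0,
) -> OccurrenceGrid:
    """Register records to grid cells, dropping coarse records and duplicates.

    Only records with accuracy (metres) <= ``max_accuracy`` are retained;
    each occupied cell appears once regardless of how many records fall in it.
    """
    if species_id is not None:
        records = records[records["species"] == species_id]
    else:
        ids = records["species"].unique()
        if len(ids) != 1:
            raise ValueError(f"records contain {len(ids)} species; pass species_id")
        species_id = str(ids[0])
    if records.empty:
        raise ValueError(f"no records for species {species_id!r}")
    kept = records[records["accuracy"] <= max_accuracy]
    if kept.empty:
        warnings.warn(
            f"{species_id}: no records with accuracy <= {max_accuracy:g} m; empty grid"
        )
        return OccurrenceGrid(species_id, np.empty((0, 2), dtype=int), spec)
    cells = spec.point_to_cell(kept["easting"].to_numpy(), kept["northing"].to_numpy())
    inside = spec.contains_cells(cells)
    if not inside.all():
        warnings.warn(f"{species_id}: {np.sum(~inside)} records fall outside the grid")
        cells = cells[inside]
    cells = np.unique(cells, axis=0)
    return OccurrenceGrid(species_id, cells, spec)


def q3_longest_distance(points: np.ndarray) -> float:
    """Longest pairwise distance within the third quartile of all pairwise distances.

    ``points`` is an (n, 2) array of planar coordinates in km, n >= 2. The
    75th percentile is taken with linear interpolation; the result is the
    largest distance not exceeding it.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise ValueError(f"need >= 2 points for pairwise distances, got {len(points)}")
    d = pdist(points)
    q3 = np.percentile(d, 75)
    return float(d[d <= q3].max())


def species_profile(grid: OccurrenceGrid, records: pd.DataFrame) -> SpeciesProfile:
    """Summarize one species: counts, bounding box, and Q3 distance.

    ``records`` must be the (accuracy-filtered) record table of the same
    species the grid was built from; ``prevalence_tau`` is left unset until
    :func:`assign_prevalence`.
    """
    ids = set(records["species"].unique())
    if ids != {grid.species_id}:
        raise ValueError(f"records are for {sorted(ids)}, grid is {grid.species_id!r}")
    centers = grid.spec.centers_of(grid.cells) if grid.n_occurrences else np.empty((0, 2))
    if len(centers):
        bbox = (
            float(centers[:, 0].min()),
            float(centers[:, 1].min()),
            float(centers[:, 0].max()),
            float(centers[:, 1].max()),
        )
    else:
        bbox = (math.nan,) * 4
    q3 = q3_longest_distance(centers) if len(centers) >= 2 else 0.0
    return SpeciesProfile(
        species_id=grid.species_id,
        n_records=int(len(records)),
        n_occurrences=grid.n_occurrences,
        n_years_nonzero=int(records["year"].nunique()),
        bbox=bbox,
        q3_longest_distance=q3,
    )


def _genus(species_id: str) -> str:
    for sep in (" ", "_"):
        if sep in species_id:
            return species_id.split(sep)[0]
    return species_id


def select_calibration_species(
    profiles: list[SpeciesProfile],
    n_clusters: int = 4,
    fraction: float = 1 / 3,
    seed: int = 0,
) -> list[str]:
    """Pick a representative calibration subset by hierarchical clustering.

    Species are clustered (Ward linkage, Euclidean distance on z-scored
    occurrence count, bounding-box coordinates and Q3 distance); from each
    cluster ``ceil(fraction * size)`` species are selected, cycling across
    genera so no genus dominates.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if len(profiles) < n_clusters:
        raise ValueError(f"{len(profiles)} species but {n_clusters} clusters requested")
    X = np.array([p.feature_vector() for p in profiles])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if n_clusters == 1:
        labels = np.zeros(len(profiles), dtype=int)
    else:
        labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(Z)
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for lab in np.unique(labels):
        members = [profiles[i] for i in np.flatnonzero(labels == lab)]
        quota = math.ceil(fraction * len(members))
        by_genus: dict[str, list[SpeciesProfile]] = {}
        for p in members:
            by_genus.setdefault(_genus(p.species_id), []).append(p)
        for plist in by_genus.values():
            plist.sort(key=lambda p: (-p.n_occurrences, p.species_id))
        genera = sorted(by_genus)
        rng.shuffle(genera)
        picked: list[str] = []
        while len(picked) < quota:
            progressed = False
            for g in genera:
                if by_genus[g] and len(picked) < quota:
                    picked.append(by_genus[g].pop(0).species_id)
                    progressed = True
            if not progressed:
                break
        selected.extend(picked)
    return selected


def assign_prevalence(profiles: list[SpeciesProfile]) -> list[SpeciesProfile]:
    """Assign each species a modified prevalence tau in {0.1, ..., 0.5}.

    Commonality is the geometric mean of min-max-normalized record count,
    occurrence count and years-with-observations; species are quintile-binned
    by commonality rank so the most common get 0.5 and the least common 0.1.
    Ties share a bin (average ranks), so the mapping is permutation-equivariant.
    """
    if not profiles:
        return profiles
    counts = np.array(
        [[p.n_records, p.n_occurrences, p.n_years_nonzero] for p in profiles], dtype=float
    )
    lo = counts.min(axis=0)
    rng_ = counts.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    norm = (counts - lo) / rng_
    score = np.exp(np.log(norm + 1e-12).mean(axis=1))
    from scipy.stats import rankdata

    ranks = rankdata(score, method="average")  # 1..n, ties averaged
    frac = (ranks - 1) / len(profiles)
    bins = np.minimum((frac * 5).astype(int), 4)
    for p, b in zip(profiles, bins):
        p.prevalence_tau = PREVALENCE_LEVELS[b]
    return profiles
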