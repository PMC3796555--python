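"""Distance-weighted pollination service (Lonsdorf-style kernel).

For each crop cell o the relative service from species s is the
distance-weighted proportion of the surrounding cells occupied by the
pollinator:

    P_os = sum_m P_sm exp(-D_om / a_s) / sum_m exp(-D_om / a_s),

where P_sm is the species' final suitability (probability of presence) on
map cell m, D_om the Euclidean centre-to-centre distance, and a_s the
species' average foraging distance (the e-folding scale of the decay). The
sum runs over all map cells within ``kernel_radius_factor x a_s`` of the
crop cell — the exponential never reaches zero, so a finite support radius
is what makes crop fields beyond foraging reach score exactly 0. Cells of
zero suitability still count in the denominator (the kernel is a weighted
proportion, not a weighted mean of occupied cells only).

Total service sums the compatible species' P_os per crop cell. The managed
honey-bee layer is processed separately (forager counts disaggregated from
4 km^2 to 1 km^2, rescaled to [0, 1], with a 5th-percentile absence cut-off)
and is never summed with the wild-species surface: the two indices measure
different things (forager density vs probability of occurrence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import convolve2d

from .grids import GridSpec
from .synthetic import CropMap

__all__ = [
    "ForagingSpec",
    "ServiceMap",
    "HoneyBeeLayer",
    "DEFAULT_FORAGING_DISTANCES",
    "service_single_species",
    "total_service",
    "honeybee_layer",
    "resample_crop",
    "low_service_mask",
]

# Average foraging distances (km) for the field-bean pollinator set: 1 km for
# most species, doubled for the three wide-ranging Bombus.
DEFAULT_FORAGING_DISTANCES: dict[str, float] = {
    "Andrena labialis": 1.0,
    "Andrena wilkella": 1.0,
    "Bombus hortorum": 1.0,
    "Bombus lucorum": 1.0,
    "Bombus muscorum": 1.0,
    "Osmia rufa": 1.0,
    "Bombus lapidarius": 2.0,
    "Bombus pascuorum": 2.0,
    "Bombus terrestris": 2.0,
}


@dataclass
class ForagingSpec:
    species_id: str
    foraging_distance: float  # a_s, km

    def __post_init__(self) -> None:
        if not self.foraging_distance > 0:
            raise ValueError("foraging distance must be > 0")


@dataclass
class ServiceMap:
    """Per-crop-cell relative service; zero outside crop cells."""

    values: np.ndarray
    crop_mask: np.ndarray
    spec: GridSpec
    species_id: str = "total"


@dataclass
class HoneyBeeLayer:
    """Relative honey-bee forager score in [0, 1] with an absence mask."""

    score: np.ndarray
    absence_mask: np.ndarray
    spec: GridSpec
    cutoff: float = 0.0


def _kernel(a_s: float, radius: float, cell_size: float) -> np.ndarray:
    """Exponential decay weights on the cell-offset disc of the given radius."""
    r_cells = int(np.floor(radius / cell_size))
    di = np.arange(-r_cells, r_cells + 1)
    dist = cell_size * np.hypot(di[:, None], di[None, :])
    w = np.exp(-dist / a_s)
    w[dist > radius] = 0.0
    return w


def service_single_species(
    p_sm: np.ndarray,
    crop: CropMap,
    a_s: float,
    kernel_radius_factor: float = 3.0,
    species_id: str = "species",
) -> ServiceMap:
    """Relative service P_os of one species to each crop cell.

    ``crop`` must already be at the suitability grid's grain (see
    :func:`resample_crop`). Crop cells with no positive-suitability cell
    within the kernel radius score exactly 0; non-crop cells are zero.
    """
    p_sm = np.asarray(p_sm, dtype=float)
    if not a_s > 0:
        raise ValueError("a_s must be > 0")
    spec = crop.spec
    if p_sm.shape != spec.shape:
        raise ValueError(
            f"suitability shape {p_sm.shape} != crop grid {spec.shape}; resample first"
        )
    if np.any(p_sm < 0) or np.any(p_sm > 1):
        raise ValueError("P_sm must lie in [0, 1]")
    radius = kernel_radius_factor * a_s
    w = _kernel(a_s, radius, spec.cell_size)
    if not np.any(w > 0):
        raise ValueError("kernel radius smaller than one cell; no cells in M")
    # direct (non-FFT) convolution keeps exact zeros where no source cell
    # contributes; edge cells simply see a smaller M
    numer = convolve2d(p_sm, w, mode="same", boundary="fill", fillvalue=0.0)
    denom = convolve2d(np.ones_like(p_sm), w, mode="same", boundary="fill", fillvalue=0.0)
    crop_mask = crop.raster.astype(bool)
    values = np.zeros_like(p_sm)
    values[crop_mask] = numer[crop_mask] / denom[crop_mask]
    return ServiceMap(values=values, crop_mask=crop_mask, spec=spec, species_id=species_id)


def total_service(
    per_species: Sequence[ServiceMap], compatibility: Mapping[str, int]
) -> ServiceMap:
    """Total service P_o = sum over compatible species of P_os, per crop cell."""
    if not per_species:
        raise ValueError("no per-species service maps given")
    spec = per_species[0].spec
    crop_mask = per_species[0].crop_mask
    total = np.zeros(spec.shape)
    for sm in per_species:
        if sm.spec != spec:
            raise ValueError("service maps do not share a grid")
        if sm.species_id not in compatibility:
            raise KeyError(f"species {sm.species_id!r} missing from compatibility table")
        if compatibility[sm.species_id]:
            total += sm.values
    return ServiceMap(values=total, crop_mask=crop_mask, spec=spec, species_id="total")


def honeybee_layer(
    foragers_coarse: np.ndarray,
    coarse_spec: GridSpec,
    absence_percentile: float = 5.0,
) -> HoneyBeeLayer:
    """Managed honey-bee forager score at fine grain with an absence cut-off.

    Each 4 km^2 forager count is divided by four and spread uniformly over
    its four 1 km^2 children, then min-max rescaled to [0, 1]. Cells whose
    rescaled score falls below the ``absence_percentile`` of the nonzero
    scores are set to exactly 0 (absence), mirroring the thresholding of the
    wild-species maps.
    """
    foragers_coarse = np.asarray(foragers_coarse, dtype=float)
    if np.any(foragers_coarse < 0):
        raise ValueError("forager counts must be >= 0")
    fine_spec = coarse_spec.refine(2)
    fine = np.kron(foragers_coarse / 4.0, np.ones((2, 2)))
    if fine.max() == 0:
        warnings.warn("all-zero forager layer; every cell is absence")
        return HoneyBeeLayer(
            score=np.zeros(fine_spec.shape),
            absence_mask=np.ones(fine_spec.shape, dtype=bool),
            spec=fine_spec,
        )
    span = fine.max() - fine.min()
    # a spatially constant positive field rescales to 1 everywhere
    score = (fine - fine.min()) / span if span > 0 else (fine > 0).astype(float)
    nonzero = score[score > 0]
    cutoff = float(np.percentile(nonzero, absence_percentile))
    absence = score < cutoff
    score = np.where(absence, 0.0, score)
    return HoneyBeeLayer(score=score, absence_mask=absence, spec=fine_spec, cutoff=cutoff)


def resample_crop(crop: CropMap, factor: int = 2) -> CropMap:
    """Block-replicate a coarse crop map to fine grain (4 km^2 -> 1 km^2)."""
    fine_spec = crop.spec.refine(factor)
    fine = np.kron(crop.raster, np.ones((factor, factor), dtype=crop.raster.dtype))
    return CropMap(fine, fine_spec)


def low_service_mask(
    total: ServiceMap, low_quantile: float = 10.0
) -> tuple[np.ndarray, dict]:
    """Flag crop cells with poor service: the lowest quantile of positive
    service plus every zero-service crop cell.

    Returns the mask and a summary (min/max service over crop cells, flagged
    area in km^2).
    """
    crop_mask = total.crop_mask
    if not crop_mask.any():
        raise ValueError("no crop cells")
    vals = total.values[crop_mask]
    positive = vals[vals > 0]
    mask = np.zeros_like(crop_mask)
    if len(positive):
        thr = float(np.percentile(positive, low_quantile))
        mask[crop_mask] = (vals == 0) | ((vals > 0) & (vals < thr))
    else:
        mask[crop_mask] = True
    cell_area = total.spec.cell_size**2
    summary = {
        "min_service": float(vals.min()),
        "max_service": float(vals.max()),
        "flagged_area_km2": float(mask.sum() * cell_area),
        "n_crop_cells": int(crop_mask.sum()),
    }
    return mask, summary
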