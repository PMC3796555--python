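"""Synthetic landscapes, virtual species, and opportunistic sampling.

Everything downstream of this module (occurrence gridding, MaxEnt fitting,
ensembling, the service kernel) is exercised against data generated here,
where the ground truth — the species' true environment response, its occupied
fraction, the spatial structure of recorder effort — is known exactly.

Random fields are produced by smoothing white noise with a Gaussian kernel of
a stated length-scale and standardizing, which gives simple, controllable
spatial autocorrelation. Virtual species combine per-layer responses
multiplicatively and rescale by the field maximum, so the true suitability
stays in [0, 1] without clipping. Occurrence sampling draws cells with
replacement with probability proportional to suitability x effort, emulating
opportunistic recording whose intensity varies in space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, PredictorStack

__all__ = [
    "EffortLayer",
    "VirtualSpecies",
    "CropMap",
    "generate_landscape",
    "generate_virtual_species",
    "sample_occurrences",
    "make_effort",
    "generate_crop_map",
    "generate_apiaries",
    "forager_counts",
]


@dataclass
class EffortLayer:
    """Relative recorder effort per cell (>= 0, not all zero)."""

    raster: np.ndarray

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if np.any(self.raster < 0):
            raise ValueError("effort must be non-negative")
        if not np.any(self.raster > 0):
            raise ValueError("effort is all zero; cannot normalize to a sampling distribution")


@dataclass
class VirtualSpecies:
    """A simulated species with a known environment-suitability relationship."""

    species_id: str
    response_spec: Mapping[str, Mapping]
    true_suitability: np.ndarray
    occupancy_threshold: float
    occupied_fraction: float
    foraging_distance: float = 1.0

    def occupied_mask(self) -> np.ndarray:
        return self.true_suitability > self.occupancy_threshold


@dataclass
class CropMap:
    """Binary crop-presence raster on its own (possibly coarse) grid."""

    raster: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.shape != self.spec.shape:
            raise ValueError(
                f"crop raster shape {self.raster.shape} != grid {self.spec.shape}"
            )
        if not np.isin(self.raster, (0, 1)).all():
            raise ValueError("crop raster must be binary")


def generate_landscape(
    spec: GridSpec, n_layers: int, smoothness: float = 3.0, seed: int = 0
) -> PredictorStack:
    """Gaussian-random-field predictor layers, standardized cellwise.

    Parameters
    ----------
    smoothness
        Gaussian kernel length-scale in km. Zero gives cellwise independent
        values.

    Each layer has mean 0 and variance 1 over the grid to within float
    round-off.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = smoothness / spec.cell_size
    stack = PredictorStack(spec)
    for i in range(n_layers):
        field = rng.standard_normal(spec.shape)
        if sigma > 0:
            field = gaussian_filter(field, sigma=sigma, mode="wrap")
        field = (field - field.mean()) / field.std()
        stack.add(f"env{i + 1}", field)
    return stack


def _response_values(layer: np.ndarray, spec: Mapping) -> np.ndarray:
    kind = spec.get("kind", "flat")
    if kind == "flat":
        return np.ones_like(layer)
    if kind == "gaussian":
        center = float(spec["center"])
        width = float(spec["width"])
        return np.exp(-0.5 * ((layer - center) / width) ** 2)
    if kind == "ramp":
        lo = float(spec["lo"])
        hi = float(spec["hi"])
        return np.clip((layer - lo) / (hi - lo), 0.0, 1.0)
    raise ValueError(f"unknown response kind {kind!r}")


def generate_virtual_species(
    stack: PredictorStack,
    response_spec: Mapping[str, Mapping],
    occupancy_threshold: float = 0.5,
    species_id: str = "virtual",
    foraging_distance: float = 1.0,
) -> VirtualSpecies:
    """Build a virtual species from per-layer responses.

    ``response_spec`` maps layer names to response descriptions: Gaussian
    (``{"kind": "gaussian", "center": c, "width": w}``), monotone ramp
    (``{"kind": "ramp", "lo": a, "hi": b}``) or flat. Responses multiply and
    are rescaled by the field maximum so suitability is in [0, 1].
    """
    unknown = [name for name in response_spec if name not in stack]
    if unknown:
        raise KeyError(f"response references unknown layers {unknown}; stack has {stack.names}")
    suit = np.ones(stack.spec.shape)
    for name, resp in response_spec.items():
        suit = suit * _response_values(stack[name], resp)
    peak = suit.max()
    if peak > 0:
        suit = suit / peak
    occupied_fraction = float(np.mean(suit > occupancy_threshold))
    return VirtualSpecies(
        species_id=species_id,
        response_spec=dict(response_spec),
        true_suitability=suit,
        occupancy_threshold=occupancy_threshold,
        occupied_fraction=occupied_fraction,
        foraging_distance=foraging_distance,
    )


def make_effort(
    spec: GridSpec, kind: str = "uniform", ratio: float = 100.0
) -> EffortLayer:
    """Convenience effort surfaces: uniform, one heavily recorded quadrant, or
    an east-west gradient."""
    if kind == "uniform":
        raster = np.ones(spec.shape)
    elif kind == "quadrant":
        raster = np.ones(spec.shape)
        raster[: spec.n_rows // 2, : spec.n_cols // 2] = ratio
    elif kind == "gradient":
        raster = np.linspace(1.0, ratio, spec.n_cols)[None, :] * np.ones((spec.n_rows, 1))
    else:
        raise ValueError(f"unknown effort kind {kind!r}")
    return EffortLayer(raster)


def effort_from_layer(layer: np.ndarray, strength: float = 1.0) -> EffortLayer:
    """Recorder effort correlated with an environmental layer.

    Effort ∝ exp(strength x layer): recorders concentrate where the layer is
    high (think accessibility or urban proximity). This is the biased-effort
    regime the target-group background correction is meant to absorb.
    """
    return EffortLayer(np.exp(strength * np.asarray(layer, dtype=float)))


def sample_occurrences(
    sp: VirtualSpecies,
    n: int,
    effort: EffortLayer,
    seed: int = 0,
    spec: GridSpec | None = None,
    years: tuple[int, int] = (2000, 2010),
    max_accuracy: float = 1000.0,
) -> pd.DataFrame:
    """Draw ``n`` point records with cell probability ∝ suitability x effort.

    Sampling is with replacement at the cell level, so duplicate records in a
    cell are expected (and are what the deduplication stage removes). Points
    are jittered uniformly within their cell; accuracy is drawn in
    (10, ``max_accuracy``] metres.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if spec is None:
        spec = GridSpec(*sp.true_suitability.shape)
    weights = sp.true_suitability * effort.raster
    total = weights.sum()
    if total <= 0:
        raise ValueError("species unobservable under this effort (all-zero product layer)")
    rng = np.random.default_rng(seed)
    p = (weights / total).ravel()
    flat = rng.choice(weights.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(flat, weights.shape)
    jitter = rng.uniform(0.0, spec.cell_size, size=(n, 2))
    east = spec.origin[0] + cols * spec.cell_size + jitter[:, 0]
    north = spec.origin[1] + rows * spec.cell_size + jitter[:, 1]
    return pd.DataFrame(
        {
            "species": sp.species_id,
            "easting": east,
            "northing": north,
            "year": rng.integers(years[0], years[1] + 1, size=n),
            "accuracy": rng.uniform(10.0, max_accuracy, size=n),
        }
    )


def generate_crop_map(
    spec: GridSpec, n_patches: int, patch_radius: float = 4.0, seed: int = 0
) -> CropMap:
    """Random circular crop patches on the coarse (2x2-block, 4 km^2) grid."""
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    if patch_radius <= 0:
        raise ValueError(f"patch_radius must be > 0, got {patch_radius}")
    coarse = spec.coarsen(2)
    raster = np.zeros(coarse.shape, dtype=np.uint8)
    if n_patches:
        rng = np.random.default_rng(seed)
        xs, ys = coarse.cell_centers()
        width = coarse.n_cols * coarse.cell_size
        height = coarse.n_rows * coarse.cell_size
        cx = coarse.origin[0] + rng.uniform(0, width, n_patches)
        cy = coarse.origin[1] + rng.uniform(0, height, n_patches)
        for x, y in zip(cx, cy):
            raster[np.hypot(xs - x, ys - y) <= patch_radius] = 1
    return CropMap(raster, coarse)


def generate_apiaries(
    spec: GridSpec, n: int, max_colonies: int = 40, seed: int = 0
) -> pd.DataFrame:
    """Apiary point register: location (km) and colony count."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if max_colonies < 1:
        raise ValueError("max_colonies must be >= 1")
    rng = np.random.default_rng(seed)
    width = spec.n_cols * spec.cell_size
    height = spec.n_rows * spec.cell_size
    return pd.DataFrame(
        {
            "easting": spec.origin[0] + rng.uniform(0, width, n),
            "northing": spec.origin[1] + rng.uniform(0, height, n),
            "colonies": rng.integers(1, max_colonies + 1, size=n),
        }
    )


def forager_counts(
    coarse: GridSpec, apiaries: pd.DataFrame, foraging_distance: float = 2.0
) -> np.ndarray:
    """Exponential-kernel redistribution of colonies to a coarse forager raster.

    Testing aid only: stands in for an externally modelled forager layer.
    Each apiary spreads ``colonies`` over cells with weight exp(-d / a),
    normalized per apiary, so total foragers equal total colonies.
    """
    xs, ys = coarse.cell_centers()
    counts = np.zeros(coarse.shape)
    for _, ap in apiaries.iterrows():
        w = np.exp(-np.hypot(xs - ap["easting"], ys - ap["northing"]) / foraging_distance)
        counts += ap["colonies"] * w / w.sum()
    return counts
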