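"""Bioclimatic predictor derivation and collinearity reduction.

Six bioclimatic layers are derived from 12 monthly rasters each of minimum
temperature, maximum temperature and precipitation:

* ``TAR``  — temperature annual range: warmest-month tmax minus
  coldest-month tmin.
* ``Isoth`` — isothermality %: 100 x MDR / TAR, where MDR is the mean of the
  monthly diurnal ranges (tmax - tmin). 100 means the day-night oscillation
  equals the summer-winter oscillation; 50 means it is half of it.
* ``MTDQ`` / ``MTCQ`` — mean temperature of the driest / coldest quarter,
  where a quarter is any 3 consecutive months (circular over the year
  boundary) and monthly mean temperature is (tmin + tmax) / 2.
* ``RainCQ`` — precipitation total over the coldest quarter (mm).
* ``RainSeasCV`` — precipitation seasonality: 100 x sd / mean of the monthly
  precipitation (sample sd).

Aspect (degrees from north) enters as the pair (sin, cos) of its radian
angle so the circular quantity becomes two continuous predictors.

Collinearity among continuous layers is reduced with a backward Jolliffe
procedure: while the smallest eigenvalue of the correlation matrix is below
``eigen_threshold`` (0.70), drop the variable loading most heavily on that
last component; then screen remaining pairs with |Pearson r| above ``r_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, PredictorStack

__all__ = [
    "MonthlyClimate",
    "derive_bioclim",
    "aspect_transform",
    "resample_layer",
    "select_predictors",
]


@dataclass
class MonthlyClimate:
    """12 monthly rasters each of tmin (degC), tmax (degC), precipitation (mm)."""

    tmin: np.ndarray  # (12, n_rows, n_cols)
    tmax: np.ndarray
    prec: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, *self.spec.shape):
                raise ValueError(
                    f"{name} must have shape (12, {self.spec.n_rows}, {self.spec.n_cols})"
                )
            setattr(self, name, arr)
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in some cell-month")
        if np.any(self.prec < 0):
            raise ValueError("negative precipitation")


def _quarter_windows(monthly: np.ndarray) -> np.ndarray:
    """Sum of each circular 3-month window; shape (12, rows, cols)."""
    return np.stack(
        [monthly[[m, (m + 1) % 12, (m + 2) % 12]].sum(axis=0) for m in range(12)]
    )


def derive_bioclim(clim: MonthlyClimate) -> PredictorStack:
    """Derive {Isoth, TAR, MTDQ, MTCQ, RainSeasCV, RainCQ} from monthly climate."""
    tmean = (clim.tmin + clim.tmax) / 2.0
    tar = clim.tmax.max(axis=0) - clim.tmin.min(axis=0)
    mdr = (clim.tmax - clim.tmin).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        isoth = 100.0 * mdr / tar
    if np.any(tar == 0):
        warnings.warn("TAR = 0 in some cells; isothermality set to nodata there")
        isoth = np.where(tar == 0, np.nan, isoth)

    prec_q = _quarter_windows(clim.prec)  # quarterly precipitation totals
    tmean_q = _quarter_windows(tmean) / 3.0  # quarterly mean temperature
    driest = prec_q.argmin(axis=0)
    coldest = tmean_q.argmin(axis=0)
    rows, cols = np.indices(clim.spec.shape)
    mtdq = tmean_q[driest, rows, cols]
    mtcq = tmean_q[coldest, rows, cols]
    raincq = prec_q[coldest, rows, cols]

    pm = clim.prec.mean(axis=0)
    psd = clim.prec.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raincv = np.where(pm > 0, 100.0 * psd / pm, 0.0)

    return PredictorStack(
        clim.spec,
        {
            "Isoth": isoth,
            "TAR": tar,
            "MTDQ": mtdq,
            "MTCQ": mtcq,
            "RainSeasCV": raincv,
            "RainCQ": raincq,
        },
    )


def aspect_transform(aspect_deg: np.ndarray) -> dict[str, np.ndarray]:
    """Aspect in degrees from north -> {AspNS: sin, AspEW: cos} of the radian angle."""
    aspect_deg = np.asarray(aspect_deg, dtype=float)
    if np.any((aspect_deg < 0) | (aspect_deg >= 360)):
        warnings.warn("aspect values outside [0, 360) wrapped modulo 360")
        aspect_deg = np.mod(aspect_deg, 360.0)
    rad = np.radians(aspect_deg)
    return {"AspNS": np.sin(rad), "AspEW": np.cos(rad)}


def resample_layer(
    values: np.ndarray, source: GridSpec, target: GridSpec, method: str = "block-mean"
) -> np.ndarray:
    """Resample between grids with an integer grain ratio.

    ``block-replicate`` splits each coarse cell's value unchanged into its
    children; ``block-mean`` averages children into a parent; ``nearest``
    picks the child whose centre is nearest the parent centre (coarsening) or
    replicates (refining).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != source.shape:
        raise ValueError(f"values shape {values.shape} != source grid {source.shape}")
    ratio = source.cell_size / target.cell_size
    if ratio >= 1:  # refining
        f = ratio
        if abs(f - round(f)) > 1e-9:
            raise ValueError(f"non-integer grain ratio {ratio}")
        f = int(round(f))
        if target.shape != (source.n_rows * f, source.n_cols * f):
            raise ValueError("target grid does not tile the source grid")
        if method == "block-mean" and f != 1:
            raise ValueError("block-mean cannot refine; use block-replicate or nearest")
        return np.kron(values, np.ones((f, f)))
    f = 1 / ratio
    if abs(f - round(f)) > 1e-9:
        raise ValueError(f"non-integer grain ratio {ratio}")
    f = int(round(f))
    if source.shape != (target.n_rows * f, target.n_cols * f):
        raise ValueError("source grid does not tile the target grid")
    blocks = values.reshape(target.n_rows, f, target.n_cols, f)
    if method == "block-mean":
        return blocks.mean(axis=(1, 3))
    if method == "nearest":
        return blocks[:, f // 2, :, f // 2]
    if method == "block-replicate":
        raise ValueError("block-replicate cannot coarsen; use block-mean or nearest")
    raise ValueError(f"unknown method {method!r}")


def select_predictors(
    stack: PredictorStack, eigen_threshold: float = 0.70, r_max: float = 0.7
) -> tuple[PredictorStack, list[dict]]:
    """Reduce collinearity: backward Jolliffe PCA discard, then Pearson screen.

    Returns the reduced stack and a report listing each discarded layer with
    the reason ("jolliffe" with the offending eigenvalue, or "correlation"
    with the offending |r|).
    """
    names = [n for n in stack.names if stack.kinds.get(n) == "continuous"]
    if len(names) < 2:
        raise ValueError("need >= 2 continuous layers")
    report: list[dict] = []

    def corr(keep: list[str]) -> np.ndarray:
        X = np.column_stack([stack[n].ravel() for n in keep])
        X = X[~np.isnan(X).any(axis=1)]
        return np.corrcoef(X, rowvar=False)

    keep = list(names)
    while len(keep) > 1:
        R = corr(keep)
        eigval, eigvec = np.linalg.eigh(R)  # ascending
        if eigval[0] >= eigen_threshold:
            break
        loadings = np.abs(eigvec[:, 0])
        drop = keep[int(np.argmax(loadings))]
        report.append(
            {
                "layer": drop,
                "reason": "jolliffe",
                "eigenvalue": float(eigval[0]),
                "loading": float(loadings.max()),
            }
        )
        keep.remove(drop)

    while len(keep) > 1:
        R = corr(keep)
        np.fill_diagonal(R, 0.0)
        absR = np.abs(R)
        i, j = np.unravel_index(np.argmax(absR), absR.shape)
        if absR[i, j] <= r_max:
            break
        # drop the member with the larger mean absolute correlation to the rest
        drop_idx = i if absR[i].mean() >= absR[j].mean() else j
        drop = keep[drop_idx]
        report.append(
            {"layer": drop, "reason": "correlation", "abs_r": float(absR[i, j])}
        )
        keep.remove(drop)

    if not keep:
        raise ValueError("all variables discarded; thresholds too strict")
    categorical = [n for n in stack.names if stack.kinds.get(n) == "categorical"]
    return stack.subset(keep + categorical), report
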