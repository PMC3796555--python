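"""Presence/background maximum-entropy species distribution model.

The model estimates the most spread-out (maximum entropy) probability
distribution q over a background sample of landscape cells, subject to the
fitted feature expectations matching those observed at the presence cells:

    q(x) ∝ exp(Σ_j λ_j f_j(x)),

fitted by maximizing the L1-penalized presence log-likelihood

    mean_presences Σ_j λ_j f_j(x)  −  log Z  −  Σ_j β_j |λ_j|,

where Z normalizes q over the background. The L1 penalty is handled exactly
by splitting λ = u − v with u, v >= 0 and minimizing with L-BFGS-B.

Feature classes follow standard MaxEnt usage — linear, quadratic, product,
threshold, hinge (forward and reverse piecewise-linear splines), and
categorical indicators — all min-max scaled to [0, 1] against the background.

The logistic (probability-of-presence) output uses the entropy-offset form

    p(x) = sigmoid(logit(tau) + eta(x) + H),

with eta = log q and H the entropy of the fitted q, so that a "typical" site
(one with raw probability e^{-H}) scores exactly the prevalence tau — the
assumed probability of presence at ordinary occurrence sites (0.5 by default
when no absence data exist, lowered for rarer species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import rankdata, spearmanr

from .grids import GridSpec, PredictorStack

__all__ = [
    "FeatureExpansion",
    "MaxEntModel",
    "BackgroundSet",
    "CVResult",
    "build_features",
    "sample_background",
    "fit_maxent",
    "predict_logistic",
    "auc_presence_background",
    "cross_validate",
    "permutation_importance",
    "null_model_test",
    "tgb_bias_test",
    "single_predictor_gain_ranks",
    "rank_correlation_bootstrap",
]

FEATURE_CLASSES = frozenset(
    {"linear", "quadratic", "product", "threshold", "hinge", "categorical"}
)


@dataclass
class FeatureExpansion:
    """Mapping from raw predictor values to bounded feature columns.

    Built against a background sample: ranges, quantile knots and category
    sets all come from the background, and every column is scaled (and, for
    out-of-range values, clipped) to [0, 1].
    """

    layer_names: list[str]
    columns: list[dict]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Raw value matrix (n, n_layers) -> feature matrix (n, n_columns)."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[1] != len(self.layer_names):
            raise ValueError(
                f"raw matrix has {raw.shape[1]} layers, expansion expects "
                f"{len(self.layer_names)}"
            )
        out = np.empty((raw.shape[0], len(self.columns)))
        for j, c in enumerate(self.columns):
            kind = c["kind"]
            if kind == "product":
                x = raw[:, c["layer"][0]] * raw[:, c["layer"][1]]
            else:
                x = raw[:, c["layer"]]
            if kind in ("linear", "product"):
                lo, hi = c["lo"], c["hi"]
                col = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
            elif kind == "quadratic":
                lo, hi = c["lo"], c["hi"]
                col = (x * x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
            elif kind == "threshold":
                col = (x > c["knot"]).astype(float)
            elif kind == "hinge":
                k = c["knot"]
                if c["forward"]:
                    hi = c["hi"]
                    col = (x - k) / (hi - k) if hi > k else np.zeros_like(x)
                else:
                    lo = c["lo"]
                    col = (k - x) / (k - lo) if k > lo else np.zeros_like(x)
            elif kind == "categorical":
                col = (x == c["value"]).astype(float)
            else:  # pragma: no cover - guarded at build time
                raise ValueError(f"unknown feature kind {kind!r}")
            out[:, j] = np.clip(col, 0.0, 1.0)
        return out


def build_features(
    stack: PredictorStack,
    background_cells: np.ndarray,
    classes: Sequence[str] = ("hinge",),
    n_presence: int = 0,
    min_samples: int = 12,
    n_hinge_knots: int = 50,
    n_thresholds: int = 10,
    species_id: str | None = None,
) -> FeatureExpansion:
    """Expand the requested feature classes against a background sample.

    Hinge knots sit at ``n_hinge_knots`` equally spaced interior quantiles of
    the background values of each layer, giving 2 x n_hinge_knots columns
    (forward + reverse) per continuous layer. Species with fewer than
    ``min_samples`` presences are rejected.
    """
    if n_presence < min_samples:
        raise ValueError(
            f"species {species_id or '<unnamed>'} has {n_presence} presences, "
            f"below the minimum sample size of {min_samples}"
        )
    classes = set(classes)
    unknown = classes - FEATURE_CLASSES
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    raw = stack.matrix(np.asarray(background_cells))
    if not np.isfinite(raw).all():
        raise ValueError("non-finite predictor values in background sample")
    names = stack.names
    continuous = [i for i, n in enumerate(names) if stack.kinds.get(n) == "continuous"]
    categorical = [i for i, n in enumerate(names) if stack.kinds.get(n) == "categorical"]
    columns: list[dict] = []
    for i in continuous:
        x = raw[:, i]
        lo, hi = float(x.min()), float(x.max())
        if "linear" in classes:
            columns.append({"kind": "linear", "layer": i, "lo": lo, "hi": hi})
        if "quadratic" in classes:
            sq = x * x
            columns.append(
                {"kind": "quadratic", "layer": i, "lo": float(sq.min()), "hi": float(sq.max())}
            )
        if "threshold" in classes:
            qs = np.linspace(0, 1, n_thresholds + 2)[1:-1]
            for k in np.quantile(x, qs):
                columns.append({"kind": "threshold", "layer": i, "knot": float(k)})
        if "hinge" in classes:
            qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
            for k in np.quantile(x, qs):
                columns.append(
                    {"kind": "hinge", "layer": i, "knot": float(k), "forward": True, "hi": hi}
                )
                columns.append(
                    {"kind": "hinge", "layer": i, "knot": float(k), "forward": False, "lo": lo}
                )
    if "product" in classes:
        for a_pos, a in enumerate(continuous):
            for b in continuous[a_pos + 1 :]:
                prod = raw[:, a] * raw[:, b]
                columns.append(
                    {
                        "kind": "product",
                        "layer": (a, b),
                        "lo": float(prod.min()),
                        "hi": float(prod.max()),
                    }
                )
    if "categorical" in classes:
        for i in categorical:
            for v in np.unique(raw[:, i]):
                columns.append({"kind": "categorical", "layer": i, "value": float(v)})
    return FeatureExpansion(layer_names=list(names), columns=columns)


@dataclass
class BackgroundSet:
    """A sample of background cells and where it came from."""

    cells: np.ndarray  # (n, 2) int
    origin: str = "uniform"  # "uniform" | "target-group"
    n_requested: int = 0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.cells)


def sample_background(
    pool_cells: np.ndarray, n: int = 5000, seed: int = 0, origin: str = "uniform"
) -> BackgroundSet:
    """Draw ``n`` background cells without replacement from a pool.

    If the pool holds fewer than ``n`` cells the whole pool is returned with
    a warning.
    """
    pool_cells = np.asarray(pool_cells, dtype=int).reshape(-1, 2)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(pool_cells) == 0:
        raise ValueError("empty background pool")
    rng = np.random.default_rng(seed)
    if len(pool_cells) <= n:
        if len(pool_cells) < n:
            warnings.warn(
                f"background pool has {len(pool_cells)} cells < requested {n}; "
                "returning the whole pool"
            )
        cells = pool_cells.copy()
    else:
        idx = rng.choice(len(pool_cells), size=n, replace=False)
        cells = pool_cells[idx]
    return BackgroundSet(cells=cells, origin=origin, n_requested=n)


@dataclass
class MaxEntModel:
    """Fitted maxent model: feature weights and the quantities derived from q."""

    expansion: FeatureExpansion | None
    lam: np.ndarray
    reg_beta: np.ndarray
    normalizer: float  # log partition value over the background
    entropy_H: float
    tau: float
    converged: bool = True
    n_iter: int = 0

    def eta(self, features: np.ndarray) -> np.ndarray:
        """log raw probability: lambda . f(x) - log Z."""
        return np.atleast_2d(features) @ self.lam - self.normalizer

    def logistic_from_eta(self, eta: np.ndarray | float) -> np.ndarray | float:
        """Entropy-offset logistic transform; a typical site (eta = -H) scores tau."""
        return expit(logit(self.tau) + np.asarray(eta) + self.entropy_H)

    def predict_features(self, features: np.ndarray) -> np.ndarray:
        return self.logistic_from_eta(self.eta(features))


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    reg_beta: float | np.ndarray = 0.0,
    tau: float = 0.5,
    expansion: FeatureExpansion | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MaxEntModel:
    """Fit the Gibbs distribution by penalized maximum likelihood.

    Minimizes -[mean_p λ.f - log Z] + Σ β_j|λ_j| over λ, in the exact
    split-variable formulation λ = u - v (u, v >= 0) with L-BFGS-B.
    Convergence: successive penalized log-likelihood improvement below
    ``tol`` or ``max_iter`` iterations; a non-converged fit is returned
    flagged, never silently.
    """
    Fp = np.atleast_2d(np.asarray(presence_features, dtype=float))
    Fb = np.atleast_2d(np.asarray(background_features, dtype=float))
    if Fp.shape[1] != Fb.shape[1]:
        raise ValueError("presence and background feature matrices disagree on columns")
    if Fp.shape[1] < 1:
        raise ValueError("need at least one feature column")
    if not (np.isfinite(Fp).all() and np.isfinite(Fb).all()):
        raise ValueError("non-finite feature values")
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    J = Fp.shape[1]
    beta = np.broadcast_to(np.asarray(reg_beta, dtype=float), (J,)).copy()
    if np.any(beta < 0):
        raise ValueError("reg_beta must be >= 0")
    mean_p = Fp.mean(axis=0)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = theta[:J] - theta[J:]
        s = Fb @ lam
        log_z = logsumexp(s)
        q = np.exp(s - log_z)
        nll = -(mean_p @ lam) + log_z + beta @ (theta[:J] + theta[J:])
        grad_lam = -mean_p + Fb.T @ q
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return nll, grad

    res = minimize(
        objective,
        np.zeros(2 * J),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    lam = res.x[:J] - res.x[J:]
    s = Fb @ lam
    log_z = float(logsumexp(s))
    q = np.exp(s - log_z)
    assert abs(q.sum() - 1.0) < 1e-8, "raw distribution must sum to 1 over background"
    with np.errstate(divide="ignore", invalid="ignore"):
        h_terms = np.where(q > 0, q * np.log(q), 0.0)
    model = MaxEntModel(
        expansion=expansion,
        lam=lam,
        reg_beta=beta,
        normalizer=log_z,
        entropy_H=float(-h_terms.sum()),
        tau=tau,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
    if not res.success:
        warnings.warn(f"maxent fit did not converge: {res.message}")
    return model


def predict_logistic(
    model: MaxEntModel, stack: PredictorStack, cells: np.ndarray | None = None
) -> np.ndarray:
    """Probability-of-presence at ``cells`` (default: the whole grid).

    Returns a raster when ``cells`` is None, else a vector aligned to cells.
    """
    if model.expansion is None:
        raise ValueError("model carries no feature expansion; predict from features instead")
    as_raster = cells is None
    if cells is None:
        cells = stack.spec.all_cells()
    raw = stack.matrix(np.asarray(cells), names=model.expansion.layer_names)
    p = model.predict_features(model.expansion.transform(raw))
    return p.reshape(stack.spec.shape) if as_raster else p


def auc_presence_background(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Rank-based (Mann-Whitney) AUC of presences vs background; ties count 0.5."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k mutually exclusive folds with sizes differing <= 1."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def default_beta(
    background_features: np.ndarray, n_presence: int, beta0: float = 1.0
) -> np.ndarray:
    """Per-column L1 weight: global multiplier x background sd / sqrt(n_presence)."""
    sd = np.asarray(background_features).std(axis=0)
    return beta0 * np.maximum(sd, 1e-6) / np.sqrt(max(n_presence, 1))


@dataclass
class CVResult:
    """k-fold cross-validation summary for one species model."""

    train_auc: np.ndarray
    test_auc: np.ndarray
    permutation_importance: dict[str, float]
    permutation_importance_sd: float
    fold_indices: list[np.ndarray] = field(default_factory=list)
    surfaces: list[np.ndarray] = field(default_factory=list)
    fold_train_cells: list[np.ndarray] = field(default_factory=list)
    models: list[MaxEntModel] = field(default_factory=list)

    @property
    def mean_test_auc(self) -> float:
        return float(self.test_auc.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.test_auc.std(ddof=1)) if len(self.test_auc) > 1 else 0.0

    @property
    def mean_train_auc(self) -> float:
        return float(self.train_auc.mean())


def cross_validate(
    presence_cells: np.ndarray,
    stack: PredictorStack,
    background: BackgroundSet,
    k: int = 10,
    classes: Sequence[str] = ("hinge",),
    tau: float = 0.5,
    seed: int = 0,
    beta0: float = 1.0,
    n_hinge_knots: int = 50,
    min_samples: int = 12,
    background_pool: np.ndarray | None = None,
    with_importance: bool = True,
    predict_all: bool = False,
    species_id: str | None = None,
) -> CVResult:
    """k-fold cross-validated maxent models for one species.

    Presences are split into k mutually exclusive folds; each fold is held
    out once for testing. Training AUC scores training presences against the
    model's own background; testing AUC scores the held-out presences against
    a freshly drawn background of the same size (from ``background_pool``
    when given, falling back to the training background otherwise).

    With ``predict_all`` the per-fold logistic surfaces over the whole grid
    and the per-fold training presence cells are retained for ensembling.
    """
    cells = np.asarray(presence_cells, dtype=int).reshape(-1, 2)
    n = len(cells)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"{n} presences but k={k} folds requested")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng)
    expansion = build_features(
        stack,
        background.cells,
        classes=classes,
        n_presence=n,
        min_samples=min_samples,
        n_hinge_knots=n_hinge_knots,
        species_id=species_id,
    )
    raw_pres = stack.matrix(cells)
    raw_bg = stack.matrix(background.cells)
    Fp_all = expansion.transform(raw_pres)
    Fb = expansion.transform(raw_bg)

    train_aucs, test_aucs = [], []
    imp_sums: dict[str, float] = {}
    result = CVResult(
        train_auc=np.empty(0),
        test_auc=np.empty(0),
        permutation_importance={},
        permutation_importance_sd=0.0,
        fold_indices=folds,
    )
    for fold in folds:
        train_idx = np.setdiff1d(np.arange(n), fold)
        beta = default_beta(Fb, len(train_idx), beta0)
        model = fit_maxent(
            Fp_all[train_idx], Fb, reg_beta=beta, tau=tau, expansion=expansion
        )
        eta_bg = model.eta(Fb)
        train_aucs.append(
            auc_presence_background(model.eta(Fp_all[train_idx]), eta_bg)
        )
        if background_pool is not None:
            test_bg = sample_background(
                background_pool,
                n=len(background.cells),
                seed=int(rng.integers(2**31)),
                origin=background.origin,
            )
            eta_test_bg = model.eta(expansion.transform(stack.matrix(test_bg.cells)))
        else:
            eta_test_bg = eta_bg
        test_aucs.append(
            auc_presence_background(model.eta(Fp_all[fold]), eta_test_bg)
        )
        if with_importance:
            imp, _ = permutation_importance(
                model, raw_pres[train_idx], raw_bg, seed=int(rng.integers(2**31))
            )
            for name, v in imp.items():
                imp_sums[name] = imp_sums.get(name, 0.0) + v
        if predict_all:
            result.surfaces.append(predict_logistic(model, stack))
            result.fold_train_cells.append(cells[train_idx])
            result.models.append(model)
    result.train_auc = np.array(train_aucs)
    result.test_auc = np.array(test_aucs)
    if with_importance:
        mean_imp = {name: v / k for name, v in imp_sums.items()}
        vals = np.array(list(mean_imp.values()))
        result.permutation_importance = mean_imp
        result.permutation_importance_sd = (
            float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        )
    return result


def permutation_importance(
    model: MaxEntModel,
    presence_raw: np.ndarray,
    background_raw: np.ndarray,
    seed: int = 0,
    n_permutations: int = 1,
) -> tuple[dict[str, float], float]:
    """Percent importance of each source predictor by permutation.

    Each predictor's values are permuted jointly across the pooled
    presence + background rows, the model is re-evaluated without refitting,
    and the drop in training AUC is recorded, floored at zero, and
    normalized so the importances sum to 100%. Also returns the SD of the
    importances across predictors (the discrimination-spread statistic).
    """
    if model.expansion is None:
        raise ValueError("model carries no feature expansion")
    exp = model.expansion
    rng = np.random.default_rng(seed)
    Pr = np.atleast_2d(np.asarray(presence_raw, dtype=float))
    Br = np.atleast_2d(np.asarray(background_raw, dtype=float))
    n_p = len(Pr)
    base = auc_presence_background(
        model.eta(exp.transform(Pr)), model.eta(exp.transform(Br))
    )
    drops = np.zeros(len(exp.layer_names))
    for li in range(len(exp.layer_names)):
        acc = 0.0
        for _ in range(n_permutations):
            pooled = np.concatenate([Pr[:, li], Br[:, li]])
            perm = rng.permutation(pooled)
            Pp, Bp = Pr.copy(), Br.copy()
            Pp[:, li] = perm[:n_p]
            Bp[:, li] = perm[n_p:]
            auc_perm = auc_presence_background(
                model.eta(exp.transform(Pp)), model.eta(exp.transform(Bp))
            )
            acc += max(0.0, base - auc_perm)
        drops[li] = acc / n_permutations
    total = drops.sum()
    if total > 0:
        pct = 100.0 * drops / total
    else:
        pct = np.full_like(drops, 100.0 / len(drops))
    imp = {name: float(v) for name, v in zip(exp.layer_names, pct)}
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else 0.0
    return imp, sd


@dataclass
class NullModelResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def null_model_test(
    observed_auc: float,
    n_occ: int,
    domain_cells: np.ndarray,
    stack: PredictorStack,
    background: BackgroundSet,
    n_null: int = 100,
    k: int = 10,
    classes: Sequence[str] = ("hinge",),
    tau: float = 0.5,
    seed: int = 0,
    min_samples: int = 12,
    background_pool: np.ndarray | None = None,
    **cv_kwargs,
) -> NullModelResult:
    """Raes-ter Steege null-model significance test.

    Fits ``n_null`` models to ``n_occ`` uniformly random cells each,
    cross-validated exactly like the species model, and computes the
    one-sided p-value (1 + #{null mean AUC >= observed}) / (n_null + 1).
    """
    if n_occ < k:
        raise ValueError(f"n_occ={n_occ} below k={k}")
    if n_null < 19:
        warnings.warn(
            f"n_null={n_null} < 19: a p-value at alpha = 0.05 is unresolvable"
        )
    domain_cells = np.asarray(domain_cells, dtype=int).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_null)
    for i in range(n_null):
        idx = rng.choice(len(domain_cells), size=n_occ, replace=False)
        cv = cross_validate(
            domain_cells[idx],
            stack,
            background,
            k=k,
            classes=classes,
            tau=tau,
            seed=int(rng.integers(2**31)),
            min_samples=min_samples,
            background_pool=background_pool,
            with_importance=False,
            **cv_kwargs,
        )
        null_aucs[i] = cv.mean_test_auc
    p = (1 + int(np.sum(null_aucs >= observed_auc))) / (n_null + 1)
    return NullModelResult(observed_auc=observed_auc, null_aucs=null_aucs, p_value=p)


@dataclass
class TgbBiasResult:
    tgb_mean: float
    tgb_sd: float
    null_mean: float
    null_sd: float
    null_q95: float
    biased: bool
    tgb_aucs: np.ndarray
    null_aucs: np.ndarray

    def summary(self) -> str:
        return (
            f"TGB AUC {self.tgb_mean:.3f} +/- {self.tgb_sd:.3f}; "
            f"null AUC {self.null_mean:.3f} +/- {self.null_sd:.3f}; "
            f"bias {'detected' if self.biased else 'not detected'}"
        )


def tgb_bias_test(
    tgb_cells: np.ndarray,
    domain_cells: np.ndarray,
    stack: PredictorStack,
    n_points: int = 5000,
    n_tgb_sets: int = 10,
    n_null: int = 100,
    seed: int = 0,
    k: int = 10,
    classes: Sequence[str] = ("hinge",),
    tau: float = 0.5,
    n_background: int = 1000,
    min_samples: int = 12,
) -> TgbBiasResult:
    """Detect recorder-effort bias by comparing TGB draws against null draws.

    Models whose "presences" are draws from the target-group background are
    cross-validated against models on uniform random draws; bias is declared
    when the TGB mean AUC exceeds the null distribution's 95th percentile
    (if recording were spatially unbiased the two would coincide).
    """
    tgb_cells = np.asarray(tgb_cells, dtype=int).reshape(-1, 2)
    domain_cells = np.asarray(domain_cells, dtype=int).reshape(-1, 2)
    if len(tgb_cells) == 0:
        raise ValueError("empty TGB cell pool")
    rng = np.random.default_rng(seed)

    def mean_auc_for(pool: np.ndarray, n_sets: int) -> np.ndarray:
        aucs = np.empty(n_sets)
        n_draw = min(n_points, len(pool))
        for i in range(n_sets):
            idx = rng.choice(len(pool), size=n_draw, replace=False)
            bg = sample_background(
                domain_cells, n=n_background, seed=int(rng.integers(2**31))
            )
            cv = cross_validate(
                pool[idx],
                stack,
                bg,
                k=k,
                classes=classes,
                tau=tau,
                seed=int(rng.integers(2**31)),
                min_samples=min_samples,
                background_pool=domain_cells,
                with_importance=False,
            )
            aucs[i] = cv.mean_test_auc
        return aucs

    tgb_aucs = mean_auc_for(tgb_cells, n_tgb_sets)
    null_aucs = mean_auc_for(domain_cells, n_null)
    q95 = float(np.percentile(null_aucs, 95))
    return TgbBiasResult(
        tgb_mean=float(tgb_aucs.mean()),
        tgb_sd=float(tgb_aucs.std(ddof=1)) if n_tgb_sets > 1 else 0.0,
        null_mean=float(null_aucs.mean()),
        null_sd=float(null_aucs.std(ddof=1)) if n_null > 1 else 0.0,
        null_q95=q95,
        biased=bool(tgb_aucs.mean() > q95),
        tgb_aucs=tgb_aucs,
        null_aucs=null_aucs,
    )


def single_predictor_gain_ranks(
    presence_cells: np.ndarray,
    stack: PredictorStack,
    background: BackgroundSet,
    k: int = 10,
    tau: float = 0.5,
    seed: int = 0,
    classes: Sequence[str] = ("hinge",),
    n_hinge_knots: int = 50,
    beta0: float = 1.0,
    min_samples: int = 12,
) -> pd.DataFrame:
    """Rank predictors by the gain of their single-predictor models.

    Gain is the mean log-likelihood improvement of the fitted q over the
    uniform background distribution (training: on training presences;
    testing: on held-out presences), averaged over the k folds. Rank 1 is the
    lowest gain; ties get average ranks.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need >= 2 predictors to rank")
    cells = np.asarray(presence_cells, dtype=int).reshape(-1, 2)
    n = len(cells)
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng)
    n_b = len(background.cells)
    rows = []
    for name in names:
        sub = stack.subset([name])
        expansion = build_features(
            sub,
            background.cells,
            classes=classes,
            n_presence=n,
            min_samples=min_samples,
            n_hinge_knots=n_hinge_knots,
        )
        Fp_all = expansion.transform(sub.matrix(cells))
        Fb = expansion.transform(sub.matrix(background.cells))
        tg, sg = [], []
        for fold in folds:
            train_idx = np.setdiff1d(np.arange(n), fold)
            beta = default_beta(Fb, len(train_idx), beta0)
            model = fit_maxent(Fp_all[train_idx], Fb, reg_beta=beta, tau=tau)
            # gain = mean log(n_b * q(x)) at presences
            tg.append(float(model.eta(Fp_all[train_idx]).mean() + np.log(n_b)))
            sg.append(float(model.eta(Fp_all[fold]).mean() + np.log(n_b)))
        rows.append({"predictor": name, "train_gain": np.mean(tg), "test_gain": np.mean(sg)})
    out = pd.DataFrame(rows).set_index("predictor")
    out["train_rank"] = rankdata(out["train_gain"], method="average")
    out["test_rank"] = rankdata(out["test_gain"], method="average")
    return out


def rank_correlation_bootstrap(
    ranks_a: Sequence[float],
    ranks_b: Sequence[float],
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman's rho of the observed pairing, with a permutation p-value.

    p is the proportion of random re-pairings with rho >= observed, with
    +1/(n_boot + 1) continuity.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("rank lists must have equal length")
    if len(a) < 3:
        raise ValueError("need rank lists of length >= 3")
    rho = float(spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        if spearmanr(a, rng.permutation(b)).statistic >= rho:
            count += 1
    p = (count + 1) / (n_boot + 1)
    return rho, p
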