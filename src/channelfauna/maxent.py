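"""Presence-only maximum-entropy (maxent) niche model.

The model is the Gibbs distribution over background locations

    q_λ(x) = exp(Σ_j λ_j f_j(x)) / Z(λ),   Z(λ) = Σ_background exp(Σ_j λ_j f_j)

whose feature expectations match the presence-sample means — equivalently the
maximizer of the L1-penalized presence log-likelihood

    L(λ) = (1/m) Σ_presences Σ_j λ_j f_j(x_i) − log Z(λ) − Σ_j β_j |λ_j|.

Features are deterministic transforms of the environmental variables (linear,
quadratic, product, hinge), all scaled to [0, 1] by their background range, so
one regularization scale serves all classes. Fitting is cyclic coordinate
descent with Newton steps soft-thresholded by β and a backtracking guard, so
the objective never decreases and every accepted update's gain can be
attributed to the feature's source variable — the raw material for percent
contributions.

The "logistic" output c·q/(1+c·q) with c = e^H (H the entropy of q over the
background) rescales the raw distribution to an interpretable 0-1 habitat
probability.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_layers import PredictorStack
from .grids import RasterLayer

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "FeatureBuilder",
    "MaxentModel",
    "default_feature_classes",
    "build_features",
    "fit",
    "predict_raw",
    "predict_logistic",
    "training_gain",
    "cross_validate",
    "CVResult",
    "FoldResult",
]

DEFAULT_N_KNOTS = 10


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: class, source variable(s), scaling bounds, hinge knot."""

    feature_class: str  # linear | quadratic | product | hinge
    variables: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]  # (min, max) per source variable
    knot: float | None = None
    direction: str | None = None  # forward | reverse, hinge only

    @property
    def label(self) -> str:
        tag = "*".join(self.variables)
        if self.feature_class == "hinge":
            return f"hinge_{self.direction}({tag}@{self.knot:.4g})"
        return f"{self.feature_class}({tag})"


def default_feature_classes(n_presence: int) -> tuple[str, ...]:
    """Feature classes activated by presence sample size.

    Linear always; quadratic from 10 presences; hinge from 15; product from
    80 — the conventional sample-size ladder for maxent-style models.
    """
    classes = ["linear"]
    if n_presence >= 10:
        classes.append("quadratic")
    if n_presence >= 15:
        classes.append("hinge")
    if n_presence >= 80:
        classes.append("product")
    return tuple(classes)


class FeatureBuilder:
    """Builds the feature matrix; fitted on background, applied everywhere.

    The same specs transform presence, background, and prediction points, so
    train/test/score are always in one feature space.
    """

    def __init__(self, specs: list[FeatureSpec]):
        self.specs = specs

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        classes: tuple[str, ...] = ("linear",),
        n_knots: int = DEFAULT_N_KNOTS,
    ) -> "FeatureBuilder":
        bounds: dict[str, tuple[float, float]] = {}
        usable: list[str] = []
        for var in background.columns:
            lo = float(np.nanmin(background[var]))
            hi = float(np.nanmax(background[var]))
            if not (hi > lo):
                warnings.warn(f"constant variable {var!r} excluded from features")
                continue
            bounds[var] = (lo, hi)
            usable.append(var)
        specs: list[FeatureSpec] = []
        for var in usable:
            specs.append(FeatureSpec("linear", (var,), (bounds[var],)))
        if "quadratic" in classes:
            for var in usable:
                specs.append(FeatureSpec("quadratic", (var,), (bounds[var],)))
        if "product" in classes:
            for i, a in enumerate(usable):
                for b in usable[i + 1 :]:
                    specs.append(
                        FeatureSpec("product", (a, b), (bounds[a], bounds[b]))
                    )
        if "hinge" in classes:
            for var in usable:
                lo, hi = bounds[var]
                # knots at equally spaced background quantiles, strictly interior
                qs = np.linspace(0, 1, n_knots + 2)[1:-1]
                knots = np.quantile(background[var].to_numpy(), qs)
                for k in knots:
                    if not (lo < k < hi):
                        continue
                    for direction in ("forward", "reverse"):
                        specs.append(
                            FeatureSpec(
                                "hinge", (var,), (bounds[var],), float(k), direction
                            )
                        )
        return cls(specs)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """(n_points, n_features) matrix; all features lie in [0, 1]."""
        n = len(table)
        out = np.empty((n, len(self.specs)))
        for j, s in enumerate(self.specs):
            (lo, hi) = s.bounds[0]
            v = table[s.variables[0]].to_numpy(dtype=float)
            scaled = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
            if s.feature_class == "linear":
                out[:, j] = scaled
            elif s.feature_class == "quadratic":
                out[:, j] = scaled**2
            elif s.feature_class == "product":
                lo2, hi2 = s.bounds[1]
                v2 = table[s.variables[1]].to_numpy(dtype=float)
                out[:, j] = scaled * np.clip((v2 - lo2) / (hi2 - lo2), 0.0, 1.0)
            elif s.feature_class == "hinge":
                if s.direction == "forward":
                    out[:, j] = np.clip((v - s.knot) / (hi - s.knot), 0.0, 1.0)
                else:
                    out[:, j] = np.clip((s.knot - v) / (s.knot - lo), 0.0, 1.0)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature class {s.feature_class!r}")
        if not np.isfinite(out).all():
            raise ValueError("non-finite feature values")
        return out

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.specs]


def build_features(
    background: pd.DataFrame,
    classes: tuple[str, ...] = ("linear",),
    n_knots: int = DEFAULT_N_KNOTS,
) -> tuple[np.ndarray, FeatureBuilder]:
    """Fit feature specs on the background table; return its matrix + builder."""
    builder = FeatureBuilder.from_background(background, classes, n_knots)
    return builder.transform(background), builder


@dataclass
class MaxentModel:
    """A fitted maxent model: features, coefficients, normalizer, entropy."""

    builder: FeatureBuilder
    lam: np.ndarray
    log_z: float
    entropy: float
    beta: np.ndarray
    trace: list[tuple[str, float]] = field(default_factory=list)
    n_background: int = 0
    converged: bool = True
    n_sweeps: int = 0

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for s in self.builder.specs:
            for v in s.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "class": s.feature_class,
                    "variables": list(s.variables),
                    "bounds": [list(b) for b in s.bounds],
                    "knot": s.knot,
                    "direction": s.direction,
                    "lambda": float(l),
                    "beta": float(b_),
                }
                for s, l, b_ in zip(self.builder.specs, self.lam, self.beta)
            ],
            "log_z": float(self.log_z),
            "entropy": float(self.entropy),
            "n_background": int(self.n_background),
            "converged": bool(self.converged),
            "n_sweeps": int(self.n_sweeps),
            "trace": [
                {"variable": v, "gain": float(g)} for v, g in self.trace
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _logsumexp(a: np.ndarray) -> float:
    m = a.max()
    return float(m + np.log(np.exp(a - m).sum()))


def _regularization(
    f_presence: np.ndarray, multiplier: float, floor_frac: float = 0.05
) -> np.ndarray:
    """β_j = r · s_j / sqrt(m): presence-sample std, floored, over root m."""
    m = f_presence.shape[0]
    s = f_presence.std(axis=0, ddof=0)
    s = np.maximum(s, floor_frac)  # features live in [0,1]; floor 5% of range
    return multiplier * s / np.sqrt(m)


def fit(
    f_presence: np.ndarray,
    f_background: np.ndarray,
    builder: FeatureBuilder | None = None,
    beta: np.ndarray | float | None = None,
    reg_multiplier: float = 1.0,
    max_sweeps: int = 500,
    tol: float = 1e-7,
    ktol: float = 1e-7,
) -> MaxentModel:
    """Maximize the L1-penalized maxent objective by coordinate descent.

    ``beta`` may be a per-feature vector, a scalar, or None (the default
    presence-std scaling times ``reg_multiplier``). Convergence: relative
    objective change below ``tol`` over a full sweep *and* every coordinate's
    KKT violation below ``ktol`` (at β=0 the violation is exactly the
    moment-matching gap), or ``max_sweeps`` sweeps, whichever first;
    non-convergence warns but still returns the model. Each accepted coordinate update appends ``(source variable,
    objective gain)`` to the fit trace (product features split their gain
    between both sources).
    """
    if f_presence.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    if f_background.shape[0] < 10:
        raise ValueError("need at least 10 background points")
    if f_presence.shape[1] != f_background.shape[1]:
        raise ValueError("feature matrices are not column-aligned")
    if not (np.isfinite(f_presence).all() and np.isfinite(f_background).all()):
        raise ValueError("non-finite feature values")

    K = f_presence.shape[1]
    if beta is None:
        beta_vec = _regularization(f_presence, reg_multiplier)
    else:
        beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (K,)).copy()
    if (beta_vec < 0).any():
        raise ValueError("beta must be nonnegative")

    p_mean = f_presence.mean(axis=0)
    lam = np.zeros(K)
    scores = np.zeros(f_background.shape[0])
    log_z = _logsumexp(scores)

    def objective(lz: float, lam_vec: np.ndarray) -> float:
        return float(p_mean @ lam_vec - lz - beta_vec @ np.abs(lam_vec))

    obj = objective(log_z, lam)
    trace: list[tuple[str, float]] = []
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        obj_start = obj
        for j in range(K):
            fj = f_background[:, j]
            w = np.exp(scores - log_z)  # softmax over background
            e_j = float(w @ fj)
            v_j = float(w @ (fj * fj)) - e_j**2
            g = p_mean[j] - e_j
            h = max(v_j, 1e-12)
            # soft-thresholded Newton step on the penalized coordinate problem
            z = lam[j] + g / h
            new_lam = np.sign(z) * max(abs(z) - beta_vec[j] / h, 0.0)
            delta = new_lam - lam[j]
            if delta == 0.0:
                continue
            # backtracking guard: the quadratic model can overshoot
            accepted = False
            for _ in range(40):
                cand_lam = lam[j] + delta
                cand_scores = scores + delta * fj
                cand_log_z = _logsumexp(cand_scores)
                cand_obj = (
                    obj
                    + p_mean[j] * delta
                    - (cand_log_z - log_z)
                    - beta_vec[j] * (abs(cand_lam) - abs(lam[j]))
                )
                if cand_obj >= obj:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-15:
                    break
            if not accepted:
                continue
            gain = cand_obj - obj
            lam[j] = cand_lam
            scores = cand_scores
            log_z = cand_log_z
            obj = cand_obj
            if gain > 0:
                spec = builder.specs[j] if builder is not None else None
                if spec is not None and len(spec.variables) == 2:
                    trace.append((spec.variables[0], gain / 2))
                    trace.append((spec.variables[1], gain / 2))
                else:
                    var = spec.variables[0] if spec is not None else f"f{j}"
                    trace.append((var, gain))
        if abs(obj - obj_start) <= tol * (abs(obj_start) + 1.0):
            # stationarity check: |E_q f − p̄| bounded by β at the optimum
            w_end = np.exp(scores - log_z)
            grad = p_mean - w_end @ f_background
            viol = np.where(
                lam == 0.0,
                np.maximum(np.abs(grad) - beta_vec, 0.0),
                np.abs(grad - beta_vec * np.sign(lam)),
            )
            if viol.max() <= ktol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"maxent fit did not converge in {max_sweeps} sweeps "
            f"(last objective {obj:.6g})"
        )
    w = np.exp(scores - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(w * np.where(w > 0, np.log(w), 0.0)).sum())
    return MaxentModel(
        builder=builder if builder is not None else FeatureBuilder([]),
        lam=lam,
        log_z=log_z,
        entropy=entropy,
        beta=beta_vec,
        trace=trace,
        n_background=f_background.shape[0],
        converged=converged,
        n_sweeps=sweep,
    )


def predict_raw(model: MaxentModel, features: np.ndarray) -> np.ndarray:
    """Raw maxent probabilities exp(Σλf − log Z); sum to 1 over the background."""
    if features.shape[1] != model.lam.size:
        raise ValueError("feature dimension mismatch")
    return np.exp(features @ model.lam - model.log_z)


def predict_logistic(model: MaxentModel, features: np.ndarray) -> np.ndarray:
    """Logistic output c·raw/(1 + c·raw) with c = e^H, in (0, 1)."""
    raw = predict_raw(model, features)
    c = np.exp(model.entropy)
    return c * raw / (1.0 + c * raw)


def training_gain(
    model: MaxentModel, f_presence: np.ndarray
) -> float:
    """Mean presence log-likelihood improvement over the uniform model.

    gain = mean_presences(Σλf − log Z) + log(n_background); zero for the
    uniform model, nonnegative for any β=0 optimum.
    """
    ll = f_presence @ model.lam - model.log_z
    return float(ll.mean() + np.log(model.n_background))


@dataclass
class FoldResult:
    model: MaxentModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_auc: float
    test_auc: float
    train_gain: float
    mtp: float  # minimum training presence logistic score


@dataclass
class CVResult:
    folds: list[FoldResult]
    mean_raster: RasterLayer | None
    builder: FeatureBuilder

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean([f.test_auc for f in self.folds]))

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean([f.train_auc for f in self.folds]))

    @property
    def mean_mtp(self) -> float:
        return float(np.mean([f.mtp for f in self.folds]))


def cross_validate(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    env: PredictorStack | None,
    k: int,
    seed: int,
    classes: tuple[str, ...] | None = None,
    n_knots: int = DEFAULT_N_KNOTS,
    reg_multiplier: float = 1.0,
    max_sweeps: int = 500,
) -> CVResult:
    """k-fold cross-validated replicate models and the mean prediction raster.

    Presences are shuffled once (``seed``) and split into k folds of sizes
    differing by at most one; each fold is the test set exactly once. ``k``
    larger than the presence count is lowered with a warning. Test AUC is
    test presences versus the full background. The mean raster is the
    cellwise mean logistic prediction across fold models (requires ``env``).
    """
    from .evaluation import auc as _auc  # local import avoids a cycle

    m = len(presence)
    if k < 2:
        raise ValueError("k must be >= 2")
    if m < k:
        warnings.warn(f"k={k} lowered to presence count {m}")
        k = m
    if classes is None:
        train_size = m - int(np.ceil(m / k))
        classes = default_feature_classes(max(train_size, 2))
    builder = FeatureBuilder.from_background(background, classes, n_knots)
    f_bg = builder.transform(background)
    f_pres = builder.transform(presence)

    grid_feats = None
    sea = None
    if env is not None:
        sea = env.sea_mask()
        r, c = np.nonzero(sea)
        grid_feats = builder.transform(env.values_at(r, c))

    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds_idx = np.array_split(order, k)

    folds: list[FoldResult] = []
    raster_sum = None
    for test_idx in folds_idx:
        train_idx = np.setdiff1d(order, test_idx)
        model = fit(
            f_pres[train_idx],
            f_bg,
            builder=builder,
            reg_multiplier=reg_multiplier,
            max_sweeps=max_sweeps,
        )
        train_scores = predict_logistic(model, f_pres[train_idx])
        test_scores = predict_logistic(model, f_pres[test_idx])
        bg_scores = predict_logistic(model, f_bg)
        folds.append(
            FoldResult(
                model=model,
                train_idx=train_idx,
                test_idx=np.asarray(test_idx),
                train_auc=_auc(train_scores, bg_scores),
                test_auc=_auc(test_scores, bg_scores),
                train_gain=training_gain(model, f_pres[train_idx]),
                mtp=float(train_scores.min()),
            )
        )
        if grid_feats is not None:
            pred = predict_logistic(model, grid_feats)
            raster_sum = pred if raster_sum is None else raster_sum + pred

    mean_raster = None
    if raster_sum is not None and env is not None:
        vals = np.full(env.spec.shape, np.nan)
        vals[sea] = raster_sum / k
        mean_raster = RasterLayer(
            spec=env.spec, name="mean_logistic", values=vals, season=env.season
        )
    return CVResult(folds=folds, mean_raster=mean_raster, builder=builder)
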