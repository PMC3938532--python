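"""Model scoring: AUC, MTP thresholding, jackknife importance, contributions.

With presence-only data there are no true absences, so the ROC contrasts
presences against background points: AUC is the probability that a random
presence outscores a random background point (ties count one half). The
minimum-training-presence (MTP) threshold — the lowest predicted value at any
training presence — declares suitable every cell at least as suitable as an
observed occurrence; its defining property is that binarizing a fold's
prediction at its own MTP keeps 100% of that fold's training presences inside
habitat.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import maxent
from .grids import RasterLayer

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "mtp_threshold",
    "binarize",
    "jackknife_importance",
    "percent_contribution",
    "discrimination_class",
    "EvaluationReport",
]


def auc(presence_scores, background_scores) -> float:
    """Rank-sum AUC: P(random presence outscores random background), ties ½."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty score list")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def mtp_threshold(fold_training_scores: list[np.ndarray]) -> float:
    """Mean over folds of each fold's minimum training-presence score."""
    minima = []
    for scores in fold_training_scores:
        arr = np.asarray(scores, dtype=float)
        if arr.size == 0:
            raise ValueError("a fold contributed no training scores")
        minima.append(arr.min())
    return float(np.mean(minima))


def binarize(prediction: RasterLayer, threshold: float) -> RasterLayer:
    """Habitat/non-habitat map: cell = 1 iff score ≥ threshold; NaN preserved."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    vals = np.where(
        np.isnan(prediction.values),
        np.nan,
        (prediction.values >= threshold).astype(float),
    )
    return RasterLayer(
        spec=prediction.spec,
        name=f"{prediction.name}_habitat",
        values=vals,
        season=prediction.season,
        provenance=f"binarized at {threshold:.6g}",
    )


def _fit_eval(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str],
    classes: tuple[str, ...],
    reg_multiplier: float,
    k: int,
    seed: int,
    max_sweeps: int = 500,
) -> tuple[float, float]:
    """(training gain, AUC) for a model on a variable subset.

    With k >= 2 the AUC is the mean k-fold test AUC; with k < 2 it is the
    training AUC of the single full-data fit (cheaper; used by default in
    the pipeline's jackknife).
    """
    pres = presence[variables]
    bg = background[variables]
    builder = maxent.FeatureBuilder.from_background(bg, classes)
    f_bg = builder.transform(bg)
    f_pres = builder.transform(pres)
    model = maxent.fit(
        f_pres, f_bg, builder=builder, reg_multiplier=reg_multiplier,
        max_sweeps=max_sweeps,
    )
    gain = maxent.training_gain(model, f_pres)
    if k >= 2:
        cv = maxent.cross_validate(
            pres, bg, None, k, seed, classes=classes,
            reg_multiplier=reg_multiplier, max_sweeps=max_sweeps,
        )
        score = cv.mean_test_auc
    else:
        score = auc(
            maxent.predict_logistic(model, f_pres),
            maxent.predict_logistic(model, f_bg),
        )
    return gain, score


def jackknife_importance(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str] | None = None,
    k: int = 0,
    seed: int = 0,
    classes: tuple[str, ...] | None = None,
    reg_multiplier: float = 1.0,
    max_sweeps: int = 500,
) -> pd.DataFrame:
    """Leave-one-out / only-one variable importance table.

    For each variable the model is refit without it and with only it;
    training gain and AUC are reported for both, alongside the full model
    (rows indexed by variable, plus a ``__full__`` row). A variable whose
    refit fails is flagged (NaN entries) without disturbing the others.
    """
    if variables is None:
        variables = list(presence.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    if classes is None:
        classes = maxent.default_feature_classes(len(presence))
    rows = {}
    full_gain, full_auc = _fit_eval(
        presence, background, variables, classes, reg_multiplier, k, seed,
        max_sweeps,
    )
    rows["__full__"] = {
        "gain_without": full_gain, "gain_only": full_gain,
        "auc_without": full_auc, "auc_only": full_auc,
    }
    for v in variables:
        entry = {}
        rest = [w for w in variables if w != v]
        try:
            gw, aw = _fit_eval(
                presence, background, rest, classes, reg_multiplier, k, seed,
                max_sweeps,
            )
        except Exception as exc:  # refit failure flagged, others unaffected
            logger.warning("jackknife without-%s failed: %s", v, exc)
            gw, aw = np.nan, np.nan
        try:
            go, ao = _fit_eval(
                presence, background, [v], classes, reg_multiplier, k, seed,
                max_sweeps,
            )
        except Exception as exc:
            logger.warning("jackknife only-%s failed: %s", v, exc)
            go, ao = np.nan, np.nan
        entry.update(
            gain_without=gw, gain_only=go, auc_without=aw, auc_only=ao
        )
        rows[v] = entry
    return pd.DataFrame(rows).T


def percent_contribution(trace: list[tuple[str, float]]) -> dict[str, float]:
    """Percent of fit-path objective gain attributable to each variable.

    Positive gain increments are summed per source variable and normalized to
    100. If no increment is positive (a no-signal fit) the contribution is
    uniform across observed variables, with a warning.
    """
    if not trace:
        raise ValueError("empty fit trace")
    sums: dict[str, float] = {}
    for var, gain in trace:
        if gain > 0:
            sums[var] = sums.get(var, 0.0) + gain
    if not sums:
        warnings.warn("no positive gain increments; uniform contributions")
        vars_seen = sorted({v for v, _ in trace})
        return {v: 100.0 / len(vars_seen) for v in vars_seen}
    total = sum(sums.values())
    return {v: 100.0 * g / total for v, g in sums.items()}


#: Hosmer–Lemeshow discrimination bins
_CLASSES = [
    (0.5, "no better than random"),
    (0.7, "poor"),
    (0.8, "acceptable"),
    (0.9, "excellent"),
    (1.0 + 1e-12, "outstanding"),
]


def discrimination_class(auc_value: float) -> str:
    """Hosmer–Lemeshow label for an AUC: ≤0.5 random, then poor/acceptable/
    excellent/outstanding at 0.7/0.8/0.9."""
    if not (0.0 <= auc_value <= 1.0):
        raise ValueError("AUC must lie in [0, 1]")
    if auc_value <= 0.5:
        return "no better than random"
    if auc_value < 0.7:
        return "poor"
    if auc_value < 0.8:
        return "acceptable"
    if auc_value < 0.9:
        return "excellent"
    return "outstanding"


@dataclass
class EvaluationReport:
    """Everything the evaluation emits for one (target, season) model."""

    fold_train_auc: list[float]
    fold_test_auc: list[float]
    mean_auc: float
    mtp: float
    discrimination: str
    percent_contribution: dict[str, float]
    jackknife: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "fold_train_auc": [round(float(a), 10) for a in self.fold_train_auc],
            "fold_test_auc": [round(float(a), 10) for a in self.fold_test_auc],
            "mean_auc": round(float(self.mean_auc), 10),
            "mtp_threshold": round(float(self.mtp), 10),
            "discrimination_class": self.discrimination,
            "percent_contribution": {
                k: round(float(v), 10)
                for k, v in sorted(self.percent_contribution.items())
            },
            "notes": self.notes,
        }
        if self.jackknife is not None:
            d["jackknife"] = {
                idx: {c: (None if pd.isna(row[c]) else round(float(row[c]), 10))
                      for c in self.jackknife.columns}
                for idx, row in self.jackknife.iterrows()
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def evaluate_cv(cv: "maxent.CVResult", trace_model: "maxent.MaxentModel",
                jackknife: pd.DataFrame | None = None) -> EvaluationReport:
    """Assemble an EvaluationReport from a CV result and a full-data fit.

    A fully shrunk model (regularization drove every coefficient to zero, so
    the fit path recorded no gain) reports uniform contributions.
    """
    mean_auc = cv.mean_test_auc
    if trace_model.trace:
        contributions = percent_contribution(trace_model.trace)
    else:
        vs = trace_model.variables
        warnings.warn("empty fit trace (fully shrunk model); "
                      "uniform contributions")
        contributions = {v: 100.0 / len(vs) for v in vs}
    return EvaluationReport(
        fold_train_auc=[f.train_auc for f in cv.folds],
        fold_test_auc=[f.test_auc for f in cv.folds],
        mean_auc=mean_auc,
        mtp=cv.mean_mtp,
        discrimination=discrimination_class(mean_auc),
        percent_contribution=contributions,
        jackknife=jackknife,
    )
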