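"""Uncertainty-score OOD detection with class-wise quantile thresholds.

Three scores are computed per sample from a trained classifier:

* MSP — the maximum softmax probability; OOD samples tend to score lower.
* Energy — ``-T * log sum_k exp(logit_k / T)`` (T = 1); logits of ID samples
  tend to be larger, so the energy of OOD samples is higher.
* Mahalanobis — the minimum squared Mahalanobis distance from the
  penultimate-layer feature vector to the class centers, under a tied
  covariance estimated on training features; OOD samples sit further from
  every center.

All scores are handled in an "oriented" convention in which HIGHER means
more OOD-like (MSP is negated). Class-wise cutoffs are the 95% quantile of
oriented scores of held-out ID samples grouped by their true class; at test
time a sample is flagged OOD when its oriented score strictly exceeds the
cutoff of its predicted class (nearest-center class for Mahalanobis). A
majority vote of the three detectors is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = [
    "msp_score",
    "energy_score",
    "MahalanobisFit",
    "fit_mahalanobis",
    "mahalanobis_score",
    "score_table",
    "ThresholdSet",
    "calibrate_thresholds",
    "detect",
    "majority_vote",
    "fnr_at_95",
    "fpr_on_id",
]

METHODS = ("msp", "energy", "mahalanobis")


def msp_score(proba: np.ndarray) -> np.ndarray:
    """Maximum softmax probability per sample."""
    proba = np.atleast_2d(proba)
    return proba.max(axis=1)


def energy_score(logits: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Energy score: -T * logsumexp(logits / T); higher for OOD samples."""
    logits = np.atleast_2d(logits)
    return -temperature * logsumexp(logits / temperature, axis=1)


@dataclass
class MahalanobisFit:
    """Class centers plus a tied, shrinkage-regularized covariance."""

    classes: list[str]
    means: np.ndarray  # (n_classes, d)
    cov: np.ndarray  # (d, d)
    _cho: tuple = field(repr=False, default=None)

    def solve(self, deltas: np.ndarray) -> np.ndarray:
        if self._cho is None:
            self._cho = cho_factor(self.cov)
        return cho_solve(self._cho, deltas.T).T


def fit_mahalanobis(
    features: np.ndarray, labels, shrinkage: float = 1e-3
) -> MahalanobisFit:
    """Per-class means and a pooled covariance, regularized for small classes.

    The tied covariance is the within-class scatter divided by (n - K), with
    ``shrinkage * trace(cov)/d`` added to the diagonal so the fit stays
    invertible when classes are small or features degenerate.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    n, d = features.shape
    if any(np.sum(labels == c) < 2 for c in classes):
        raise ValueError("every class needs >= 2 samples to fit a covariance")
    means = np.stack([features[labels == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        delta = features[labels == c] - means[i]
        scatter += delta.T @ delta
    denom = max(n - len(classes), 1)
    cov = scatter / denom
    trace = np.trace(cov)
    ridge = shrinkage * (trace / d if trace > 0 else 1.0)
    cov = cov + ridge * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("covariance singular even after shrinkage") from exc
    return MahalanobisFit(classes=[str(c) for c in classes], means=means, cov=cov)


def mahalanobis_score(
    features: np.ndarray, fit: MahalanobisFit, squared: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum (squared) Mahalanobis distance to any class center.

    Returns ``(scores, nearest_classes)``; the nearest-center class is the
    one whose threshold applies at detection time.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    dists = np.empty((features.shape[0], len(fit.classes)))
    for i, mu in enumerate(fit.means):
        delta = features - mu
        dists[:, i] = np.einsum("nd,nd->n", delta, fit.solve(delta))
    idx = dists.argmin(axis=1)
    scores = dists[np.arange(len(idx)), idx]
    if not squared:
        scores = np.sqrt(np.maximum(scores, 0.0))
    return scores, np.array([fit.classes[i] for i in idx])


def score_table(
    model,
    records,
    maha_fit: MahalanobisFit | None = None,
    temperature: float = 1.0,
) -> pd.DataFrame:
    """Per-sample OOD score table for a record collection.

    Columns: sample_id, species (true label), predicted_class, msp, energy,
    mahalanobis, maha_class. Oriented scores are derived on demand by
    :func:`calibrate_thresholds` / :func:`detect`.
    """
    logits = model.logits(records)
    proba = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
    table = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "species": [r.species for r in records],
            "predicted_class": [model.classes[i] for i in proba.argmax(axis=1)],
            "msp": msp_score(proba),
            "energy": energy_score(logits, temperature),
        }
    )
    if maha_fit is not None:
        feats = model.penultimate_features(records)
        scores, nearest = mahalanobis_score(feats, maha_fit)
        table["mahalanobis"] = scores
        table["maha_class"] = nearest
    return table


def _oriented(table: pd.DataFrame, method: str) -> np.ndarray:
    if method == "msp":
        return -table["msp"].to_numpy()
    return table[method].to_numpy()


@dataclass
class ThresholdSet:
    """Per-class cutoffs on the oriented score of one method."""

    method: str
    q: float
    cutoffs: dict[str, float]
    low_confidence: list[str] = field(default_factory=list)

    def cutoff_for(self, cls: str) -> float:
        return self.cutoffs[cls]


def calibrate_thresholds(
    table: pd.DataFrame,
    q: float = 0.95,
    methods: tuple[str, ...] = METHODS,
    group_by: str = "species",
    min_class_size: int = 5,
) -> dict[str, ThresholdSet]:
    """Class-wise ``q``-quantile cutoffs from an ID calibration score table.

    Samples are grouped by their true class; classes with fewer than
    ``min_class_size`` calibration samples are flagged low-confidence (their
    quantile rests on very few minima) but still receive a cutoff.
    """
    methods = tuple(m for m in methods if m == "msp" or m in table.columns)
    out: dict[str, ThresholdSet] = {}
    for method in methods:
        oriented = _oriented(table, method)
        cutoffs: dict[str, float] = {}
        low: list[str] = []
        for cls, idx in table.groupby(group_by).groups.items():
            values = oriented[table.index.get_indexer(idx)]
            if values.size == 0:
                continue
            if values.size < min_class_size:
                low.append(str(cls))
            cutoffs[str(cls)] = float(np.quantile(values, q))
        out[method] = ThresholdSet(method=method, q=q, cutoffs=cutoffs, low_confidence=low)
    return out


def detect(
    table: pd.DataFrame, thresholds: ThresholdSet | dict[str, ThresholdSet],
    method: str | None = None,
) -> np.ndarray:
    """Boolean OOD flags: oriented score strictly above the class cutoff.

    The applicable class is the predicted class for MSP/energy and the
    nearest-center class for Mahalanobis. Scores exactly at the cutoff are
    accepted as ID.
    """
    if isinstance(thresholds, dict):
        if method is None:
            raise ValueError("method required when passing a threshold dict")
        thresholds = thresholds[method]
    method = thresholds.method
    class_col = "maha_class" if method == "mahalanobis" else "predicted_class"
    oriented = _oriented(table, method)
    cut = np.array([thresholds.cutoffs[c] for c in table[class_col]])
    return oriented > cut


def majority_vote(*flag_sets: np.ndarray) -> np.ndarray:
    """OOD iff a majority of detectors says OOD (no ties with three voters)."""
    if len(flag_sets) < 2:
        raise ValueError("majority vote needs at least two detectors")
    stacked = np.stack([np.asarray(f, dtype=bool) for f in flag_sets])
    return stacked.sum(axis=0) * 2 > stacked.shape[0]


def fnr_at_95(flags_on_ood: np.ndarray) -> float:
    """Fraction of true-OOD samples accepted as ID."""
    flags_on_ood = np.asarray(flags_on_ood, dtype=bool)
    if flags_on_ood.size == 0:
        raise ValueError("empty input")
    return float(1.0 - flags_on_ood.mean())


def fpr_on_id(flags_on_id: np.ndarray) -> float:
    """Fraction of true-ID samples rejected as OOD."""
    flags_on_id = np.asarray(flags_on_id, dtype=bool)
    if flags_on_id.size == 0:
        raise ValueError("empty input")
    return float(flags_on_id.mean())
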