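"""The learning pipeline: class re-weighting, supervised MDL discretization
and weighted ridge-regularised logistic regression.

The three stages mirror a classical filter-then-classify design:

1. ``balance_classes`` gives every instance a weight so that each class
   carries half the total weight (total preserved at n).
2. ``mdl_discretize_fit`` finds cut points for the numeric features by
   recursive entropy minimisation, accepting a split only when the
   information gain beats the minimum-description-length cost
   (Fayyad & Irani); instance weights enter through the class counts and
   cut points land at midpoints of adjacent observed values, rounded to six
   decimals.
3. ``fit_logistic`` maximises the weighted log-likelihood minus
   ridge * ||beta||^2 (intercept unpenalised, default ridge 1e-8) over an
   indicator encoding of the discretized bins.

``train_pipeline`` wires the stages together; the decision threshold on the
disease-class probability defaults to 0.56 and classification is positive at
probability >= threshold (boundary inclusive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

DEFAULT_RIDGE = 1.0e-8
DEFAULT_THRESHOLD = 0.56
CUT_PRECISION = 6
MISSING = "missing"

NUMERIC_FEATURES = ("f5", "f8")


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


# ---------------------------------------------------------------------------
# class balancing


def balance_classes(labels: np.ndarray | list, weights: np.ndarray | None = None) -> np.ndarray:
    """Per-instance weights giving each class equal total mass, sum preserved.

    Starting from prior weights (default 1), each class's mass is rescaled to
    (total mass) / (number of classes); instances within a class keep their
    relative weights.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("class balancing needs at least two classes present")
    w = np.ones(len(labels), dtype=float) if weights is None else np.asarray(weights, float)
    total = w.sum()
    out = np.empty_like(w)
    for c in classes:
        mask = labels == c
        out[mask] = w[mask] * (total / len(classes)) / w[mask].sum()
    return out


# ---------------------------------------------------------------------------
# MDL (Fayyad-Irani) supervised discretization


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _mdl_accepts(
    seg: np.ndarray, left: np.ndarray, right: np.ndarray
) -> bool:
    """Fayyad-Irani MDL acceptance for one binary split (weighted counts)."""
    n = seg.sum()
    ent = _entropy(seg)
    ent_l, ent_r = _entropy(left), _entropy(right)
    gain = ent - (left.sum() / n) * ent_l - (right.sum() / n) * ent_r
    k = int((seg > 0).sum())
    k_l = int((left > 0).sum())
    k_r = int((right > 0).sum())
    delta = math.log2(3**k - 2) - (k * ent - k_l * ent_l - k_r * ent_r)
    return gain > (math.log2(n - 1) + delta) / n


def _best_split(values: np.ndarray, counts: np.ndarray) -> int | None:
    """Index i of the entropy-minimising cut between values[i] and values[i+1]."""
    if len(values) < 2:
        return None
    n = counts.sum()
    cum = np.cumsum(counts, axis=0)
    best_i, best_e = None, None
    for i in range(len(values) - 1):
        left = cum[i]
        right = cum[-1] - left
        e = (left.sum() / n) * _entropy(left) + (right.sum() / n) * _entropy(right)
        if best_e is None or e < best_e - 1e-12:
            best_i, best_e = i, e
    return best_i


def _recurse_cuts(values: np.ndarray, counts: np.ndarray, cuts: list[float]) -> None:
    i = _best_split(values, counts)
    if i is None:
        return
    if not _mdl_accepts(counts.sum(axis=0), counts[: i + 1].sum(axis=0),
                        counts[i + 1 :].sum(axis=0)):
        return
    cuts.append(float(round((values[i] + values[i + 1]) / 2.0, CUT_PRECISION)))
    _recurse_cuts(values[: i + 1], counts[: i + 1], cuts)
    _recurse_cuts(values[i + 1 :], counts[i + 1 :], cuts)


def mdl_discretize_fit(
    values: np.ndarray | list,
    labels: np.ndarray | list,
    weights: np.ndarray | list | None = None,
) -> list[float]:
    """Fit Fayyad-Irani cut points for one numeric feature.

    Returns a sorted, strictly increasing list of cut points (possibly empty).
    Missing values (NaN) are ignored during fitting.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    weights = (
        np.ones(len(values)) if weights is None else np.asarray(weights, dtype=float)
    )
    if len(values) < 2:
        raise ValueError("need at least 2 instances")
    keep = ~np.isnan(values)
    values, labels, weights = values[keep], labels[keep], weights[keep]
    if len(values) == 0:
        return []
    classes = np.unique(labels)
    order = np.argsort(values, kind="stable")
    values, labels, weights = values[order], labels[order], weights[order]
    distinct, inverse = np.unique(values, return_inverse=True)
    counts = np.zeros((len(distinct), len(classes)))
    for ci, c in enumerate(classes):
        np.add.at(counts[:, ci], inverse[labels == c], weights[labels == c])
    cuts: list[float] = []
    _recurse_cuts(distinct, counts, cuts)
    return sorted(cuts)


def apply_cuts(values: np.ndarray | list, cuts: list[float]) -> np.ndarray:
    """Map each value to its bin index (0..len(cuts)); NaN maps to -1."""
    values = np.asarray(values, dtype=float)
    bins = np.searchsorted(np.asarray(cuts, dtype=float), values, side="left")
    bins = bins.astype(int)
    bins[np.isnan(values)] = -1
    return bins


# ---------------------------------------------------------------------------
# discretization model over a feature table


@dataclass
class DiscretizationModel:
    """Per-feature cut points (numeric) or observed level lists (categorical)."""

    cuts: dict[str, list[float]] = field(default_factory=dict)
    levels: dict[str, list[str]] = field(default_factory=dict)
    observed: dict[str, list[str]] = field(default_factory=dict)

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        """Map every feature column to string bin labels (totality guaranteed)."""
        out = {}
        for col, cuts in self.cuts.items():
            bins = apply_cuts(features[col].to_numpy(dtype=float), cuts)
            out[col] = np.where(bins < 0, MISSING, np.char.add("bin", bins.astype(str)))
        for col, _ in self.levels.items():
            vals = features[col].astype(object)
            out[col] = np.asarray(
                [MISSING if pd.isna(v) else str(v) for v in vals], dtype=object
            )
        return pd.DataFrame(out, index=features.index)

    def bin_labels(self, col: str) -> list[str]:
        """Encoding levels for a column: those observed at fit time, in stable order."""
        if col in self.observed:
            return self.observed[col]
        if col in self.cuts:
            return [f"bin{i}" for i in range(len(self.cuts[col]) + 1)] + [MISSING]
        return self.levels[col]


def fit_discretization(
    features: pd.DataFrame,
    labels: np.ndarray,
    weights: np.ndarray,
    numeric_features: tuple[str, ...] = NUMERIC_FEATURES,
) -> DiscretizationModel:
    model = DiscretizationModel()
    for col in features.columns:
        if col in numeric_features:
            model.cuts[col] = mdl_discretize_fit(
                features[col].to_numpy(dtype=float), labels, weights
            )
        else:
            observed = sorted(
                {MISSING if pd.isna(v) else str(v) for v in features[col]}
            )
            model.levels[col] = observed
    binned = model.transform(features)
    for col in features.columns:
        full = (
            [f"bin{i}" for i in range(len(model.cuts[col]) + 1)] + [MISSING]
            if col in model.cuts
            else model.levels[col]
        )
        present = set(binned[col])
        model.observed[col] = [l for l in full if l in present]
    return model


# ---------------------------------------------------------------------------
# indicator encoding


def encode_indicators(
    binned: pd.DataFrame, model: DiscretizationModel
) -> tuple[np.ndarray, list[str]]:
    """One-hot encode bin labels; 2-level features collapse to one column."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for col in binned.columns:
        present = model.bin_labels(col)
        if len(present) < 2:
            continue  # constant feature carries no information
        if len(present) == 2:
            present = present[1:]  # single indicator for the second level
        for level in present:
            cols.append((binned[col].to_numpy() == level).astype(float))
            names.append(f"{col}={level}")
    if not cols:
        # all features constant: intercept-only model
        return np.empty((len(binned), 0)), names
    X = np.column_stack(cols)
    return X, names


# ---------------------------------------------------------------------------
# weighted ridge logistic regression


@dataclass
class LogisticModel:
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]
    ridge: float = DEFAULT_RIDGE

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-z))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    ridge: float = DEFAULT_RIDGE,
    feature_names: list[str] | None = None,
    max_iter: int = 500,
) -> LogisticModel:
    """Maximise weighted log-likelihood - ridge * ||beta||^2 (intercept free).

    ``y`` is 1 for the positive (disease) class.  Deterministic given inputs;
    the penalised likelihood is strictly concave for ridge > 0 so the optimum
    is unique even under complete separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("need both classes present, y coded 0/1")
    if X.shape[0] and (np.abs(X).sum(axis=0) == 0).any():
        raise ValueError("all-zero column in the design matrix")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)

    def negloglik(params: np.ndarray) -> tuple[float, np.ndarray]:
        b0, beta = params[0], params[1:]
        z = b0 + X @ beta
        # stable log(1 + exp(z)) and sigmoid
        log1pez = np.logaddexp(0.0, z)
        nll = float(np.sum(w * (log1pez - y * z)) + ridge * beta @ beta)
        p = 1.0 / (1.0 + np.exp(-z))
        resid = w * (p - y)
        grad = np.concatenate(([resid.sum()], X.T @ resid + 2.0 * ridge * beta))
        return nll, grad

    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        negloglik, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-5:
        raise ConvergenceError(
            f"logistic fit did not converge after {res.nit} iterations: {res.message}",
            n_iter=res.nit,
        )
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return LogisticModel(
        coefficients=res.x[1:], intercept=float(res.x[0]),
        feature_names=names, ridge=ridge,
    )


# ---------------------------------------------------------------------------
# the trained pipeline


@dataclass
class TrainedPipeline:
    discretization: DiscretizationModel
    logistic: LogisticModel
    class_weights: dict[str, float]
    threshold: float = DEFAULT_THRESHOLD
    positive_label: str = "D"
    feature_columns: list[str] = field(default_factory=list)

    def predict_probability(self, features: pd.DataFrame) -> np.ndarray:
        """Probability of the disease class for each row."""
        binned = self.discretization.transform(features[self.feature_columns])
        X, _ = encode_indicators(binned, self.discretization)
        return self.logistic.predict_proba(X)

    def predict_class(self, features: pd.DataFrame) -> np.ndarray:
        """'D'/'N' call at the decision threshold (boundary inclusive)."""
        p = self.predict_probability(features)
        return np.where(p >= self.threshold, self.positive_label, "N")

    # -- plain-text serialization ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cuts": self.discretization.cuts,
            "levels": self.discretization.levels,
            "observed": self.discretization.observed,
            "coefficients": dict(
                zip(self.logistic.feature_names, self.logistic.coefficients.tolist())
            ),
            "intercept": self.logistic.intercept,
            "ridge": self.logistic.ridge,
            "class_weights": self.class_weights,
            "threshold": self.threshold,
            "positive_label": self.positive_label,
            "feature_columns": self.feature_columns,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPipeline":
        d = json.loads(Path(path).read_text())
        disc = DiscretizationModel(
            cuts=d["cuts"], levels=d["levels"], observed=d.get("observed", {})
        )
        names = list(d["coefficients"])
        logistic = LogisticModel(
            coefficients=np.asarray([d["coefficients"][n] for n in names]),
            intercept=d["intercept"], feature_names=names, ridge=d["ridge"],
        )
        return cls(
            discretization=disc, logistic=logistic,
            class_weights=d["class_weights"], threshold=d["threshold"],
            positive_label=d["positive_label"], feature_columns=d["feature_columns"],
        )


def train_pipeline(
    features: pd.DataFrame,
    labels: np.ndarray | list,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = DEFAULT_THRESHOLD,
    positive_label: str = "D",
    feature_columns: list[str] | None = None,
    numeric_features: tuple[str, ...] = NUMERIC_FEATURES,
) -> TrainedPipeline:
    """Balance, discretize and fit the logistic model on a feature table."""
    labels = np.asarray(labels)
    if feature_columns is None:
        feature_columns = [c for c in features.columns
                           if c not in ("label", "hgvs_p", "clash_source")]
    feats = features[feature_columns]
    weights = balance_classes(labels)
    disc = fit_discretization(feats, labels, weights, numeric_features=numeric_features)
    binned = disc.transform(feats)
    X, names = encode_indicators(binned, disc)
    y = (labels == positive_label).astype(float)
    logistic = fit_logistic(X, y, weights, ridge=ridge, feature_names=names)
    class_totals = {
        str(c): float(weights[labels == c].sum()) for c in np.unique(labels)
    }
    return TrainedPipeline(
        discretization=disc, logistic=logistic, class_weights=class_totals,
        threshold=threshold, positive_label=positive_label,
        feature_columns=list(feature_columns),
    )
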