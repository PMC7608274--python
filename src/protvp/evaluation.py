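"""Classifier evaluation and cohort-level statistics.

Metrics: confusion counts at a threshold, ROC AUC (trapezoidal, identical to
the Mann-Whitney pairwise-probability form), PR AUC (step-wise average
precision, no interpolation), MCC, pooled stratified tenfold cross-validation,
Mann-Whitney U, McNemar's paired chi-square and the Bonferroni correction,
plus Monte-Carlo reference variant sets for the cohort contrasts.

Cross-validation is leakage-free: balancing, discretization and the logistic
fit happen on the training fold only; out-of-fold scores are pooled into a
single ROC/PR surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classifier import DEFAULT_RIDGE, DEFAULT_THRESHOLD, NUMERIC_FEATURES, train_pipeline
from .io_formats import TopologyAnnotation, VariantRecord
from .structure_features import in_modelled_region

MAX_EXACT_PRODUCT = 400
MAX_ENUMERATION = 200_000


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


@dataclass
class EvalReport:
    roc_points: np.ndarray  # (n, 2) FPR, TPR
    pr_points: np.ndarray  # (n, 2) recall, precision
    auc_roc: float
    auc_pr: float
    mcc: float
    confusion: ConfusionCounts
    threshold: float
    fold_assignments: np.ndarray | None = None
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "mcc": self.mcc,
            "recall_pct": 100.0 * self.confusion.recall,
            "fpr_pct": 100.0 * self.confusion.fpr,
            "precision_pct": 100.0 * self.confusion.precision,
            "threshold": self.threshold,
        }


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both classes must be present")


def _as_binary(labels, positive_label="D") -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OU S":
        return (labels == positive_label).astype(int)
    return labels.astype(int)


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float, positive_label="D"
) -> ConfusionCounts:
    """Counts with predicted positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, positive_label)
    _check_two_classes(y)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def roc_points(scores: np.ndarray, labels: np.ndarray, positive_label="D") -> np.ndarray:
    """(FPR, TPR) at every threshold induced by the scores, plus the corners."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, positive_label)
    _check_two_classes(y)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # collapse tied thresholds to one point
    distinct = np.r_[np.where(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / tps[-1]]
    fpr = np.r_[0.0, fps[distinct] / fps[-1]]
    return np.column_stack([fpr, tpr])


def auc_roc(scores: np.ndarray, labels: np.ndarray, positive_label="D") -> float:
    """Trapezoidal ROC area; equals P(score_D > score_N) + 0.5 P(tie)."""
    pts = roc_points(scores, labels, positive_label)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def pr_points(scores: np.ndarray, labels: np.ndarray, positive_label="D") -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, positive_label)
    _check_two_classes(y)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    preds = np.arange(1, len(y_sorted) + 1)
    distinct = np.r_[np.where(np.diff(s_sorted))[0], len(s_sorted) - 1]
    recall = tps[distinct] / tps[-1]
    precision = tps[distinct] / preds[distinct]
    return np.column_stack([recall, precision])


def auc_pr(scores: np.ndarray, labels: np.ndarray, positive_label="D") -> float:
    """Step-wise (average-precision) PR area: sum of precision at each new
    recall level weighted by the recall increment; no linear interpolation."""
    pts = pr_points(scores, labels, positive_label)
    recall = np.r_[0.0, pts[:, 0]]
    return float(np.sum(np.diff(recall) * pts[:, 1]))


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    positive_label="D",
) -> EvalReport:
    """Full metric panel for one score vector."""
    scores = np.asarray(scores, dtype=float)
    counts = confusion_at_threshold(scores, labels, threshold, positive_label)
    return EvalReport(
        roc_points=roc_points(scores, labels, positive_label),
        pr_points=pr_points(scores, labels, positive_label),
        auc_roc=auc_roc(scores, labels, positive_label),
        auc_pr=auc_pr(scores, labels, positive_label),
        mcc=mcc(counts),
        confusion=counts,
        threshold=threshold,
        scores=scores,
        labels=np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# cross-validation


def stratified_tenfold_cv(
    labels: np.ndarray | list, seed: int, n_folds: int = 10
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds; class proportions per fold within +-1 instance."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; use at most {counts.min()} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    features: pd.DataFrame,
    labels: np.ndarray | list,
    seed: int,
    n_folds: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
    ridge: float = DEFAULT_RIDGE,
    positive_label: str = "D",
    feature_columns: list[str] | None = None,
    numeric_features: tuple[str, ...] = NUMERIC_FEATURES,
    pooled: bool = True,
) -> EvalReport:
    """Pooled out-of-fold evaluation of the full pipeline.

    All three pipeline stages are re-fit inside every training fold.  With
    ``pooled=False`` the report's extras carry per-fold AUCs and their mean
    instead of the single pooled curve being the headline.
    """
    labels = np.asarray(labels)
    folds = stratified_tenfold_cv(labels, seed, n_folds)
    scores = np.full(len(labels), np.nan)
    assignment = np.full(len(labels), -1)
    fold_aucs = []
    for fold_id, (train, test) in enumerate(folds):
        try:
            pipe = train_pipeline(
                features.iloc[train], labels[train], ridge=ridge,
                threshold=threshold, positive_label=positive_label,
                feature_columns=feature_columns, numeric_features=numeric_features,
            )
        except Exception as exc:
            raise RuntimeError(f"fold {fold_id}: pipeline fit failed: {exc}") from exc
        scores[test] = pipe.predict_probability(features.iloc[test])
        assignment[test] = fold_id
        y_te = _as_binary(labels[test], positive_label)
        if 0 < y_te.sum() < len(y_te):
            fold_aucs.append(auc_roc(scores[test], labels[test], positive_label))
    report = evaluate_scores(scores, labels, threshold, positive_label)
    report.fold_assignments = assignment
    report.extras["fold_auc_roc"] = fold_aucs
    report.extras["mean_fold_auc_roc"] = float(np.mean(fold_aucs))
    report.extras["pooled"] = pooled
    return report


# ---------------------------------------------------------------------------
# statistics


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairwise wins plus half-ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (for sample_a) and a two-sided p-value.

    Exact null distribution when n1*n2 <= 400: dynamic programming without
    ties, full combination enumeration for small tied samples; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n1, n2 = len(a), len(b)
    if n1 * n2 <= MAX_EXACT_PRODUCT:
        if not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return u, float(res.pvalue)
        if math.comb(n1 + n2, n1) <= MAX_ENUMERATION:
            return u, _exact_tied_p(pooled, n1, u)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def _exact_tied_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided permutation p over all assignments of the pooled values."""
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def mcnemar(pred_a, pred_b, labels) -> tuple[float, float]:
    """McNemar chi-square (continuity-corrected) on paired classifier calls.

    b10 counts instances a got right and b got wrong, b01 the converse; with
    no discordant pairs the statistic is 0 and p = 1.
    """
    pred_a, pred_b, labels = map(np.asarray, (pred_a, pred_b, labels))
    if not (len(pred_a) == len(pred_b) == len(labels)):
        raise ValueError("prediction vectors and labels must align")
    correct_a = pred_a == labels
    correct_b = pred_b == labels
    b10 = int(np.sum(correct_a & ~correct_b))
    b01 = int(np.sum(~correct_a & correct_b))
    if b10 + b01 == 0:
        return 0.0, 1.0
    statistic = (abs(b10 - b01) - 1) ** 2 / (b10 + b01)
    return statistic, float(stats.chi2.sf(statistic, df=1))


def bonferroni(
    p_values, alpha: float = 0.05, m: int | None = None
) -> tuple[float, list[bool]]:
    """Adjusted threshold alpha/m and per-test significance flags (p < threshold).

    ``m`` is the size of the comparison family; it defaults to the number of
    p-values supplied but can be set larger when only part of the family is
    being flagged (e.g. m=10 gives the 0.005 threshold at alpha 0.05).
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("need at least one p-value")
    m = len(p_values) if m is None else m
    if m < len(p_values):
        raise ValueError("family size m smaller than the number of tests")
    threshold = alpha / m
    return threshold, [p < threshold for p in p_values]


# ---------------------------------------------------------------------------
# Monte-Carlo reference variant sets


def monte_carlo_reference(
    variants: list[VariantRecord],
    mode: str,
    n_draws: int,
    seed: int,
    topology: TopologyAnnotation | None = None,
    reference_sequence: dict[int, str] | None = None,
    exclude_ctd: bool = False,
) -> list[VariantRecord]:
    """Random reference variants for the cohort contrasts.

    ``random_alt`` keeps each observed variant's position and reference
    residue and redraws the introduced residue uniformly from the 19 others;
    ``uniform_position`` draws positions uniformly over the eligible residues
    (modelled, optionally non-CTD) and then a uniform non-reference residue.
    """
    from .aa_scales import STANDARD_AA

    rng = np.random.default_rng(seed)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    out: list[VariantRecord] = []
    if mode == "random_alt":
        for _ in range(n_draws):
            src = variants[rng.integers(len(variants))]
            alts = [aa for aa in STANDARD_AA if aa != src.ref_aa]
            out.append(
                VariantRecord(src.ref_aa, src.position,
                              alts[rng.integers(19)], label="unknown")
            )
    elif mode == "uniform_position":
        if topology is None or reference_sequence is None:
            raise ValueError("uniform_position needs topology and reference sequence")
        eligible = [
            p for p in sorted(reference_sequence)
            if in_modelled_region(topology, p)
            and not (exclude_ctd and topology.ctd_range[0] <= p <= topology.ctd_range[1])
        ]
        if not eligible:
            raise ValueError("no eligible positions")
        for _ in range(n_draws):
            pos = eligible[rng.integers(len(eligible))]
            ref = reference_sequence[pos]
            alts = [aa for aa in STANDARD_AA if aa != ref]
            out.append(VariantRecord(ref, pos, alts[rng.integers(19)], label="unknown"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def all_pairs_volume_reference() -> list[tuple[str, str, float]]:
    """All 380 ordered distinct amino-acid pairs with their volume change."""
    from .aa_scales import STANDARD_AA, volume_change

    return [
        (r, a, volume_change(r, a))
        for r in STANDARD_AA for a in STANDARD_AA if r != a
    ]


# ---------------------------------------------------------------------------
# external-tool comparison (ingested score columns only)


@dataclass(frozen=True)
class ToolConfig:
    name: str
    column: str
    threshold: float
    higher_is_damaging: bool = True


DEFAULT_TOOLS = (
    ToolConfig("SIFT", "sift", 0.05, higher_is_damaging=False),
    ToolConfig("PolyPhen2", "polyphen2", 0.85),
    ToolConfig("CADD", "cadd", 15.0),
    ToolConfig("CADD_raw", "cadd_raw", 5.25),
    ToolConfig("CONDEL", "condel", 0.52),
)


def compare_tools(
    variants: list[VariantRecord],
    tools: tuple[ToolConfig, ...] = DEFAULT_TOOLS,
) -> pd.DataFrame:
    """Metric rows for external predictors from their ingested score columns.

    Scores whose convention is "lower = damaging" are negated for ranking and
    their threshold test flipped, so every row reads on the same scale.
    """
    rows = []
    labels = np.asarray([v.label for v in variants])
    for tool in tools:
        have = [i for i, v in enumerate(variants) if tool.column in v.external_scores]
        if not have:
            continue
        raw = np.asarray([variants[i].external_scores[tool.column] for i in have])
        sub_labels = labels[have]
        ranking = raw if tool.higher_is_damaging else -raw
        rank_threshold = tool.threshold if tool.higher_is_damaging else -tool.threshold
        report = evaluate_scores(ranking, sub_labels, threshold=rank_threshold)
        rows.append({
            "tool": tool.name, "threshold": tool.threshold, "n": len(have),
            "tp": report.confusion.tp, "fp": report.confusion.fp,
            **report.summary(),
        })
    return pd.DataFrame(rows)
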