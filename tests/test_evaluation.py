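"""Metrics, cross-validation and the statistical tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from protvp.evaluation import (
    ConfusionCounts,
    all_pairs_volume_reference,
    auc_pr,
    auc_roc,
    bonferroni,
    compare_tools,
    confusion_at_threshold,
    cross_validate,
    evaluate_scores,
    mann_whitney_u,
    mcc,
    mcnemar,
    monte_carlo_reference,
    stratified_tenfold_cv,
)
from protvp.io_formats import VariantRecord


def random_scores_labels(rng, n=30):
    scores = rng.integers(0, 6, size=n).astype(float)
    labels = rng.integers(0, 2, size=n)
    while labels.sum() in (0, n):
        labels = rng.integers(0, 2, size=n)
    return scores, labels


# -- confusion ----------------------------------------------------------


def test_confusion_perfect_scores():
    c = confusion_at_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5, positive_label=1)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)


def test_confusion_threshold_zero_all_positive():
    c = confusion_at_threshold([0.3, 0.6, 0.1], [1, 0, 0], 0.0, positive_label=1)
    assert c.fpr == 1.0 and c.fn == 0


def test_confusion_matches_enumeration():
    scores = np.array([0.9, 0.56, 0.55, 0.3, 0.56, 0.1])
    labels = np.array([1, 1, 0, 1, 0, 0])
    c = confusion_at_threshold(scores, labels, 0.56, positive_label=1)
    tp = sum(1 for s, l in zip(scores, labels) if s >= 0.56 and l == 1)
    fp = sum(1 for s, l in zip(scores, labels) if s >= 0.56 and l == 0)
    assert (c.tp, c.fp) == (tp, fp)
    assert (c.tn, c.fn) == (3 - fp, 3 - tp)


def test_confusion_single_class_errors():
    with pytest.raises(ValueError):
        confusion_at_threshold([0.5, 0.6], [1, 1], 0.5, positive_label=1)


# -- AUCs ---------------------------------------------------------------


def test_auc_roc_degenerate_cases():
    assert auc_roc([1, 1, 1, 1], [1, 0, 1, 0], positive_label=1) == pytest.approx(0.5)
    assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], positive_label=1) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_auc_roc_equals_pair_counting(seed):
    rng = np.random.default_rng(seed)
    scores, labels = random_scores_labels(rng)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    pairs = sum(
        (p > q) + 0.5 * (p == q) for p in pos for q in neg
    ) / (len(pos) * len(neg))
    assert auc_roc(scores, labels, positive_label=1) == pytest.approx(pairs, abs=1e-12)


def test_auc_pr_perfect_and_null():
    assert auc_pr([4, 3, 2, 1], [1, 1, 0, 0], positive_label=1) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    n = 4000
    labels = rng.integers(0, 2, size=n)
    scores = rng.random(n)
    assert auc_pr(scores, labels, positive_label=1) == pytest.approx(labels.mean(), abs=0.05)


def test_auc_pr_matches_rank_by_rank_summation():
    rng = np.random.default_rng(3)
    scores = rng.random(10)
    labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 1])
    # oracle: walk the ranking, add precision at each positive hit
    order = np.argsort(-scores)
    tp = 0
    total = 0.0
    for k, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            total += tp / k
    assert auc_pr(scores, labels, positive_label=1) == pytest.approx(
        total / labels.sum(), abs=1e-12
    )


# -- MCC ----------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(5, 0, 7, 0), 1.0),
        (ConfusionCounts(0, 7, 0, 5), -1.0),
        (ConfusionCounts(3, 1, 4, 2),
         (3 * 4 - 1 * 2) / math.sqrt((3 + 1) * (3 + 2) * (4 + 1) * (4 + 2))),
        (ConfusionCounts(0, 0, 5, 5), 0.0),
    ],
)
def test_mcc_values(counts, expected):
    assert mcc(counts) == pytest.approx(expected)


# -- cross-validation ---------------------------------------------------


def test_stratified_folds_cover_and_balance():
    labels = np.array(["D"] * 72 + ["N"] * 322)
    folds = stratified_tenfold_cv(labels, seed=0)
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(394))
    for _, te in folds:
        n_d = (labels[te] == "D").sum()
        assert n_d in (7, 8)


def test_stratified_folds_seed_reproducible():
    labels = np.array(["D"] * 30 + ["N"] * 50)
    f1 = stratified_tenfold_cv(labels, seed=5)
    f2 = stratified_tenfold_cv(labels, seed=5)
    for (a, b), (c, d) in zip(f1, f2):
        assert (a == c).all() and (b == d).all()


def test_stratified_folds_small_class_errors():
    with pytest.raises(ValueError, match="folds"):
        stratified_tenfold_cv(np.array(["D"] * 5 + ["N"] * 50), seed=0)


def shuffled_feature_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "f1": rng.integers(0, 2, n),
        "f5": rng.integers(1, 11, n).astype(float),
        "f8": -rng.exponential(0.5, n),
        "label": rng.permutation(["D"] * 60 + ["N"] * 140),
    })


def test_cv_null_labels_near_half():
    aucs = []
    for seed in range(10):
        df = shuffled_feature_table(seed=seed)
        rep = cross_validate(df, df["label"].to_numpy(), seed=seed)
        aucs.append(rep.auc_roc)
    assert 0.4 <= np.mean(aucs) <= 0.6


def test_cv_deterministic_given_seed():
    df = shuffled_feature_table(seed=1)
    r1 = cross_validate(df, df["label"].to_numpy(), seed=3)
    r2 = cross_validate(df, df["label"].to_numpy(), seed=3)
    assert r1.auc_roc == r2.auc_roc
    np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)


def test_cv_pooled_equals_whole_dataset_for_constant_scores():
    """Degenerate check: a feature-free constant model scores everything alike."""
    df = shuffled_feature_table(seed=2)
    df["f_const"] = 1.0
    rep = cross_validate(
        df, df["label"].to_numpy(), seed=0,
        feature_columns=["f_const"], numeric_features=(),
    )
    assert rep.auc_roc == pytest.approx(0.5, abs=1e-12)


# -- Mann-Whitney -------------------------------------------------------


def exhaustive_permutation_p(a, b):
    """Oracle: enumerate all assignments via rank sums (different route)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    mean_u = n1 * len(b) / 2
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


def test_mw_identical_samples():
    u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert u == 4.5 and p == pytest.approx(1.0)


def test_mw_complete_separation():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(exhaustive_permutation_p([1, 2, 3], [4, 5, 6]))


@pytest.mark.parametrize("seed", range(6))
def test_mw_matches_exhaustive_permutation(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
    a = rng.integers(0, 8, n1).astype(float)
    b = rng.integers(0, 8, n2).astype(float)
    _, p = mann_whitney_u(a, b)
    assert p == pytest.approx(exhaustive_permutation_p(a, b), abs=1e-9)


def test_mw_large_sample_uses_normal_approximation():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 80)
    b = rng.normal(0.8, 1, 90)
    u, p = mann_whitney_u(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided")
    assert p == pytest.approx(ref.pvalue)
    assert u == pytest.approx(ref.statistic)


def test_mw_empty_sample_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# -- McNemar ------------------------------------------------------------


def test_mcnemar_identical_predictions():
    y = np.array([1, 0, 1, 0, 1])
    stat, p = mcnemar(y, y, y)
    assert stat == 0.0 and p == 1.0


def test_mcnemar_formula_and_statsmodels_cross_check():
    # b10 = 15 (a right, b wrong), b01 = 3
    labels = np.ones(30, dtype=int)
    pred_a = np.ones(30, dtype=int)
    pred_b = np.ones(30, dtype=int)
    pred_b[:15] = 0          # b wrong where a right -> b10 = 15
    pred_a[15:18] = 0        # a wrong where b right -> b01 = 3
    stat, p = mcnemar(pred_a, pred_b, labels)
    expected_stat = (abs(15 - 3) - 1) ** 2 / (15 + 3)
    assert stat == pytest.approx(expected_stat)
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    table = [[9, 15], [3, 3]]  # concordant counts arbitrary
    res = sm.mcnemar(table, exact=False, correction=True)
    assert stat == pytest.approx(res.statistic)
    assert p == pytest.approx(res.pvalue)


def test_mcnemar_balanced_discordance_small_statistic():
    labels = np.ones(20, dtype=int)
    pred_a = np.ones(20, dtype=int)
    pred_b = np.ones(20, dtype=int)
    pred_b[:5] = 0
    pred_a[5:10] = 0
    stat, p = mcnemar(pred_a, pred_b, labels)
    assert stat == pytest.approx(1 / 10)  # (|5-5|-1)^2 / 10
    assert p > 0.7


# -- Bonferroni ---------------------------------------------------------


def test_bonferroni_study_configuration():
    threshold, flags = bonferroni([0.048, 0.002, 0.2] + [0.5] * 7, alpha=0.05)
    assert threshold == pytest.approx(0.005)
    assert flags == [False, True, False] + [False] * 7


def test_bonferroni_single_test():
    threshold, flags = bonferroni([0.04])
    assert threshold == 0.05 and flags == [True]


# -- Monte-Carlo references ---------------------------------------------


def test_random_alt_never_equals_ref():
    variants = [VariantRecord("L", 10, "R"), VariantRecord("K", 20, "E")]
    ref = monte_carlo_reference(variants, "random_alt", 2000, seed=0)
    assert all(v.ref_aa != v.alt_aa for v in ref)
    assert {v.position for v in ref} <= {10, 20}


def test_uniform_position_marginal_uniform(small_bundle):
    model, topo, refseq = small_bundle
    draws = monte_carlo_reference(
        [], "uniform_position", 10_000, seed=1,
        topology=topo, reference_sequence=refseq,
    )
    eligible = [p for p in refseq if any(lo <= p <= hi for lo, hi in topo.modelled_ranges)]
    counts = np.array([sum(v.position == p for v in draws) for p in eligible])
    stat, p = sps.chisquare(counts)
    assert p > 0.01


def test_all_pairs_volume_reference_has_380_entries():
    ref = all_pairs_volume_reference()
    assert len(ref) == 380
    assert len({(r, a) for r, a, _ in ref}) == 380


def test_reference_sets_seed_deterministic():
    variants = [VariantRecord("L", 10, "R")]
    a = monte_carlo_reference(variants, "random_alt", 50, seed=9)
    b = monte_carlo_reference(variants, "random_alt", 50, seed=9)
    assert [v.key() for v in a] == [v.key() for v in b]


# -- external tool comparison -------------------------------------------


def test_compare_tools_directionality():
    """A tool whose low scores mean damaging must rank like its negation."""
    rng = np.random.default_rng(6)
    variants = []
    for i in range(60):
        label = "D" if i < 20 else "N"
        damaging = label == "D"
        sift = rng.uniform(0, 0.04) if damaging else rng.uniform(0.06, 1.0)
        poly = rng.uniform(0.86, 1.0) if damaging else rng.uniform(0.0, 0.84)
        variants.append(
            VariantRecord("L", i + 1, "R", label, {"sift": sift, "polyphen2": poly})
        )
    table = compare_tools(variants).set_index("tool")
    assert table.loc["SIFT", "auc_roc"] == pytest.approx(1.0)
    assert table.loc["SIFT", "tp"] == 20 and table.loc["SIFT", "fp"] == 0
    assert table.loc["PolyPhen2", "auc_roc"] == pytest.approx(1.0)


def test_evaluate_scores_consistency_between_metrics():
    rng = np.random.default_rng(8)
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    while labels.sum() in (0, 50):
        labels = rng.integers(0, 2, 50)
    rep = evaluate_scores(scores, labels, threshold=0.5, positive_label=1)
    c = confusion_at_threshold(scores, labels, 0.5, positive_label=1)
    assert rep.confusion == c
    assert rep.mcc == pytest.approx(mcc(c))
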