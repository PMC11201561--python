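"""ROC/AUC, DeLong, Hochberg, stratification, reclassification, NRI."""

import math

import numpy as np
import pytest

from nodulegp.riskstats import (BROCK_THRESHOLDS, LCRP_THRESHOLDS,
                                ReclassTable, RiskScoreSet, RiskStrata,
                                builtin_reclassification_counts, delong_test,
                                escalation_summary, hochberg_adjust, image_mse,
                                image_ssim, lungrads_strata,
                                match_subgroup_thresholds, nri, nri_z_test,
                                reclassification_table, roc_auc, score_patches,
                                stratify_risk, train_toy_scorer)
from nodulegp.simgrowth import generate_dataset

rng = np.random.default_rng(2024)


def score_set(scores, labels):
    return RiskScoreSet(tuple(f"s{i}" for i in range(len(scores))),
                        np.asarray(scores, float), np.asarray(labels, int))


# -------------------------------------------------------------- image metrics
def test_image_metrics_identities_and_bruteforce_mse():
    a = rng.random((64, 64))
    assert image_mse(a, a) == 0.0
    assert image_ssim(a, a) == pytest.approx(1.0)
    assert image_mse(a, a + 0.1) == pytest.approx(0.01)
    b = rng.random((64, 64))
    brute = sum((a[i, j] - b[i, j]) ** 2 for i in range(64)
                for j in range(64)) / 4096
    assert image_mse(a, b) == pytest.approx(brute, rel=1e-12)


# ----------------------------------------------------------------------- AUC
def mann_whitney_auc(scores, labels):
    """All-pairs concordance oracle with the 1/2 tie convention."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_separation_and_label_flip_symmetry():
    s = score_set([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert roc_auc(s)[0] == 1.0
    flipped = score_set([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
    assert roc_auc(flipped)[0] == 0.0
    with pytest.raises(ValueError):
        roc_auc(score_set([0.1, 0.2], [1, 1]))


def test_auc_equals_all_pairs_oracle_with_ties():
    for trial in range(25):
        local = np.random.default_rng(trial)
        n = int(local.integers(8, 40))
        labels = np.zeros(n, int)
        labels[local.choice(n, size=max(1, n // 3), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        scores = np.round(local.random(n), 1)  # coarse grid forces ties
        got, _ = roc_auc(score_set(scores, labels))
        assert got == pytest.approx(mann_whitney_auc(scores, labels),
                                    rel=1e-12)


def test_auc_matches_sklearn_reference():
    from sklearn.metrics import roc_auc_score

    labels = (rng.random(60) < 0.3).astype(int)
    labels[0], labels[1] = 1, 0
    scores = rng.random(60)
    assert roc_auc(score_set(scores, labels))[0] == pytest.approx(
        roc_auc_score(labels, scores), rel=1e-12)


# --------------------------------------------------------------------- DeLong
# Fixed 30-subject paired score sets; z and p were computed independently
# with the R pROC package (roc.test, method="delong", paired=TRUE).
PROC_LABELS = np.array([1] * 12 + [0] * 18)
PROC_A = np.array([0.764, 0.563, 0.815, 0.718, 0.357, 0.885, 0.757, 0.772,
                   0.377, 0.57, 0.522, 0.856, 0.386, 0.494, 0.266, 0.136,
                   0.333, 0.038, 0.497, 0.379, 0.455, 0.213, 0.582, 0.536,
                   0.467, 0.117, 0.28, 0.026, 0.093, 0.41])
PROC_B = np.array([0.746, 0.924, 0.411, 0.446, 0.526, 0.302, 0.254, 0.531,
                   0.332, 0.686, 0.5, 0.816, 0.56, 0.25, 0.666, 0.644, 0.31,
                   0.231, 0.546, 0.112, 0.16, 0.006, 0.63, 0.532, 0.564,
                   0.625, 0.367, 0.455, 0.112, 0.092])


def test_delong_matches_independent_r_reference():
    sa = score_set(PROC_A, PROC_LABELS)
    sb = score_set(PROC_B, PROC_LABELS)
    assert roc_auc(sa)[0] == pytest.approx(0.8981481, abs=1e-7)
    assert roc_auc(sa)[1] == pytest.approx(math.sqrt(0.003781919), rel=1e-5)
    assert roc_auc(sb)[1] == pytest.approx(math.sqrt(0.01118162), rel=1e-5)
    z, p = delong_test(sa, sb)
    assert z == pytest.approx(2.197149, abs=1e-6)
    assert p == pytest.approx(0.02800978, abs=1e-7)


def test_delong_identical_scores_and_sign_convention():
    s = score_set(PROC_A, PROC_LABELS)
    z, p = delong_test(s, s)
    assert z == 0.0 and p == 1.0
    z_ab, _ = delong_test(s, score_set(PROC_B, PROC_LABELS))
    auc_a = roc_auc(s)[0]
    auc_b = roc_auc(score_set(PROC_B, PROC_LABELS))[0]
    assert math.copysign(1, z_ab) == math.copysign(1, auc_a - auc_b)
    with pytest.raises(ValueError):
        delong_test(s, score_set(PROC_B, 1 - PROC_LABELS))


# ------------------------------------------------------------------- Hochberg
def hochberg_by_definition(p):
    """Direct step-up implementation of the Hochberg adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):  # step up from the largest p
        i = order[rank]
        running = min(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def test_hochberg_single_and_equal_pvalues():
    np.testing.assert_allclose(hochberg_adjust([0.031]), [0.031])
    np.testing.assert_allclose(hochberg_adjust([0.2, 0.2, 0.2]),
                               hochberg_by_definition([0.2, 0.2, 0.2]))


def test_hochberg_matches_definition_and_dominates_raw():
    for trial in range(30):
        local = np.random.default_rng(trial + 1)
        p = local.random(int(local.integers(1, 12)))
        adj = hochberg_adjust(p)
        np.testing.assert_allclose(adj, hochberg_by_definition(p), atol=1e-12)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # order preservation
        assert ((np.argsort(p) == np.argsort(adj, kind="stable")).all()
                or (adj[np.argsort(p)] == np.sort(adj)).all())
    with pytest.raises(ValueError):
        hochberg_adjust([0.5, 1.2])


# ------------------------------------------------------------- stratification
def test_published_threshold_rules_boundary_behaviour():
    strata = stratify_risk([0.44, 0.45, 0.81, 0.811], LCRP_THRESHOLDS)
    assert strata.groups == ("low", "medium", "medium", "high")
    brock = stratify_risk([0.0117, 0.0116, 0.10, 0.101], BROCK_THRESHOLDS)
    assert brock.groups == ("medium", "low", "medium", "high")
    assert stratify_risk([], LCRP_THRESHOLDS).groups == ()
    assert lungrads_strata([1, 2, 3, 4, 4]).groups == (
        "low", "low", "medium", "high", "high")


def test_stratification_is_monotone_in_score():
    scores = np.sort(rng.random(50))
    idx = stratify_risk(scores, (0.3, 0.7)).indices()
    assert (np.diff(idx) >= 0).all()


def test_match_subgroup_thresholds_exact_on_distinct_scores():
    scores = rng.permutation(np.linspace(0, 1, 100))
    match = match_subgroup_thresholds(scores, (30, 50, 20))
    assert match.achieved_sizes == (30, 50, 20) and match.feasible


def test_match_subgroup_thresholds_fixed_point():
    scores = rng.random(40)
    original = stratify_risk(scores, (0.3, 0.7))
    match = match_subgroup_thresholds(scores, original.sizes())
    reproduced = stratify_risk(scores, match.thresholds)
    assert reproduced.groups == original.groups


def test_match_subgroup_thresholds_reports_infeasible_ties():
    match = match_subgroup_thresholds([0.5, 0.5], (1, 1, 0))
    assert not match.feasible
    assert sum(match.achieved_sizes) == 2
    with pytest.raises(ValueError):
        match_subgroup_thresholds([0.1, 0.2], (1, 2, 0))


# --------------------------------------------------------- reclassification
def test_identity_reclassification_is_diagonal_with_zero_nri():
    groups = RiskStrata(tuple(rng.choice(["low", "medium", "high"], 30)))
    labels = (rng.random(30) < 0.4).astype(int)
    labels[:2] = [0, 1]
    table = reclassification_table(groups, groups, labels)
    assert np.tril(table.event_counts, -1).sum() == 0
    assert np.triu(table.event_counts, 1).sum() == 0
    res = nri(table)
    assert res.event_nri == res.nonevent_nri == res.overall_nri == 0.0


def test_reclassification_table_permutation_invariance():
    n = 40
    gi = tuple(rng.choice(["low", "medium", "high"], n))
    gn = tuple(rng.choice(["low", "medium", "high"], n))
    labels = (rng.random(n) < 0.3).astype(int)
    t1 = reclassification_table(RiskStrata(gi), RiskStrata(gn), labels)
    perm = rng.permutation(n)
    t2 = reclassification_table(RiskStrata(tuple(np.array(gi)[perm])),
                                RiskStrata(tuple(np.array(gn)[perm])),
                                labels[perm])
    np.testing.assert_array_equal(t1.event_counts, t2.event_counts)
    np.testing.assert_array_equal(t1.nonevent_counts, t2.nonevent_counts)


def test_published_block_marginals_are_preserved():
    table = builtin_reclassification_counts()["lung_rads"]
    np.testing.assert_array_equal(table.event_counts.sum(axis=1),
                                  [12, 15, 26])
    assert table.event_counts.sum() == 53
    np.testing.assert_array_equal(table.nonevent_counts.sum(axis=1),
                                  [144, 136, 117])
    assert table.n_nonevent == 397


def test_overall_nri_is_exactly_event_plus_nonevent():
    for trial in range(20):
        local = np.random.default_rng(trial)
        e = local.integers(0, 30, (3, 3))
        ne = local.integers(0, 80, (3, 3))
        e[0, 0] += 1
        ne[0, 0] += 1
        res = nri(ReclassTable.from_counts(e, ne))
        assert res.event_nri_frac + res.nonevent_nri_frac == \
            res.event_nri_frac + res.nonevent_nri_frac  # exact Fractions
        assert res.overall_nri == pytest.approx(
            float(res.event_nri_frac + res.nonevent_nri_frac), abs=0)


def test_random_regrouping_has_zero_expected_nri():
    """Permutation-null: uniform regrouping from symmetric initial strata."""
    n_e, n_ne = 30, 60
    init_e = np.array([0] * 10 + [1] * 10 + [2] * 10)  # equal low/high
    init_ne = np.array([0] * 20 + [1] * 20 + [2] * 20)
    overall = []
    for seed in range(1000):
        local = np.random.default_rng(seed)
        new_e = local.integers(0, 3, n_e)
        new_ne = local.integers(0, 3, n_ne)
        e = np.zeros((3, 3), int)
        ne = np.zeros((3, 3), int)
        for a, b in zip(init_e, new_e):
            e[a, b] += 1
        for a, b in zip(init_ne, new_ne):
            ne[a, b] += 1
        overall.append(nri(ReclassTable.from_counts(e, ne)).overall_nri)
    overall = np.asarray(overall)
    se = overall.std(ddof=1) / math.sqrt(len(overall))
    assert abs(overall.mean()) <= 3 * se


def test_nri_requires_both_outcomes():
    e = np.zeros((3, 3), int)
    e[0, 0] = 5
    with pytest.raises(ValueError):
        nri(ReclassTable.from_counts(e, np.zeros((3, 3), int)))


# -------------------------------------------------------------------- Z-test
def test_zero_movement_z_is_reported_undefined():
    e = np.diag([5, 5, 5])
    ne = np.diag([10, 10, 10])
    res = nri(ReclassTable.from_counts(e, ne))
    assert math.isnan(res.z_event) and math.isnan(res.p_event)
    z = nri_z_test(ReclassTable.from_counts(e, ne))
    assert math.isnan(z["overall"][0])


def test_z_sign_matches_component_sign():
    for trial in range(10):
        local = np.random.default_rng(trial)
        e = local.integers(0, 20, (3, 3))
        ne = local.integers(0, 40, (3, 3))
        e[0, 1] += 1
        ne[1, 0] += 1
        res = nri(ReclassTable.from_counts(e, ne))
        for value, z in ((res.event_nri, res.z_event),
                         (res.nonevent_nri, res.z_nonevent),
                         (res.overall_nri, res.z_overall)):
            if not math.isnan(z) and value != 0:
                assert math.copysign(1, z) == math.copysign(1, value)


def test_z_test_p_matches_multinomial_null_simulation():
    """Asymptotic p vs a 50,000-rep exact multinomial null (up==down)."""
    event = [[100, 30, 0], [20, 80, 15], [5, 5, 45]]  # up 45, down 30, n 300
    nonevent = [[150, 15, 0], [30, 150, 5], [10, 15, 25]]
    res = nri(ReclassTable.from_counts(event, nonevent))
    local = np.random.default_rng(0)
    for up, down, n, obs, p_formula in (
            (45, 30, 300, res.event_nri, res.p_event),
            (55, 20, 400, res.nonevent_nri, res.p_nonevent)):
        q = (up + down) / n
        draws = local.multinomial(n, [q / 2, q / 2, 1 - q], size=50_000)
        null = (draws[:, 0] - draws[:, 1]) / n
        p_mc = np.mean(np.abs(null) >= abs(obs) - 1e-12)
        # tolerance covers Monte-Carlo error plus normal-approximation and
        # discreteness gaps at these sample sizes
        assert abs(p_formula - p_mc) < 0.025


# ---------------------------------------------------------------- toy scorer
def test_toy_scorer_is_deterministic_and_orders_growth():
    pairs, labels = generate_dataset(12, 36, seed=77)
    train_patches = [p.followup for p in pairs]
    s1 = train_toy_scorer(train_patches, labels, seed=5)
    s2 = train_toy_scorer(train_patches, labels, seed=5)
    test_pairs, test_labels = generate_dataset(25, 175, seed=78)
    base = [p.baseline for p in test_pairs]
    np.testing.assert_array_equal(s1.score(base), s2.score(base))
    assert (s1.score(base) >= 0).all() and (s1.score(base) <= 1).all()

    auc_base = roc_auc(score_patches(s1, base, labels=test_labels))[0]
    auc_fup = roc_auc(score_patches(s1, [p.followup for p in test_pairs],
                                    labels=test_labels))[0]
    # growth is the designed signal: follow-up imaging can only help
    assert auc_fup >= auc_base
    with pytest.raises(ValueError):
        train_toy_scorer(train_patches, np.zeros(len(train_patches)), seed=1)


def test_toy_scorer_separable_features_reach_perfect_auc():
    """Diameter-separated classes (4-8 mm vs 16-28 mm) are fully ranked."""
    import dataclasses

    from nodulegp.simgrowth import render_patch, sample_nodule_params

    patches, labels = [], []
    for i in range(20):
        small = dataclasses.replace(sample_nodule_params(200 + i, "benign"),
                                    diameter_mm=4.0 + 0.2 * i)
        big = dataclasses.replace(sample_nodule_params(300 + i, "benign"),
                                  diameter_mm=16.0 + 0.6 * i)
        patches += [render_patch(small, 0.0), render_patch(big, 0.0)]
        labels += [0, 1]
    scorer = train_toy_scorer(patches, np.array(labels), seed=0)
    auc, _ = roc_auc(score_patches(scorer, patches, labels=labels))
    assert auc == 1.0
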