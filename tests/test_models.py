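"""Random-forest Model/Results objects, cross-validation and validation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guidekit.features import tokenize_many
from guidekit.models import (
    GuideEfficiencyModel,
    LoadedModel,
    SnvOutcomeModel,
    cross_validate,
    percentile_ranks,
    train_regressor,
    validate,
)
from guidekit.simulate import OutcomeConfig, generate_outcomes, random_dna


def test_constant_labels_predicted_exactly():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    res = train_regressor(X, np.full(30, 42.0), n_trees=50, seed=1)
    assert np.allclose(res.predict(X), 42.0)


def test_planted_single_feature_signal_recovered():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, size=500)
    X = x.reshape(-1, 1)
    y = 100 * x  # noise-free linear signal
    model = GuideEfficiencyModel(X[:400], y[:400], n_trees=200)
    res = model.fit(seed=0)
    pred = res.predict(X[400:])
    r, _ = stats.pearsonr(y[400:], pred)
    assert r >= 0.95


def test_refit_with_same_seed_is_bit_identical():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 5))
    y = rng.uniform(0, 100, 60)
    a = GuideEfficiencyModel(X, y, n_trees=50).fit(seed=7)
    b = GuideEfficiencyModel(X, y, n_trees=50).fit(seed=7)
    assert np.array_equal(a.predict(X), b.predict(X))
    assert a.oob_error == b.oob_error


def test_regressor_requires_minimum_samples():
    with pytest.raises(ValueError, match="at least 10"):
        GuideEfficiencyModel(np.zeros((5, 2)), np.zeros(5))


def test_cross_validation_partitions_index_set():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(53, 3))
    y = rng.uniform(0, 100, 53)
    cv = cross_validate(X, y, task="regression", folds=5, n_trees=20, seed=0)
    assign = cv["fold_assignment"]
    assert len(assign) == 53
    assert set(assign) == set(range(5))
    # disjoint and exhaustive by construction of the assignment vector
    counts = np.bincount(assign)
    assert counts.sum() == 53 and counts.min() >= 10


def test_stratified_folds_preserve_class_counts():
    X = np.random.default_rng(4).normal(size=(40, 2))
    y = np.array(["A"] * 30 + ["C"] * 10)
    cv = cross_validate(X, y, task="classification", folds=5, n_trees=10, seed=0)
    for k in range(5):
        fold_labels = y[cv["fold_assignment"] == k]
        assert (fold_labels == "A").sum() == 6
        assert (fold_labels == "C").sum() == 2


def test_class_smaller_than_folds_errors_with_name():
    X = np.zeros((10, 2))
    y = np.array(["A"] * 8 + ["G"] * 2)
    with pytest.raises(ValueError, match="'G'"):
        cross_validate(X, y, task="classification", folds=5)


def test_perfect_signal_regression_cv():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 1, 300)
    cv = cross_validate(
        x.reshape(-1, 1), 100 * x, task="regression", folds=5, n_trees=100, seed=0
    )
    assert cv["mean"]["pearson_r"] >= 0.9


def test_validate_identity_and_antisymmetry():
    truth = np.array([1.0, 2.0, 5.0, 7.0])
    rep = validate(truth, truth, task="regression")
    assert rep.mse == 0.0
    assert rep.pearson_r == pytest.approx(1.0)
    neg = validate(truth, -truth, task="regression")
    assert neg.pearson_r == pytest.approx(-1.0)


def test_validate_matches_hand_formulas():
    truth = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    pred = np.array([1.0, 5.0, 5.0, 9.0, 12.0])
    rep = validate(truth, pred, task="regression")
    mse_hand = np.mean((truth - pred) ** 2)
    r_hand = np.corrcoef(truth, pred)[0, 1]
    assert rep.mse == pytest.approx(mse_hand, abs=1e-9)
    assert rep.pearson_r == pytest.approx(r_hand, abs=1e-9)


def test_validate_zero_variance_reports_missing():
    rep = validate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], task="regression")
    assert rep.pearson_r is None


def test_percentile_rank_conventions():
    vals = [10.0, 20.0, 30.0, 40.0]
    ranks = percentile_ranks(vals)
    # mean-of-strict-and-weak: max of n distinct values -> (75+100)/2
    assert ranks[-1] == pytest.approx(87.5)
    assert list(ranks) == sorted(ranks)
    assert np.allclose(percentile_ranks([5.0] * 4), 50.0)


def test_percentile_rank_tie_fixture_matches_hand():
    vals = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    ranks = percentile_ranks(vals)
    # value 2.0: strict = 1/6, weak = 3/6 -> mean = 2/6
    assert ranks[1] == pytest.approx(100 * 2 / 6)
    assert ranks[2] == pytest.approx(100 * 2 / 6)


def test_feature_importance_normalised_and_ranked():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 5))
    y = 50 + 30 * X[:, 2]  # only feature 2 is informative
    res = train_regressor(X, np.clip(y, 0, 100), n_trees=100, seed=0,
                          schema=[f"f{i}" for i in range(5)])
    imp = res.feature_importance()
    assert imp[0][0] == "f2"
    assert sum(w for _, w in imp) == pytest.approx(1.0, abs=1e-9)
    assert all(w >= 0 for _, w in imp)


def test_feature_importance_equivariant_under_permutation():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(120, 4))
    y = np.clip(50 + 20 * X[:, 0] - 10 * X[:, 3], 0, 100)
    schema = ["a", "b", "c", "d"]
    res = train_regressor(X, y, n_trees=80, seed=3, schema=schema)
    perm = [2, 0, 3, 1]
    res_p = train_regressor(X[:, perm], y, n_trees=80, seed=3,
                            schema=[schema[i] for i in perm])
    # column order perturbs the forest's internal random draws, so
    # importances agree approximately, with the ranking preserved
    a = dict(res.feature_importance())
    b = dict(res_p.feature_importance())
    assert a.keys() == b.keys()
    assert all(abs(a[k] - b[k]) < 0.02 for k in a)
    assert [n for n, _ in res.feature_importance()][:2] == [
        n for n, _ in res_p.feature_importance()
    ][:2]


def test_snv_classifier_rejects_reference_base_labels():
    X = np.zeros((12, 3))
    y = np.array(["A"] * 6 + ["C"] * 6)
    refs = np.array(["A"] * 6 + ["G"] * 6)
    with pytest.raises(ValueError, match="reference base"):
        SnvOutcomeModel(X, y, reference_bases=refs)


def test_snv_classifier_learns_planted_rule():
    cfg = OutcomeConfig(
        n_targets=500, reads_per_target=200, snv_share=0.65,
        outcome_rule_offset=4, hotspot_enrichment=3.0,
    )
    sim = generate_outcomes(cfg, seed=8)
    # label each target with its majority hotspot SNV outcome
    snvs = sim["alleles"].query(
        "variant_type == 'SNV' and position == @cfg.hotspot_position"
    )
    labels = (
        snvs.groupby(["target_id", "outcome_base"])["read_count"].sum()
        .reset_index()
        .sort_values("read_count")
        .groupby("target_id")
        .last()["outcome_base"]
    )
    windows = sim["targets"].set_index("target_id").loc[labels.index, "window"]
    X, schema = tokenize_many(windows.tolist())
    res = SnvOutcomeModel(X, labels.to_numpy(), schema=schema, n_trees=150).fit(seed=0)
    report = res.holdout_report(test_size=0.25)
    assert report.accuracy >= 0.9
    top5 = [name for name, _ in res.feature_importance()[:5]]
    assert any(f"pos{cfg.outcome_rule_offset}_" in n for n in top5)


def test_confusion_matrix_trace_counts_correct_predictions():
    truth = np.array(list("ACGTACGTAC"))
    pred = np.array(list("ACGTTCGAAC"))
    rep = validate(truth, pred, task="classification")
    assert np.trace(rep.confusion.to_numpy()) == int(np.sum(truth == pred))
    assert rep.confusion.sum(axis=1).tolist() == [
        int((truth == c).sum()) for c in rep.confusion.index
    ]


def test_null_classifier_auc_near_half():
    rng = np.random.default_rng(9)
    n = 1000
    truth = rng.choice(list("ACG"), n)
    scores = rng.dirichlet(np.ones(3), size=n)
    pred = np.array(list("ACG"))[np.argmax(scores, axis=1)]
    rep = validate(truth, pred, task="classification", scores=scores,
                   classes=list("ACG"))
    assert 0.45 <= rep.mean_auc <= 0.55


def test_save_load_roundtrip_and_schema_guard(tmp_path):
    seqs = [random_dna(34, np.random.default_rng(s)) for s in range(40)]
    y = np.random.default_rng(10).uniform(0, 100, 40)
    res = GuideEfficiencyModel.from_sequences(seqs, y, n_trees=30).fit(seed=1)
    path = tmp_path / "model.bin"
    res.save(path)
    assert path.with_suffix(".bin.json").exists()
    loaded = LoadedModel.load(path)
    assert np.array_equal(loaded.predict_sequences(seqs), res.predict(sequences=seqs))
    with pytest.raises(ValueError, match="schema"):
        loaded.predict_sequences([random_dna(20, np.random.default_rng(0))] * 2)


def test_oob_error_definitions():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 120)
    res = GuideEfficiencyModel(x.reshape(-1, 1), 100 * x, n_trees=100).fit(seed=0)
    assert res.oob_error >= 0.0  # an MSE
    seqs = [random_dna(39, np.random.default_rng(s)) for s in range(60)]
    labels = np.array([("A", "C", "G")[s % 3] for s in range(60)])
    X, schema = tokenize_many(seqs)
    cres = SnvOutcomeModel(X, labels, schema=schema, n_trees=60).fit(seed=0)
    assert 0.0 <= cres.oob_error <= 1.0  # a misclassification rate
    assert "misclassification" in cres.summary()


def test_oob_error_lower_on_signal_than_permuted_labels():
    """Paired over 20 seeds: the planted-signal fixture's OOB error never
    loses to its label-permuted twin."""
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(150, 6))
        y = np.clip(50 + 25 * X[:, 0] + rng.normal(0, 5, 150), 0, 100)
        signal = GuideEfficiencyModel(X, y, n_trees=50).fit(seed=seed)
        permuted = GuideEfficiencyModel(X, rng.permutation(y), n_trees=50).fit(
            seed=seed
        )
        wins += signal.oob_error <= permuted.oob_error
    assert wins == 20


def test_holdout_report_regression(screen_sim):
    from guidekit.screen import build_training_table

    table = build_training_table(screen_sim["counts"], screen_sim["bf"])
    model = GuideEfficiencyModel.from_training_table(table, n_trees=100)
    res = model.fit(seed=0)
    rep = res.holdout_report(test_size=0.2)
    assert rep.pearson_r > 0.5
    assert np.all(res.predict(model.X) <= 100.0)
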