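"""Splitting, LDA/OLS fits, selection, bootstrap/randomization, metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ttrqsar.fixtures import gen_classification_dataset, gen_regression_dataset
from ttrqsar.model_build import (
    auc_mann_whitney,
    classification_metrics,
    fit_lda,
    fit_ols,
    loo_bootstrap,
    overfit_knee,
    q2_f3,
    q2_loo,
    r_squared,
    randomization_probability,
    regression_metrics,
    split_by_structure,
    step_up_select,
    y_scramble,
)


# ---------------------------------------------------------------------------
# Splitting


def test_split_nine_compound_stratum_exact_thirds():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((9, 3)), index=[f"c{i}" for i in range(9)])
    train, test = split_by_structure(X)
    assert len(train) == 6 and len(test) == 3
    assert set(train) | set(test) == set(X.index)


def test_split_stratified_sizes_and_pc1_coverage():
    X, y = gen_classification_dataset(n_per_class=(30, 15), seed=1)
    train, test = split_by_structure(X, labels=y)
    ymap = dict(zip(X.index, y))
    tr_a = sum(ymap[i] == "A" for i in train)
    te_a = sum(ymap[i] == "A" for i in test)
    assert (tr_a, te_a) == (20, 10)
    assert (len(train) - tr_a, len(test) - te_a) == (10, 5)
    # both sets span the PC1 range: systematic 1-in-3 keeps the rank gap small
    from ttrqsar.model_build import _pc1_scores

    for cls in ("A", "I"):
        members = [i for i in X.index if ymap[i] == cls]
        scores = dict(zip(members, _pc1_scores(X.loc[members].to_numpy())))
        ranked = sorted(members, key=scores.get)
        ranks_te = [ranked.index(i) for i in test if i in ranked]
        gaps = np.diff([0, *sorted(ranks_te), len(ranked) - 1])
        assert gaps.max() <= 3


def test_split_is_deterministic_and_tie_tolerant():
    rng = np.random.default_rng(2)
    base = rng.standard_normal((4, 3))
    X = pd.DataFrame(np.vstack([base, base[0]]), index=list("abcde"))  # duplicate row
    t1 = split_by_structure(X)
    t2 = split_by_structure(X)
    assert t1 == t2
    assert len(t1[1]) == 1


def test_split_rejects_constant_matrix():
    X = pd.DataFrame(np.ones((6, 2)), index=list("abcdef"))
    with pytest.raises(ValueError, match="PCA"):
        split_by_structure(X)


# ---------------------------------------------------------------------------
# LDA


def test_lda_separable_clouds_train_acc_one():
    X, y = gen_classification_dataset(n_per_class=(20, 20), separation=8.0, seed=3)
    model = fit_lda(X, y)
    assert np.mean(model.predict(X) == y) == 1.0


def test_lda_posterior_half_at_equidistant_point():
    X, y = gen_classification_dataset(n_per_class=(25, 25), separation=2.0, seed=4)
    model = fit_lda(X, y, priors=[0.5, 0.5])
    # midpoint of the class means (scaled space is affine, so use raw means)
    mid = (X[np.array(y) == "A"].mean() + X[np.array(y) == "I"].mean()) / 2
    post = model.posterior(mid.to_numpy())[0]
    assert post == pytest.approx([0.5, 0.5], abs=1e-10)
    assert model.predict(mid.to_numpy())[0] == "A"  # tie goes to the active class


def test_lda_empirical_priors_74_49():
    X, y = gen_classification_dataset(n_per_class=(74, 49), seed=5)
    model = fit_lda(X, y)
    assert model.priors == pytest.approx([74 / 123, 49 / 123])
    assert model.priors == pytest.approx([0.602, 0.398], abs=5e-4)


def test_lda_matches_sklearn_posteriors_and_predictions():
    rng = np.random.default_rng(6)
    for _ in range(50):
        n, p = int(rng.integers(20, 60)), int(rng.integers(2, 6))
        X = rng.standard_normal((n, p))
        y = np.where(rng.random(n) < 0.5, "A", "I")
        if min((y == "A").sum(), (y == "I").sum()) < 3:
            continue
        model = fit_lda(X, y, autoscale=False)
        oracle = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        assert np.abs(model.posterior(X) - oracle.predict_proba(X)).max() < 1e-8
        assert (model.predict(X) == oracle.predict(X)).all()


def test_lda_posteriors_sum_to_one_and_score_shift_invariance():
    X, y = gen_classification_dataset(n_per_class=(15, 15), seed=7)
    model = fit_lda(X, y)
    post = model.posterior(X)
    assert np.allclose(post.sum(axis=1), 1.0)
    shifted = model.intercept + 123.0
    from scipy.special import softmax

    post2 = softmax(model._prepare(X) @ model.coef.T + shifted, axis=1)
    assert np.allclose(post, post2)


def test_lda_singular_covariance_error():
    rng = np.random.default_rng(8)
    col = rng.standard_normal(20)
    X = np.column_stack([col, col])  # perfectly collinear
    y = np.array(["A"] * 10 + ["I"] * 10)
    with pytest.raises(ValueError, match="singular|filter"):
        fit_lda(X, y)


# ---------------------------------------------------------------------------
# OLS


def test_ols_recovers_exact_linear_data():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((25, 2))
    y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
    model = fit_ols(X, y)
    assert model.coef == pytest.approx([1.0, 2.0, -3.0], abs=1e-8)
    assert r_squared(y, model.predict(X)) == pytest.approx(1.0)


def test_ols_constant_response_reports_r2_zero():
    rng = np.random.default_rng(10)
    X = rng.standard_normal((15, 2))
    y = np.full(15, 4.2)
    model = fit_ols(X, y)
    assert model.coef[1:] == pytest.approx([0.0, 0.0], abs=1e-10)
    assert r_squared(y, model.predict(X)) == 0.0


def test_ols_matches_reference_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    for _ in range(50):
        n, p = int(rng.integers(15, 50)), int(rng.integers(1, 5))
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + rng.normal(0, 0.5, n)
        model = fit_ols(X, y)
        oracle = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.abs(model.coef - oracle.params).max() < 1e-8
        assert np.abs(model.se - oracle.bse).max() < 1e-8


def test_ols_coefficient_coverage_simulation():
    """beta-hat within 3 SE of beta in >= 95% of seeded replicates."""
    beta = np.array([0.5, 1.6, -3.3, -11.0])
    hits = 0
    reps = 200
    for s in range(reps):
        rng = np.random.default_rng(1000 + s)
        X = rng.standard_normal((43, 3))
        y = beta[0] + X @ beta[1:] + rng.normal(0, 1.0, 43)
        m = fit_ols(X, y)
        hits += np.all(np.abs(m.coef - beta) <= 3 * m.se)
    assert hits / reps >= 0.95


def test_training_leverages_sum_to_p_plus_one():
    X, y, _, _ = gen_regression_dataset(seed=12)
    model = fit_ols(X, y)
    assert model.leverage(X).sum() == pytest.approx(model.p + 1)


# ---------------------------------------------------------------------------
# Step-up selection


def test_step_up_perfect_descriptor_heads_every_population():
    rng = np.random.default_rng(13)
    X = pd.DataFrame(rng.standard_normal((30, 6)), columns=[f"D{i}" for i in range(6)])
    y = 2.0 * X["D3"].to_numpy()
    trace = step_up_select(X, y, "ols", beam=4, max_size=3)
    for size in trace.populations:
        assert "D3" in trace.best(size)[0]


def test_step_up_infinite_beam_size2_equals_exhaustive_pairs():
    rng = np.random.default_rng(14)
    X = pd.DataFrame(rng.standard_normal((40, 10)), columns=[f"D{i}" for i in range(10)])
    y = X["D1"].to_numpy() - X["D7"].to_numpy() + rng.normal(0, 0.3, 40)
    trace = step_up_select(X, y, "ols", beam=None, max_size=2)
    best_pair, best_r2 = trace.best(2)
    exhaustive = max(
        (
            r_squared(y, fit_ols(X[list(pair)], y).predict(X[list(pair)]))
            for pair in itertools.combinations(X.columns, 2)
        ),
    )
    assert best_r2 == pytest.approx(exhaustive)
    assert set(best_pair) == {"D1", "D7"}


def test_step_up_recovers_true_signal_triple():
    hits = 0
    for s in range(25):
        rng = np.random.default_rng(2000 + s)
        X = pd.DataFrame(
            rng.standard_normal((60, 20)), columns=[f"D{i:02d}" for i in range(20)]
        )
        y = X["D03"] + X["D11"] - X["D17"] + rng.normal(0, 0.25, 60)
        trace = step_up_select(X, y.to_numpy(), "ols", beam=25, max_size=3)
        hits += set(trace.best(3)[0]) == {"D03", "D11", "D17"}
    assert hits / 25 >= 0.9


# ---------------------------------------------------------------------------
# Bootstrap and knee


def test_bootstrap_mr_near_zero_for_wide_margin():
    X, y = gen_classification_dataset(n_per_class=(20, 20), separation=10.0, seed=15)
    est, _ = loo_bootstrap(X, y, X.columns, "lda", B=30, seed=0, repeats=2)
    assert est < 0.05


def test_bootstrap_mr_near_half_for_pure_noise():
    X, y = gen_classification_dataset(n_per_class=(25, 25), separation=0.0, seed=16)
    est, _ = loo_bootstrap(X, y, X.columns, "lda", B=50, seed=0, repeats=2)
    assert 0.4 <= est <= 0.6


def test_bootstrap_mae_exceeds_resubstitution_mae():
    wins = 0
    for s in range(12):
        X, y, _, _ = gen_regression_dataset(n=40, seed=300 + s)
        model = fit_ols(X, y)
        resub = float(np.mean(np.abs(y - model.predict(X))))
        est, _ = loo_bootstrap(X, y, X.columns, "ols", B=30, seed=s, repeats=2)
        wins += est >= resub
    assert wins >= 12 * 0.95 - 1e-9  # optimism direction


def test_overfit_knee_constructed_traces():
    strictly_improving = {1: 0.40, 2: 0.30, 3: 0.20, 4: 0.10}
    assert overfit_knee(strictly_improving, tol=0.005) == 4
    flat_after_4 = {1: 0.40, 2: 0.34, 3: 0.30, 4: 0.28, 5: 0.279, 6: 0.2785}
    assert overfit_knee(flat_after_4, tol=0.005) == 4
    rising_after_3 = {1: 0.60, 2: 0.45, 3: 0.30, 4: 0.35, 5: 0.40}
    assert overfit_knee(rising_after_3, tol=0.005) == 3


# ---------------------------------------------------------------------------
# Randomization and Y-scrambling


def test_randomization_probability_small_for_perfect_model():
    rng = np.random.default_rng(17)
    X = pd.DataFrame(rng.standard_normal((40, 6)), columns=[f"D{i}" for i in range(6)])
    y = np.where(X["D2"] > 0, "A", "I")  # perfectly separable on one descriptor
    res = randomization_probability(
        X, y, "lda", subset_size=1, runs=20, seed=0, beam=6
    )
    assert res.empirical_fraction == 0.0


def test_randomization_modes_respect_descriptor_nature():
    rng = np.random.default_rng(18)
    X = pd.DataFrame(
        {
            "bin": rng.choice([0.0, 1.0], size=30, p=[0.7, 0.3]),
            "int": rng.integers(0, 9, size=30).astype(float),
            "cont": rng.standard_normal(30),
        }
    )
    from ttrqsar.model_build import _randomize_columns

    xr = _randomize_columns(X, "nature", np.random.default_rng(0))
    assert set(np.unique(xr["bin"])) <= {0.0, 1.0}
    assert np.allclose(xr["int"], np.round(xr["int"]))
    assert not np.allclose(xr["cont"], np.round(xr["cont"]))


def test_y_scramble_null_expectation_and_saturated_warning():
    rng = np.random.default_rng(19)
    n, p = 63, 3
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=list("abc"))
    y = rng.standard_normal(n)
    r2_ys = y_scramble(X, y, list("abc"), iters=50, seed=0)
    # null expectation of R^2 is p/(n-1)
    assert r2_ys == pytest.approx(p / (n - 1), abs=0.04)


def test_y_scramble_much_below_r2_for_strong_signal():
    X, y, _, _ = gen_regression_dataset(n=63, seed=20)
    model = fit_ols(X, y)
    r2 = r_squared(y, model.predict(X))
    r2_ys = y_scramble(X, y, list(X.columns), iters=50, seed=0)
    assert r2 > 0.7 and r2_ys < 0.2


# ---------------------------------------------------------------------------
# Metrics


def test_classification_metrics_hand_arithmetic():
    truth = ["A"] * 10 + ["I"] * 10
    pred = ["A"] * 9 + ["I"] + ["A"] * 2 + ["I"] * 8
    m = classification_metrics(truth, pred)
    assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 2, 8)
    assert m.sn == pytest.approx(0.9)
    assert m.sp == pytest.approx(0.8)
    assert m.acc == pytest.approx(0.85)
    assert m.precision == pytest.approx(9 / 11)
    assert m.acc + m.mr == pytest.approx(1.0)


def test_all_correct_metrics():
    truth = ["A", "I", "A", "I"]
    scores = [0.9, 0.1, 0.8, 0.2]
    m = classification_metrics(truth, truth, scores)
    assert (m.acc, m.mr, m.auc) == (1.0, 0.0, 1.0)


def test_auc_matches_sklearn_with_ties():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(21)
    truth = np.where(rng.random(60) < 0.5, "A", "I")
    scores = np.round(rng.random(60), 1)  # coarse scores force ties
    ours = auc_mann_whitney(truth, scores)
    sk = roc_auc_score((truth == "A").astype(int), scores)
    assert ours == pytest.approx(sk, abs=1e-12)


def test_single_class_truth_reports_nan_not_crash():
    m = classification_metrics(["A", "A"], ["A", "I"])
    assert np.isnan(m.sp)


def test_q2_f3_hand_fixture():
    y_train = np.array([0.0, 1.0, 2.0, 3.0])
    y_test = np.array([1.0, 2.0])
    yhat = np.full(2, y_train.mean())  # predict the training mean
    expected = 1.0 - (np.mean((y_test - 1.5) ** 2)) / (np.sum((y_train - 1.5) ** 2) / 4)
    assert q2_f3(y_train, y_test, yhat) == pytest.approx(expected)


def test_q2_loo_noiseless_linear_is_one():
    rng = np.random.default_rng(22)
    X = pd.DataFrame(rng.standard_normal((15, 2)), columns=list("ab"))
    y = 2 * X["a"].to_numpy() - X["b"].to_numpy() + 0.5
    assert q2_loo(X, y) == pytest.approx(1.0)


def test_regression_metrics_perfect_test_predictions():
    X, y, _, _ = gen_regression_dataset(n=30, noise_sd=0.0, seed=23)
    model = fit_ols(X, y)
    m = regression_metrics(X, y, model, X, y)
    assert m.q2_f3 == pytest.approx(1.0)
    assert m.mae_test == pytest.approx(0.0, abs=1e-10)


def test_q2_loo_tracks_r2_on_modelled_dataset_geometry():
    """n = 43, p = 3, noise tuned for R^2 near 0.8: Q2_LOO within 0.1 of R^2
    in >= 90% of replicates."""
    good = 0
    for s in range(20):
        X, y, _, _ = gen_regression_dataset(n=43, seed=400 + s)
        model = fit_ols(X, y)
        r2 = r_squared(y, model.predict(X))
        q2 = q2_loo(X, y)
        good += abs(r2 - q2) <= 0.1
    assert good / 20 >= 0.9
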