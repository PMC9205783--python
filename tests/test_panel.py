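"""mRMR ranking, stratified CV, logistic panel models and metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from aldpanel.panel import (
    PanelModel,
    classification_metrics,
    classify,
    cv_evaluate,
    evaluate_panel_sizes,
    final_fit,
    fit_logistic,
    mann_whitney_auc,
    missingness_strata,
    mrmr_rank,
    predict_risk,
    repeated_cv_splits,
    select_panel_size,
)


def _X(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"F{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols,
                        index=[f"S{i}" for i in range(arr.shape[0])])


# -- strata and splits -------------------------------------------------------


def test_missingness_pattern_keys():
    meta = pd.DataFrame(
        {"a": [1.0, 1.0, np.nan, 1.0], "b": [np.nan, np.nan, 1.0, np.nan]},
        index=list("wxyz"),
    )
    s = missingness_strata(meta, ["a", "b"], min_stratum_size=1)
    assert s["w"] == s["x"] == s["z"]
    assert s["y"] != s["w"]


def test_all_present_single_stratum():
    meta = pd.DataFrame({"a": [1.0] * 6, "b": [2.0] * 6},
                        index=[f"s{i}" for i in range(6)])
    assert missingness_strata(meta, ["a", "b"], 5).nunique() == 1


def test_rare_pattern_pooled():
    meta = pd.DataFrame(
        {"a": [1.0] * 10 + [np.nan] * 2}, index=[f"s{i}" for i in range(12)]
    )
    s = missingness_strata(meta, ["a"], min_stratum_size=5)
    assert (s.iloc[10:] == "rare").all()


def test_empty_vars_single_stratum_with_warning():
    meta = pd.DataFrame({"a": [1.0, 2.0]}, index=["s0", "s1"])
    with pytest.warns(UserWarning):
        s = missingness_strata(meta, [])
    assert s.nunique() == 1


def test_splits_partition_each_repeat(rng):
    y = rng.integers(0, 2, 60)
    splits = repeated_cv_splits(y, folds=5, repeats=10, seed=4)
    assert len(splits) == 50
    for r in range(10):
        tests = [set(splits[5 * r + f][1]) for f in range(5)]
        assert set().union(*tests) == set(range(60))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]
        for train, test in splits[5 * r: 5 * r + 5]:
            assert not set(train) & set(test)


def test_splits_stratify_class_proportions(rng):
    y = np.array([1] * 20 + [0] * 40)
    splits = repeated_cv_splits(y, folds=5, repeats=3, seed=1)
    for _, test in splits:
        # global case fraction 1/3; folds of 12 → 4 cases ± 1
        assert abs(y[test].sum() - len(test) / 3) <= 1


def test_splits_deterministic_and_seed_sensitive(rng):
    y = rng.integers(0, 2, 40)
    a = repeated_cv_splits(y, folds=5, repeats=2, seed=9)
    b = repeated_cv_splits(y, folds=5, repeats=2, seed=9)
    c = repeated_cv_splits(y, folds=5, repeats=2, seed=10)
    assert all((x[0] == y_[0]).all() and (x[1] == y_[1]).all()
               for x, y_ in zip(a, b))
    assert any(not np.array_equal(x[1], z[1]) for x, z in zip(a, c))


def test_small_class_rejected():
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="class"):
        repeated_cv_splits(y, folds=5, repeats=1, seed=0)


# -- mRMR --------------------------------------------------------------------


def _f_stat(x, y):
    g0, g1 = x[y == 0], x[y == 1]
    grand = x.mean()
    ssb = len(g0) * (g0.mean() - grand) ** 2 + len(g1) * (g1.mean() - grand) ** 2
    ssw = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
    return (ssb / 1) / (ssw / (len(x) - 2))


def _brute_force_mrmr(X, y, k):
    feats = list(X.columns)
    rel = {f: _f_stat(X[f].to_numpy(), y) for f in feats}
    selected = []
    while len(selected) < k:
        remaining = [f for f in feats if f not in selected]
        scores = {}
        for f in remaining:
            if not selected:
                scores[f] = rel[f]
            else:
                red = np.mean([
                    abs(np.corrcoef(X[f], X[s])[0, 1]) for s in selected
                ])
                scores[f] = rel[f] / max(red, 0.001)
        best = sorted(remaining, key=lambda f: (-scores[f], f))[0]
        selected.append(best)
    return selected


def test_mrmr_first_pick_is_max_f(rng):
    y = rng.integers(0, 2, 100)
    X = _X(rng.normal(0, 1, (100, 6)))
    X["F2"] += 2.0 * y
    assert mrmr_rank(X, y, k_max=1) == ["F2"]


def test_mrmr_matches_brute_force_greedy(rng):
    """Full 5-feature ranking equals an exhaustive evaluation of the greedy
    criterion."""
    for seed in range(3):
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, 60)
        X = _X(r.normal(0, 1, (60, 5)))
        X["F0"] += 1.0 * y
        X["F3"] += 0.5 * y
        assert mrmr_rank(X, y, k_max=5) == _brute_force_mrmr(X, y, 5)


def test_mrmr_penalizes_duplicate_feature(rng):
    """A verbatim copy of the best feature is not ranked directly after it
    while an informative alternative exists."""
    y = np.concatenate([np.zeros(30, int), np.ones(30, int)])
    r = np.random.default_rng(5)
    # "best" has top relevance; "other" is informative but constructed to be
    # nearly uncorrelated with it (the label-induced covariance is cancelled
    # through the shared noise term), so relevance/redundancy favors it over
    # the verbatim copy, whose redundancy is exactly 1
    eps = r.normal(0, 1, 60)
    best = eps + 2.5 * y
    other = -0.9375 * eps + 1.5 * y + 0.3 * r.normal(0, 1, 60)
    noise = r.normal(0, 1, 60)
    X = _X(np.column_stack([best, best.copy(), other, noise]),
           cols=["best", "copy", "other", "noise"])
    order = mrmr_rank(X, y, k_max=4)
    assert order[0] == "best"
    assert order[1] != "copy"


def test_mrmr_constant_feature_never_precedes_informative(rng):
    y = rng.integers(0, 2, 50)
    X = _X(np.column_stack([np.ones(50), rng.normal(0, 1, 50) + y]),
           cols=["const", "inf"])
    assert mrmr_rank(X, y, 2) == ["inf", "const"]


# -- logistic ----------------------------------------------------------------


def test_logistic_null_labels_shrink_coefficients(rng):
    X = _X(rng.normal(0, 1, (2000, 3)))
    y = rng.random(2000) < 0.25
    model = fit_logistic(X, y.astype(int))
    assert np.abs(model.coefficients).max() < 0.1
    assert model.intercept == pytest.approx(np.log(0.25 / 0.75), abs=0.15)


def test_logistic_separated_data_stays_finite():
    X = _X(np.linspace(-1, 1, 20)[:, None], cols=["f"])
    y = (X["f"] > 0).astype(int).to_numpy()
    model = fit_logistic(X, y)
    assert np.isfinite(model.coefficients).all()
    assert np.abs(model.coefficients[0]) < 50


def test_logistic_matches_generic_optimizer(rng):
    """Coefficients agree with a direct optimization of the penalized
    log-likelihood on a 30×3 fixture."""
    X = _X(rng.normal(0, 1, (30, 3)))
    beta_true = np.array([1.0, -0.5, 0.2])
    y = (rng.random(30) < expit(X.to_numpy() @ beta_true)).astype(int)
    C = 1.0
    model = fit_logistic(X, y, l2_strength=C)

    Z = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)

    def objective(w):
        b, beta = w[0], w[1:]
        eta = b + Z @ beta
        nll = np.sum(np.logaddexp(0, eta) - y * eta)
        return nll + (beta @ beta) / (2 * C)

    ref = minimize(objective, np.zeros(4), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    assert model.intercept == pytest.approx(ref.x[0], abs=1e-4)
    assert np.allclose(model.coefficients, ref.x[1:], atol=1e-4)


def test_predict_boundary_and_closed_form():
    model = PanelModel("F2", ["a"], intercept=np.log(1 / 3),
                       coefficients=[0.0], scaler_mean=np.zeros(1),
                       scaler_scale=np.ones(1))
    X = _X([[5.0], [7.0]], cols=["a"])
    assert np.allclose(predict_risk(model, X), 0.25)
    model2 = PanelModel("F2", ["a"], 0.0, [0.0], np.zeros(1), np.ones(1))
    assert (classify(model2, X) == 1).all()  # p=0.5 → case at ≥ cutoff


def test_predict_missing_panel_protein_named():
    model = PanelModel("F2", ["missing_prot"], 0.0, [1.0],
                       np.zeros(1), np.ones(1))
    with pytest.raises(KeyError, match="missing_prot"):
        predict_risk(model, _X([[1.0]], cols=["a"]))


def test_risk_monotone_in_positive_feature(rng):
    model = PanelModel("F2", ["a", "b"], -0.3, [1.2, -0.7],
                       scaler_mean=np.array([20.0, 20.0]),
                       scaler_scale=np.array([2.0, 2.0]))
    base = _X([[20.0, 20.0]], cols=["a", "b"])
    up = _X([[23.0, 20.0]], cols=["a", "b"])
    assert predict_risk(model, up).iloc[0] > predict_risk(model, base).iloc[0]


def test_model_json_round_trip(tmp_path, rng):
    X = _X(rng.normal(20, 2, (40, 2)))
    y = rng.integers(0, 2, 40)
    m = fit_logistic(X, y, endpoint="F2", fingerprint="seed=0")
    m.to_json(tmp_path / "m.json")
    back = PanelModel.from_json(tmp_path / "m.json")
    probs1 = predict_risk(m, X)
    probs2 = predict_risk(back, X)
    assert np.allclose(probs1, probs2)


# -- metrics -----------------------------------------------------------------


def test_perfect_predictions_all_ones():
    y = np.array([0, 1, 0, 1])
    m = classification_metrics(y, y, y.astype(float))
    assert all(m[k] == 1.0 for k in
               ("precision", "recall", "f1", "balanced_accuracy", "roc_auc"))


def test_constant_probability_auc_half(rng):
    y = rng.integers(0, 2, 30)
    assert mann_whitney_auc(y, np.full(30, 0.7)) == 0.5


def test_auc_matches_pair_counting():
    y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
    p = np.array([0.9, 0.6, 0.6, 0.6, 0.2, 0.1, 0.8, 0.3])
    wins = ties = 0
    for pi in p[y == 1]:
        for pj in p[y == 0]:
            wins += pi > pj
            ties += pi == pj
    expected = (wins + 0.5 * ties) / (4 * 4)
    assert mann_whitney_auc(y, p) == pytest.approx(expected)


def test_single_class_auc_missing():
    m = classification_metrics(np.ones(5, int), np.ones(5, int), np.ones(5))
    assert np.isnan(m["roc_auc"])
    assert m["recall"] == 1.0


# -- panel-size evaluation / final fit ---------------------------------------


def test_select_panel_size_rules():
    assert select_panel_size(pd.Series([0.7, 0.9, 0.9], index=[1, 2, 3])) == 2
    assert select_panel_size(pd.Series([0.5, 0.6, 0.7], index=[1, 2, 3])) == 3
    assert select_panel_size(pd.Series([0.8, 0.8], index=[1, 2])) == 1


def test_panel_curve_record_counts_and_plateau(rng):
    """One informative feature: per-k record count is folds×repeats and mean
    F1 does not improve materially past k=1."""
    n = 120
    y = rng.integers(0, 2, n)
    X = _X(rng.normal(0, 1, (n, 6)))
    X["F0"] += 3.0 * y
    curve = evaluate_panel_sizes(X, y, k_max=4, folds=5, repeats=3, seed=0)
    rec = curve.attrs["records"]
    assert (rec.groupby("k").size() == 15).all()
    assert curve.loc[2:, "mean_f1"].max() <= curve.loc[1, "mean_f1"] + 0.03


def test_evaluate_panel_sizes_deterministic(rng):
    y = rng.integers(0, 2, 60)
    X = _X(rng.normal(0, 1, (60, 5)))
    a = evaluate_panel_sizes(X, y, k_max=3, folds=5, repeats=2, seed=3)
    b = evaluate_panel_sizes(X, y, k_max=3, folds=5, repeats=2, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_final_fit_split_disjoint_and_frozen(rng):
    n = 100
    y = rng.integers(0, 2, n)
    X = _X(rng.normal(0, 1, (n, 8)))
    X["F1"] += 3.0 * y
    model, metrics = final_fit(X, y, k_star=2, seed=1, endpoint="F2")
    assert metrics["n_train"] + metrics["n_test"] == n
    p1 = predict_risk(model, X)
    p2 = predict_risk(model, X)
    assert np.array_equal(p1.to_numpy(), p2.to_numpy())
    assert metrics["roc_auc"] > 0.8


def test_cv_aggregate_mean_between_extremes(rng):
    y = rng.integers(0, 2, 80)
    X = _X(rng.normal(0, 1, (80, 5)))
    X["F0"] += 1.5 * y
    report = cv_evaluate(X, y, k=2, folds=5, repeats=2, seed=2)
    mean_auc = report.aggregate.loc["roc_auc", "mean"]
    assert report.records["roc_auc"].min() <= mean_auc
    assert mean_auc <= report.records["roc_auc"].max()
    lo, hi = report.aggregate.loc["roc_auc", ["ci_lo", "ci_hi"]]
    assert lo <= mean_auc <= hi
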