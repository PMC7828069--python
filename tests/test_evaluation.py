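"""CV bookkeeping, metric suites, and permutation importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from marbliq.dataset import PREDICTOR_COLUMNS
from marbliq.evaluation import (
    classification_report,
    cross_validate,
    lda_spec,
    make_cv_scheme,
    mlr_spec,
    regression_report,
    svr_spec,
    variable_importance,
)
from marbliq.synthetic import TableGroundTruth, generate_feature_table


# ---------------------------------------------------------------------------
# CV scheme
# ---------------------------------------------------------------------------

def test_scheme_yields_35_splits_for_7x5():
    scheme = make_cv_scheme(39, k=7, repeats=5, seed=0)
    splits = list(scheme.iter_splits())
    assert scheme.n_splits == 35
    assert len(splits) == 35


def test_folds_partition_every_repeat():
    scheme = make_cv_scheme(39, k=7, repeats=5, seed=1)
    for r in range(scheme.repeats):
        folds = scheme.assignments[r]
        sizes = np.bincount(folds, minlength=scheme.k)
        assert sizes.sum() == 39
        assert sizes.max() - sizes.min() <= 1
        covered = np.concatenate(
            [val for rr, f, tr, val in scheme.iter_splits() if rr == r]
        )
        assert sorted(covered) == list(range(39))


def test_scheme_deterministic_and_seed_sensitive():
    a = make_cv_scheme(30, seed=5)
    b = make_cv_scheme(30, seed=5)
    c = make_cv_scheme(30, seed=6)
    assert np.array_equal(a.assignments, b.assignments)
    assert not np.array_equal(a.assignments, c.assignments)


def test_stratified_folds_balance_groups():
    strata = np.array(["G1"] * 19 + ["G2"] * 8 + ["G3"] * 12)
    scheme = make_cv_scheme(39, k=7, repeats=5, seed=2, strata=strata)
    for r in range(scheme.repeats):
        for f in range(scheme.k):
            val = strata[scheme.assignments[r] == f]
            # every fold sees at least one member of the two larger groups
            assert np.sum(val == "G1") >= 2
            assert np.sum(val == "G3") >= 1


def test_k_larger_than_n_errors():
    with pytest.raises(ValueError):
        make_cv_scheme(5, k=7)


def test_loo_reduction():
    scheme = make_cv_scheme(12, k=12, repeats=1, seed=0)
    splits = list(scheme.iter_splits())
    assert len(splits) == 12
    assert all(len(val) == 1 for _, _, _, val in splits)


# ---------------------------------------------------------------------------
# cross_validate
# ---------------------------------------------------------------------------

def _separable_class_table(n_per=14, seed=0):
    r = np.random.default_rng(seed)
    frames = []
    for i, g in enumerate(["G1", "G2", "G3"]):
        base = generate_feature_table(n_per, seed=seed + i)
        base["BFT"] = r.normal(10 * i, 0.3, size=n_per)  # separable marker
        base["IMF%"] = [0.85, 1.38, 1.79][i]
        frames.append(base)
    tab = pd.concat(frames, ignore_index=True)
    tab["group"] = ["G1"] * n_per + ["G2"] * n_per + ["G3"] * n_per
    return tab


def test_cv_perfect_on_separable_classes():
    tab = _separable_class_table()
    scheme = make_cv_scheme(len(tab), seed=0, strata=tab["group"].to_numpy())
    res = cross_validate(lda_spec(), tab, scheme, target="group")
    assert res.mean["accuracy"] == 1.0
    assert res.n_degenerate == 0


def test_cv_noiseless_linear_regression_is_exact():
    tab = generate_feature_table(40, seed=2, link=TableGroundTruth(noise_sd=0.0))
    # drop the interaction so the response is exactly affine in the predictors
    link = TableGroundTruth(link_params={"b0": 0.5, "b1": 0.2, "b2": 0.1, "b3": 0.0},
                            noise_sd=0.0)
    tab["IMF%"] = link.evaluate(tab["BFT"], tab["CW"], tab["Marb_area%"])
    scheme = make_cv_scheme(len(tab), seed=2)
    res = cross_validate(mlr_spec(), tab, scheme)
    assert res.mean["r2"] == pytest.approx(1.0, abs=1e-9)
    assert res.mean["rmse"] == pytest.approx(0.0, abs=1e-9)


def test_cv_mean_sd_match_hand_aggregation():
    tab = generate_feature_table(39, seed=3)
    scheme = make_cv_scheme(len(tab), seed=3)
    res = cross_validate(svr_spec(), tab, scheme)
    vals = [s.metrics["rmse"] for s in res.splits]
    assert len(vals) == 35
    assert res.mean["rmse"] == pytest.approx(np.mean(vals))
    assert res.sd["rmse"] == pytest.approx(np.std(vals, ddof=1))


def test_cv_scheme_size_mismatch_errors():
    tab = generate_feature_table(20, seed=0)
    with pytest.raises(ValueError):
        cross_validate(mlr_spec(), tab, make_cv_scheme(25, seed=0))


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

def _worked_example_labels():
    """19/8/12 group sizes with exactly two G3 samples mistaken for G2."""
    truth = ["G1"] * 19 + ["G2"] * 8 + ["G3"] * 12
    predicted = list(truth)
    predicted[-2:] = ["G2", "G2"]
    return truth, predicted


def test_worked_example_metric_suite():
    truth, predicted = _worked_example_labels()
    rep = classification_report(truth, predicted)
    assert rep.accuracy == pytest.approx(37 / 39)
    assert rep.sensitivity["G3"] == pytest.approx(10 / 12)
    assert rep.specificity["G2"] == pytest.approx(29 / 31)
    assert rep.sensitivity["G1"] == 1.0 and rep.specificity["G1"] == 1.0
    assert rep.balanced_accuracy["G1"] == 1.0
    assert rep.balanced_accuracy["G2"] == pytest.approx((1 + 29 / 31) / 2)
    assert rep.balanced_accuracy["G3"] == pytest.approx((10 / 12 + 1) / 2)
    assert rep.p_value < 0.001


def test_perfect_accuracy_exact_ci():
    truth = ["G1"] * 19 + ["G2"] * 8 + ["G3"] * 12
    rep = classification_report(truth, truth)
    assert rep.accuracy == 1.0
    assert rep.ci_accuracy[0] == pytest.approx(0.025 ** (1 / 39))
    assert round(rep.ci_accuracy[0], 2) == 0.91
    assert rep.ci_accuracy[1] == 1.0


def test_report_invariant_under_relabeling():
    truth, predicted = _worked_example_labels()
    mapping = {"G1": "x", "G2": "y", "G3": "z"}
    rep1 = classification_report(truth, predicted)
    rep2 = classification_report(
        [mapping[t] for t in truth], [mapping[p] for p in predicted]
    )
    for old, new in mapping.items():
        assert rep1.sensitivity[old] == rep2.sensitivity[new]
        assert rep1.balanced_accuracy[old] == rep2.balanced_accuracy[new]
    assert rep1.accuracy == rep2.accuracy


def test_ci_width_shrinks_with_n():
    rep_small = classification_report(
        ["a"] * 8 + ["b"] * 2, ["a"] * 8 + ["b"] * 2
    )
    rep_large = classification_report(
        ["a"] * 80 + ["b"] * 20, ["a"] * 80 + ["b"] * 20
    )
    w_small = rep_small.ci_accuracy[1] - rep_small.ci_accuracy[0]
    w_large = rep_large.ci_accuracy[1] - rep_large.ci_accuracy[0]
    assert w_large < w_small
    assert rep_small.ci_accuracy[0] <= rep_small.accuracy <= rep_small.ci_accuracy[1]


def test_single_class_predictions_handled():
    truth = ["a"] * 6 + ["b"] * 4
    predicted = ["a"] * 10
    rep = classification_report(truth, predicted)
    assert rep.sensitivity["a"] == 1.0
    assert rep.specificity["a"] == 0.0
    assert rep.sensitivity["b"] == 0.0


def test_length_mismatch_errors():
    with pytest.raises(ValueError):
        classification_report(["a", "b"], ["a"])


# ---------------------------------------------------------------------------
# regression report
# ---------------------------------------------------------------------------

def test_identity_prediction_is_perfect(rng):
    obs = rng.uniform(0.6, 2.0, size=20)
    rep = regression_report(obs, obs)
    assert rep.slope == pytest.approx(1.0)
    assert rep.intercept == pytest.approx(0.0, abs=1e-12)
    assert rep.r2 == pytest.approx(1.0)
    assert rep.rmse == pytest.approx(0.0, abs=1e-12)
    assert rep.rse == pytest.approx(0.0, abs=1e-12)


def test_constant_offset_prediction(rng):
    obs = rng.uniform(0.6, 2.0, size=20)
    rep = regression_report(obs, obs + 0.3)
    assert rep.slope == pytest.approx(1.0)
    assert rep.intercept == pytest.approx(0.3)
    assert rep.rmse == pytest.approx(0.3)
    assert rep.rse == pytest.approx(0.0, abs=1e-9)


def test_six_point_fit_matches_t_quantile_oracle():
    obs = np.array([1.0, 1.2, 1.4, 1.6, 1.8, 2.0])
    pred = np.array([1.05, 1.18, 1.45, 1.52, 1.85, 1.98])
    rep = regression_report(obs, pred)
    # independent oracle: normal equations + t quantiles
    design = np.column_stack([np.ones(6), obs])
    beta = np.linalg.solve(design.T @ design, design.T @ pred)
    resid = pred - design @ beta
    rse = np.sqrt(resid @ resid / 4)
    se = rse * np.sqrt(np.diag(np.linalg.inv(design.T @ design)))
    tcrit = stats.t.ppf(0.975, 4)
    assert rep.slope == pytest.approx(beta[1])
    assert rep.intercept == pytest.approx(beta[0])
    assert rep.ci_slope[0] == pytest.approx(beta[1] - tcrit * se[1])
    assert rep.ci_slope[1] == pytest.approx(beta[1] + tcrit * se[1])
    assert rep.ci_intercept[0] == pytest.approx(beta[0] - tcrit * se[0])
    assert rep.rse == pytest.approx(rse)


def test_nonsignificant_intercept_triggers_origin_refit(rng):
    obs = rng.uniform(0.6, 2.0, size=30)
    pred = obs + rng.normal(0, 0.05, size=30)
    rep = regression_report(obs, pred)
    if rep.intercept_p_value > 0.05:
        assert rep.origin_fit is not None
        b0 = float(obs @ pred / (obs @ obs))
        assert rep.origin_fit["Slope"] == pytest.approx(b0)
    rep2 = regression_report(obs, obs + 0.5)  # intercept clearly significant
    assert rep2.origin_fit is None


def test_regression_report_validation():
    with pytest.raises(ValueError):
        regression_report([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
    with pytest.raises(ValueError):
        regression_report([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

def test_importance_null_predictor_near_zero_and_bft_first():
    tab = generate_feature_table(60, seed=9, link=TableGroundTruth(noise_sd=0.0))
    from marbliq.dataset import scale_center
    from marbliq.models import fit_svr_poly, predict_svr_poly

    fm = scale_center(tab)
    model = fit_svr_poly(fm.values, tab["IMF%"].to_numpy())
    predict_fn = lambda frame: predict_svr_poly(model, fm.transform(frame))
    imp = variable_importance(
        predict_fn, tab.loc[:, list(PREDICTOR_COLUMNS)], tab["IMF%"].to_numpy(),
        metric="r2", n_permutations=20, seed=0,
    )
    assert imp.loc[0, "predictor"] == "BFT"
    # L* never enters the generating link: the kernel model's residual
    # reliance on it is negligible next to the dominant predictor
    null_imp = imp.set_index("predictor").loc["L*", "importance"]
    bft_imp = imp.set_index("predictor").loc["BFT", "importance"]
    assert abs(null_imp) < 0.02
    assert abs(null_imp) < 0.05 * bft_imp


def test_duplicated_predictor_shares_importance(rng):
    # a kernel model spreads the signal over duplicate copies, so permuting
    # one copy hurts less than permuting the lone original
    from marbliq.models import fit_svr_poly, predict_svr_poly

    n = 80
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 2 * x + 0.1 * rng.normal(size=n)
    base = pd.DataFrame({"x": x, "z": z})
    dup = pd.DataFrame({"x1": x, "x2": x, "z": z})
    m_base = fit_svr_poly(base.to_numpy(), y, degree=1, scale=1.0, cost=10.0)
    m_dup = fit_svr_poly(dup.to_numpy(), y, degree=1, scale=1.0, cost=10.0)
    imp_base = variable_importance(
        lambda f: predict_svr_poly(m_base, f.to_numpy()), base, y, metric="r2", seed=1
    )
    imp_dup = variable_importance(
        lambda f: predict_svr_poly(m_dup, f.to_numpy()), dup, y, metric="r2", seed=1
    )
    x_base = imp_base.set_index("predictor").loc["x", "importance"]
    x1 = imp_dup.set_index("predictor").loc["x1", "importance"]
    x2 = imp_dup.set_index("predictor").loc["x2", "importance"]
    # the two copies split the signal: each matters less than the lone copy
    assert x1 < x_base and x2 < x_base
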