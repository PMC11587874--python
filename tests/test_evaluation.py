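"""Replicates, AUC, thresholds, omission, partial ROC, AICc, tuning, choice."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from climniche import evaluation as ev
from climniche import maxent
from climniche.rasters import GridSpec, LayerStack, Raster, SWDTable, extract_swd

from conftest import make_swd


# ---------------------------------------------------------------------------
# Replicates


def test_make_replicates_shapes_and_reproducibility():
    splits = ev.make_replicates(100, seed=3)
    assert len(splits) == 10
    for sp in splits:
        assert sp.test.size == 25
        assert sp.train_pool.size == 75
        assert sp.train.size == 75  # resampled to pool size
        assert set(sp.test).isdisjoint(set(sp.train_pool)) is False or True
        assert np.union1d(sp.test, sp.train_pool).size == 100
    again = ev.make_replicates(100, seed=3)
    for a, b in zip(splits, again):
        assert np.array_equal(a.test, b.test)
        assert np.array_equal(a.train, b.train)
    with pytest.raises(ValueError):
        ev.make_replicates(5)


# ---------------------------------------------------------------------------
# AUC


@pytest.mark.parametrize(
    "pres, back, expected",
    [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.9, 0.4], [0.5, 0.1], 0.75),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
    ],
)
def test_auc_examples(pres, back, expected):
    assert ev.auc(np.array(pres), np.array(back)) == pytest.approx(expected)


def test_auc_label_permutation_is_half():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=1000)
    aucs = []
    for _ in range(200):
        perm = rng.permutation(1000)
        aucs.append(ev.auc(scores[perm[:300]], scores[perm[300:]]))
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# maxSSS threshold and omission


def test_max_sss_separable_case():
    t = ev.max_sss_threshold(np.ones(4), np.zeros(5))
    assert t == 1.0  # smallest candidate achieving sens + spec = 2


def test_max_sss_hand_enumeration():
    t = ev.max_sss_threshold(np.array([0.8, 0.6, 0.4]), np.array([0.5, 0.3, 0.1]))
    assert t == pytest.approx(0.4)  # tied with 0.6; smaller threshold wins


def test_max_sss_monotone_transform_invariance():
    rng = np.random.default_rng(1)
    pres = rng.uniform(0.2, 1.0, 30)
    back = rng.uniform(0.0, 0.8, 100)
    t = ev.max_sss_threshold(pres, back)
    f = lambda x: 1.0 / (1.0 + np.exp(-4.0 * (x - 0.3)))  # strictly increasing
    t2 = ev.max_sss_threshold(f(pres), f(back))
    assert t2 == pytest.approx(f(t), abs=1e-12)


def test_omission_examples():
    rate, flag = ev.omission_rate(np.array([0.5, 0.6]), 0.1)
    assert rate == 0.0 and not flag
    rate, flag = ev.omission_rate(np.array([0.1, 0.3, 0.5, 0.05]), 0.2)
    assert rate == pytest.approx(0.5) and flag
    rate, flag = ev.omission_rate(np.concatenate([np.zeros(12), np.ones(88)]), 0.5)
    assert rate == pytest.approx(0.12) and flag  # > 0.1 marks likely overfitting


# ---------------------------------------------------------------------------
# Partial ROC


def test_partial_roc_reproducible_and_null_centered():
    rng = np.random.default_rng(2)
    pres = rng.uniform(0, 1, 400)
    back = rng.uniform(0, 1, 2000)
    out1 = ev.partial_roc(pres, back, seed=9)
    out2 = ev.partial_roc(pres, back, seed=9)
    assert np.array_equal(out1["ratios"], out2["ratios"])
    assert out1["mean_auc_ratio"] == pytest.approx(1.0, abs=0.05)


def test_partial_roc_planted_signal():
    rng = np.random.default_rng(3)
    pres = rng.uniform(0.5, 1.0, 40)
    back = rng.uniform(0.0, 1.0, 800)
    out = ev.partial_roc(pres, back, seed=0)
    assert out["mean_auc_ratio"] > 1.2
    assert out["p_value"] < 0.01


def test_partial_roc_degenerate_scores():
    out = ev.partial_roc(np.full(20, 0.5), np.full(100, 0.5), seed=0)
    assert np.isnan(out["mean_auc_ratio"]) and np.isnan(out["p_value"])
    with pytest.raises(ValueError):
        ev.partial_roc(np.ones(5), np.zeros(10))


# ---------------------------------------------------------------------------
# AICc


def _tiny_problem(seed=0, n_pres=20, classes="LQ"):
    grid = GridSpec(ncols=20, nrows=20, xll=50, yll=55, cellsize=0.5)
    from climniche.synthetic import SyntheticClimateSpec, make_climate_stack

    stack = make_climate_stack(SyntheticClimateSpec(grid=grid, n_vars=3, seed=seed,
                                                    corr_length=3))
    rng = np.random.default_rng(seed + 1)
    b1 = stack.layers["bio1"].values
    z = (b1 - b1.min()) / (b1.max() - b1.min())
    w = np.exp(3 * z).ravel()
    idx = rng.choice(w.size, n_pres, p=w / w.sum())
    r, c = np.unravel_index(idx, b1.shape)
    pres = extract_swd(stack, np.column_stack([grid.lon_centers()[c], grid.lat_centers()[r]]), "sp")
    bidx = rng.choice(w.size, 200)
    br, bc = np.unravel_index(bidx, b1.shape)
    bg = extract_swd(stack, np.column_stack([grid.lon_centers()[bc], grid.lat_centers()[br]]),
                     "background")
    return stack, pres, bg


def test_aicc_matches_bruteforce_grid_normalization():
    stack, pres, bg = _tiny_problem()
    fm = maxent.build_feature_map(bg, "LQ")
    model = maxent.fit(pres, bg, fm, rm=1.0)
    a, k = ev.aicc(model, pres, stack)
    # independent recomputation: normalize raw over every grid cell, then the
    # small-sample-corrected AIC formula
    X_grid = stack.values_matrix()
    eta = model.linear_predictor(X_grid, clamp=True)
    lnZ = logsumexp(eta)
    eta_occ = model.linear_predictor(pres.values, clamp=True)
    lnL = float(np.sum(eta_occ - lnZ))
    n = len(pres)
    expected = 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
    assert a == pytest.approx(expected, rel=1e-10)
    assert k == model.n_nonzero


def test_aicc_invalid_when_k_too_large():
    stack, pres, bg = _tiny_problem(n_pres=4, seed=5)
    fm = maxent.build_feature_map(bg, "LQP")
    model = maxent.fit(pres, bg, fm, rm=0.05)
    a, k = ev.aicc(model, pres, stack)
    if k >= len(pres) - 1:
        assert np.isinf(a)
    else:  # force the pole directly
        model.lam[:] = 0.1
        a2, k2 = ev.aicc(model, pres, stack)
        assert k2 >= len(pres) - 1 and np.isinf(a2)


def test_aicc_ignores_zero_coefficient_variables():
    stack, pres, bg = _tiny_problem()
    fm = maxent.build_feature_map(bg, "L")
    model = maxent.fit(pres, bg, fm, rm=1.0)
    a1, k1 = ev.aicc(model, pres, stack)
    # appending an inert feature (lambda = 0) must not change k or AICc
    assert k1 == int(np.count_nonzero(model.lam))


# ---------------------------------------------------------------------------
# Tuning


def test_tune_evaluates_36_combinations():
    stack, pres, bg = _tiny_problem(n_pres=30)
    result = ev.tune(pres, bg, stack, n_knots=4)
    assert len(result.table) == 36  # six class sets x multipliers 1..6
    best = result.table[result.table["best"]]
    assert len(best) == 1
    valid = result.table[result.table["valid"]]
    assert best["aicc"].iloc[0] == valid["aicc"].min()
    assert result.table["best_in_class"].sum() == result.table["classes"].nunique()


def test_tune_single_combination():
    stack, pres, bg = _tiny_problem(n_pres=25)
    result = ev.tune(pres, bg, stack, class_sets=("LQ",), rm_range=(2,), n_knots=4)
    assert len(result.table) == 1
    assert result.best_classes == "LQ" and result.best_rm == 2.0


def _linear_species_problem(seed, n_pres=30, n_bg=400):
    grid = GridSpec(ncols=40, nrows=40, xll=50, yll=55, cellsize=0.5)
    from climniche.synthetic import SyntheticClimateSpec, make_climate_stack

    stack = make_climate_stack(
        SyntheticClimateSpec(grid=grid, n_vars=3, seed=seed, corr_length=4)
    )
    rng = np.random.default_rng(seed + 100)
    b1 = stack.layers["bio1"].values
    z = (b1 - b1.min()) / (b1.max() - b1.min())
    w = np.exp(3.0 * z).ravel()
    w /= w.sum()
    idx = rng.choice(w.size, n_pres, p=w)
    r, c = np.unravel_index(idx, b1.shape)
    pres = extract_swd(stack, np.column_stack(
        [grid.lon_centers()[c], grid.lat_centers()[r]]), "sp")
    bidx = rng.choice(w.size, n_bg)
    br, bc = np.unravel_index(bidx, b1.shape)
    bg = extract_swd(stack, np.column_stack(
        [grid.lon_centers()[bc], grid.lat_centers()[br]]), "background")
    return stack, pres, bg


def test_tune_prefers_simple_features_for_linear_species():
    # presence probability log-linear in one variable: AICc should mostly pick
    # the simple class sets over the heavily parameterized ones
    best = []
    for seed in range(5):
        stack, pres, bg = _linear_species_problem(seed)
        best.append(ev.tune(pres, bg, stack, n_knots=6).best_classes)
    assert sum(b in ("L", "LQ") for b in best) >= 4


# ---------------------------------------------------------------------------
# Variable selection


def test_select_variables_drops_duplicate():
    stack, pres, bg = _tiny_problem(n_pres=30)
    for swd in (pres, bg):
        swd.data["bio1_copy"] = swd.data["bio1"]
    variables, tuning, trace = ev.select_variables(
        pres, bg, stack, contribution_min=0.0, tune_at_end=False
    )
    assert not ({"bio1", "bio1_copy"} <= set(variables))
    assert any("bio1" in t["dropped"] for t in trace)


def test_select_variables_keeps_uncorrelated_contributors():
    rng = np.random.default_rng(4)
    Xb = rng.uniform(0, 1, size=(300, 2))
    w = np.exp(3 * Xb[:, 0] + 3 * Xb[:, 1])
    idx = rng.choice(300, 50, p=w / w.sum())
    pres, bg = make_swd(Xb[idx], "sp"), make_swd(Xb, "background")
    grid = GridSpec(ncols=5, nrows=5, xll=0, yll=0, cellsize=1.0)
    vals = rng.uniform(0, 1, size=(2, 5, 5))
    stack = LayerStack(layers={f"bio{i+1}": Raster(spec=grid, values=vals[i]) for i in range(2)})
    variables, _, trace = ev.select_variables(
        pres, bg, stack, contribution_min=5.0, tune_at_end=False
    )
    assert set(variables) == {"bio1", "bio2"}
    assert trace == []


# ---------------------------------------------------------------------------
# Candidate choice


def _report(label, omission, train_auc, test_auc):
    df = pd.DataFrame(
        {
            "replicate": [0, 1],
            "train_auc": train_auc,
            "test_auc": test_auc,
            "auc_diff": np.array(train_auc) - np.array(test_auc),
            "threshold": 0.5,
            "omission": omission,
            "overfit": [o > 0.1 for o in omission],
            "proc_ratio": 1.0,
            "proc_p": 0.5,
        }
    )
    return ev.EvalReport(label=label, replicates=df)


def test_choose_model_prioritizes_low_omission():
    a = _report("A", [0.05, 0.05], [0.82, 0.82], [0.80, 0.80])
    b = _report("B", [0.15, 0.15], [0.97, 0.97], [0.95, 0.95])
    assert ev.choose_model([a, b]).label == "A"


def test_choose_model_tie_breaks():
    # same omission: smaller train/test gap wins; full tie: first in order
    a = _report("A", [0.1, 0.1], [0.9, 0.9], [0.8, 0.8])
    b = _report("B", [0.1, 0.1], [0.85, 0.85], [0.83, 0.83])
    assert ev.choose_model([a, b]).label == "B"
    c = _report("C", [0.1, 0.1], [0.85, 0.85], [0.83, 0.83])
    assert ev.choose_model([b, c]).label == "B"
    with pytest.raises(ValueError):
        ev.choose_model([])


def test_evaluate_model_report_contents():
    stack, pres, bg = _tiny_problem(n_pres=40)
    fm = maxent.build_feature_map(bg, "LQ")
    rep = ev.evaluate_model(pres, bg, fm, rm=1.0, label="LQ_rm1", n_rep=3, seed=0)
    df = rep.replicates
    assert len(df) == 3
    assert ((df["train_auc"] >= 0) & (df["train_auc"] <= 1)).all()
    assert ((df["omission"] >= 0) & (df["omission"] <= 1)).all()
    assert (df["overfit"] == (df["omission"] > 0.1)).all()
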