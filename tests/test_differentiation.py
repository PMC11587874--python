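"""PCA/broken stick, ANOVA/Tukey, subset selection, logistic discrimination, SHAP."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from climniche import synthetic
from climniche.differentiation import (
    anova_tukey,
    broken_stick,
    classification_metrics,
    DiscriminationModel,
    fit_l2_logistic_cv,
    linear_shap,
    partial_dependence,
    pca,
    retain,
    split_train_test,
    subset_select_condition_vif,
)


def _table(X, groups=None, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"bio{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "species", groups if groups is not None else "sp")
    return df


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_data():
    rng = np.random.default_rng(0)
    t = rng.normal(size=50)
    X = np.column_stack([t, 2 * t, -0.5 * t])
    res = pca(_table(X))
    assert res.proportions[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_orthonormal_loadings_and_eigen_variance():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
    res = pca(_table(X))
    assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)
    score_var = res.scores.var(axis=0, ddof=1)
    assert np.allclose(score_var, res.eigenvalues, atol=1e-8)
    assert res.proportions.sum() == pytest.approx(1.0)


def test_pca_two_uncorrelated_unit_variables():
    rng = np.random.default_rng(2)
    res = pca(_table(rng.normal(size=(2000, 2))))
    assert res.proportions[0] == pytest.approx(0.5, abs=0.05)
    assert res.proportions[1] == pytest.approx(0.5, abs=0.05)


def test_pca_constant_column_error():
    X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
    with pytest.raises(ValueError, match="bio2"):
        pca(_table(X))


def test_pca_sign_convention_and_scale_invariance():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 4))
    r1 = pca(_table(X))
    X2 = X.copy()
    X2[:, 2] *= 1000.0  # rescaling a column must not matter when standardized
    r2 = pca(_table(X2))
    assert np.allclose(r1.proportions, r2.proportions, atol=1e-10)
    assert r1.retained == r2.retained
    for j in range(4):
        i = np.argmax(np.abs(r1.loadings[:, j]))
        assert r1.loadings[i, j] > 0


# ---------------------------------------------------------------------------
# Broken stick


def test_broken_stick_closed_form():
    b = broken_stick(3)
    assert b == pytest.approx([0.611111, 0.277778, 0.111111], abs=1e-6)
    assert broken_stick(10).sum() == pytest.approx(1.0)


@pytest.mark.parametrize(
    "props, expected_k",
    [
        ((0.7, 0.2, 0.1), 1),  # 0.7 > 0.611 but 0.2 < 0.278
        ((0.65, 0.30, 0.05), 2),
        ((0.5, 0.3, 0.2), 0),
        ((0.95, 0.04, 0.01), 1),
    ],
)
def test_retention_rule(props, expected_k):
    assert retain(np.array(props)) == expected_k


# ---------------------------------------------------------------------------
# ANOVA / Tukey


def test_tukey_two_groups_equals_pooled_t_test():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.8, 1, 25)])
    g = np.array(["a"] * 30 + ["b"] * 25)
    _, tukey = anova_tukey(x.reshape(-1, 1), g)
    _, p_t = stats.ttest_ind(x[g == "a"], x[g == "b"], equal_var=True)
    assert tukey["p"].iloc[0] == pytest.approx(p_t, abs=1e-6)


def test_anova_null_on_relabeled_data():
    rng = np.random.default_rng(5)
    x = np.sort(rng.normal(size=60))
    g = np.array(["a", "b", "c"] * 20)  # cyclic labels over sorted data:
    anova, tukey = anova_tukey(x.reshape(-1, 1), g)  # near-identical groups
    assert anova["p"].iloc[0] > 0.5
    assert not tukey["significant"].any()


def test_tukey_detects_planted_shift():
    rng = np.random.default_rng(6)
    x = np.concatenate(
        [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
    )
    g = np.array(["a"] * 50 + ["b"] * 50 + ["c"] * 50)
    _, tukey = anova_tukey(x.reshape(-1, 1), g)
    ac = tukey[(tukey["group1"] == "a") & (tukey["group2"] == "c")]
    ab = tukey[(tukey["group1"] == "a") & (tukey["group2"] == "b")]
    assert bool(ac["significant"].iloc[0])
    assert not bool(ab["significant"].iloc[0])


def test_anova_small_group_error():
    with pytest.raises(ValueError, match="< 2 observations"):
        anova_tukey(np.arange(5.0).reshape(-1, 1), ["a", "a", "a", "a", "b"])


# ---------------------------------------------------------------------------
# Condition-number / VIF subset selection


def brute_force_selection(df, vif_max=10.0):
    """Independent oracle: numpy cond of the standardized matrix + VIF via
    explicit regressions, enumerating every subset."""
    names = [c for c in df.columns if c != "species"]
    X = df[names].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    best = {}
    for s in range(1, len(names) + 1):
        entries = []
        for subset in itertools.combinations(range(len(names)), s):
            kappa = np.linalg.cond(Z[:, subset])
            entries.append((kappa, subset))
        kappa, subset = min(entries, key=lambda e: e[0])
        vifs = []
        for j_pos, j in enumerate(subset):
            others = [k for k in subset if k != j]
            if not others:
                vifs.append(1.0)
                continue
            A = np.column_stack([Z[:, others], np.ones(len(Z))])
            coef, *_ = np.linalg.lstsq(A, Z[:, j], rcond=None)
            resid = Z[:, j] - A @ coef
            r2 = 1 - resid @ resid / (Z[:, j] @ Z[:, j])
            vifs.append(1.0 / max(1e-300, 1 - r2))
        best[s] = (subset, kappa, np.array(vifs))
    final = None
    for s in sorted(best):
        subset, kappa, vifs = best[s]
        if np.isfinite(kappa) and (vifs <= vif_max).all():
            final = subset
    return best, tuple(names[i] for i in final)


def test_orthonormal_columns_keep_everything():
    # sinusoids of distinct frequencies: zero-mean, mutually orthogonal
    t = np.arange(50)
    A = np.column_stack(
        [np.cos(2 * np.pi * t / 50), np.sin(2 * np.pi * t / 50),
         np.cos(4 * np.pi * t / 50), np.sin(4 * np.pi * t / 50)]
    )
    res = subset_select_condition_vif(_table(A))
    assert len(res.final_subset) == 4
    assert all(v == pytest.approx(1.0, abs=1e-6) for v in res.vifs.values())
    full = res.per_size[res.per_size["size"] == 4]
    assert full["condition_number"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_duplicated_column_never_retained():
    rng = np.random.default_rng(8)
    x = rng.normal(size=60)
    X = np.column_stack([x, x, rng.normal(size=60)])
    res = subset_select_condition_vif(_table(X, names=["a", "a_copy", "b"]))
    assert not ({"a", "a_copy"} <= set(res.final_subset))


@pytest.mark.parametrize("p, seed", [(5, 0), (6, 1), (8, 2)])
def test_selection_matches_bruteforce_oracle(p, seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(120, p))
    # plant correlation structure
    base[:, 1] = 0.9 * base[:, 0] + 0.3 * base[:, 1]
    if p >= 6:
        base[:, 5] = 0.95 * base[:, 4] + 0.2 * base[:, 5]
    df = _table(base)
    res = subset_select_condition_vif(df)
    oracle_per_size, oracle_final = brute_force_selection(df)
    assert tuple(res.final_subset) == oracle_final
    names = [c for c in df.columns if c != "species"]
    for s, (subset, kappa, _) in oracle_per_size.items():
        row = res.per_size[res.per_size["size"] == s].iloc[0]
        assert row["subset"] == tuple(names[i] for i in subset)
        if np.isfinite(kappa):
            assert row["condition_number"] == pytest.approx(kappa, rel=1e-6)


# ---------------------------------------------------------------------------
# Split and logistic discrimination


def _pair_data(seed=0, n=150, shift=2.0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0, 1, size=(n, 3))
    Xb = rng.normal(0, 1, size=(n, 3))
    Xb[:, 0] += shift  # bio1 discriminates
    X = np.vstack([Xa, Xb])
    groups = np.array(["A"] * n + ["B"] * n)
    return _table(X, groups=groups)


def test_split_fraction_stratification_reproducibility():
    table = _pair_data(n=50)
    tr, te = split_train_test(table, seed=1)
    assert len(tr) == 80 and len(te) == 20
    assert abs((tr["species"] == "A").sum() - 40) <= 1
    tr2, te2 = split_train_test(table, seed=1)
    pd.testing.assert_frame_equal(tr, tr2)
    with pytest.raises(ValueError):
        split_train_test(table.head(5))


def test_logistic_grid_and_shrinkage():
    table = _pair_data(seed=3)
    tr, te = split_train_test(table, seed=3)
    model = fit_l2_logistic_cv(tr, ["bio1", "bio2", "bio3"], ("A", "B"), seed=3)
    assert len(model.cv_table) == 100
    assert model.cv_table["lambda_pen"].iloc[0] == pytest.approx(0.001)
    assert model.cv_table["lambda_pen"].iloc[-1] == pytest.approx(0.5)
    assert model.coefficients[0] > 0  # B sits at larger bio1
    # ridge shrinkage: the refit coefficient norm is non-increasing in the penalty
    from climniche.differentiation import _sklearn_C
    from sklearn.linear_model import LogisticRegression

    Z = model._standardize(tr)
    y = model.labels(tr)
    norms = []
    for lam in np.linspace(0.001, 0.5, 12):
        clf = LogisticRegression(C=_sklearn_C(lam, len(y)), solver="lbfgs", max_iter=5000)
        clf.fit(Z, y)
        norms.append(np.linalg.norm(clf.coef_))
    assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))


def test_single_class_train_error():
    table = _pair_data(n=20)
    only_a = table[table["species"] == "A"]
    with pytest.raises(ValueError, match="single class"):
        fit_l2_logistic_cv(only_a, ["bio1"], ("A", "B"), seed=0)


def _manual_model(coefs, intercept, variables=("bio1",), pair=("A", "B")):
    k = len(variables)
    return DiscriminationModel(
        pair=pair,
        variables=list(variables),
        train_means=np.zeros(k),
        train_sds=np.ones(k),
        lambda_pen=0.1,
        intercept=intercept,
        coefficients=np.asarray(coefs, dtype=float),
        cv_table=pd.DataFrame(),
    )


def test_metrics_perfect_classifier():
    model = _manual_model([5.0], 0.0)
    test = _table(np.array([[-2.0], [-1.5], [1.5], [2.0]]),
                  groups=["A", "A", "B", "B"], names=["bio1"])
    m = classification_metrics(model, test)
    assert all(v == pytest.approx(1.0) for v in m.values())


def test_metrics_all_positive_predictions():
    # prevalence 0.4, everything predicted positive
    model = _manual_model([0.0], 10.0)
    groups = ["B"] * 4 + ["A"] * 6
    test = _table(np.zeros((10, 1)), groups=groups, names=["bio1"])
    m = classification_metrics(model, test)
    assert m["precision"] == pytest.approx(0.4)
    assert m["recall"] == pytest.approx(1.0)
    assert m["f1"] == pytest.approx(2 * 0.4 / 1.4)


def test_metrics_hand_confusion_matrix():
    # TP=3, FP=1, FN=1, TN=5 -> precision = recall = F1 = 0.75
    model = _manual_model([4.0], 0.0)
    x = np.array([1, 1, 1, -1, 1, -1, -1, -1, -1, -1], dtype=float)[:, None]
    groups = ["B", "B", "B", "B", "A", "A", "A", "A", "A", "A"]
    test = _table(x, groups=groups, names=["bio1"])
    m = classification_metrics(model, test)
    assert m["precision"] == pytest.approx(0.75)
    assert m["recall"] == pytest.approx(0.75)
    assert m["f1"] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# Linear SHAP and partial dependence


def brute_force_shapley(coefs, intercept, z_row, ref):
    """Exhaustive Shapley over all coalitions with a mean-imputation value
    function on the linear-predictor scale."""
    k = len(coefs)
    from math import factorial

    def value(S):
        x = ref.copy()
        for j in S:
            x[j] = z_row[j]
        return float(np.dot(coefs, x) + intercept)

    phi = np.zeros(k)
    for j in range(k):
        others = [i for i in range(k) if i != j]
        for r in range(len(others) + 1):
            for S in itertools.combinations(others, r):
                w = factorial(len(S)) * factorial(k - len(S) - 1) / factorial(k)
                phi[j] += w * (value(S + (j,)) - value(S))
    return phi


def test_linear_shap_local_accuracy_and_oracle():
    model = _manual_model([1.5, -2.0, 0.0], 0.7, variables=["bio1", "bio2", "bio3"])
    rng = np.random.default_rng(9)
    data = _table(rng.normal(size=(15, 3)), groups=["A"] * 15)
    phi, base = linear_shap(model, data)
    eta = model.decision_function(data)
    assert np.allclose(phi.sum(axis=1) + base, eta, atol=1e-12)
    assert (phi["bio3"] == 0).all()  # zero-coefficient variable
    Z = model._standardize(data)
    for i in range(5):
        oracle = brute_force_shapley(model.coefficients, model.intercept,
                                     Z[i], np.zeros(3))
        assert np.allclose(phi.iloc[i].to_numpy(), oracle, atol=1e-10)


def test_partial_dependence_monotone_and_unknown_variable():
    model = _manual_model([2.0], 0.0)
    rng = np.random.default_rng(10)
    data = _table(rng.normal(size=(50, 1)), groups=["A"] * 50, names=["bio1"])
    pd_curve = partial_dependence(model, data, "bio1", n_grid=10)
    assert (np.diff(pd_curve["mean_probability"]) > 0).all()
    with pytest.raises(ValueError, match="unknown"):
        partial_dependence(model, data, "bio99")


# ---------------------------------------------------------------------------
# Planted-signal recovery through the full discrimination path


def test_planted_variable_recovered_and_attributed():
    seeds = (0, 1)
    aucs = []
    for seed in seeds:
        table, truth = synthetic.two_species_scenario(
            spec=synthetic.SyntheticClimateSpec(n_vars=6, seed=seed),
            offset_sd=3.0, n_per_species=200, seed=seed,
        )
        df = table.drop(columns=["lon", "lat"])
        sel = subset_select_condition_vif(df)
        planted = truth["offset_variables"][0]
        assert planted in sel.final_subset
        tr, te = split_train_test(df[["species", *sel.final_subset]], seed=seed)
        model = fit_l2_logistic_cv(tr, sel.final_subset, tuple(truth["species"]), seed=seed)
        aucs.append(classification_metrics(model, te)["roc_auc"])
        phi, _ = linear_shap(model, te)
        # planted variable carries the largest attribution, with the right sign
        assert phi.abs().mean().idxmax() == planted
        mask_b = (te["species"] == truth["positive_species"]).to_numpy()
        assert phi.loc[mask_b, planted].mean() > 0
    assert np.median(aucs) > 0.9


def test_null_pair_auc_near_chance():
    aucs = []
    for seed in (0, 1, 2):
        table, truth = synthetic.two_species_scenario(
            spec=synthetic.SyntheticClimateSpec(n_vars=5, seed=seed),
            offset_sd=0.0, n_per_species=250, seed=seed,
        )
        df = table.drop(columns=["lon", "lat"])
        tr, te = split_train_test(df, seed=seed)
        variables = [c for c in df.columns if c != "species"]
        model = fit_l2_logistic_cv(tr, variables, tuple(truth["species"]), seed=seed)
        aucs.append(classification_metrics(model, te)["roc_auc"])
    assert np.median(aucs) == pytest.approx(0.5, abs=0.05)
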