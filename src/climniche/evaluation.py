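"""Model evaluation and selection for presence-background niche models.

Covers the replicate machinery (bootstrap run type: random test holdout plus
with-replacement resampling of the training pool), threshold-independent
discrimination (rank AUC), the maximum sensitivity-plus-specificity (maxSSS)
threshold, test omission rates with the > 0.1 overfitting flag, the partial
ROC bootstrap significance test, AICc on the renormalized grid distribution,
and the tuning loops over feature-class combinations, regularization
multipliers, and variable subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from . import maxent
from .maxent import FeatureMap, MaxentModel, build_feature_map
from .rasters import LayerStack, SWDTable

logger = logging.getLogger(__name__)

DEFAULT_CLASS_SETS = ("L", "LQ", "LQH", "H", "LQHP", "LQHPT")

__all__ = [
    "ReplicateSplit",
    "EvalReport",
    "TuningResult",
    "make_replicates",
    "auc",
    "max_sss_threshold",
    "omission_rate",
    "partial_roc",
    "aicc",
    "tune",
    "select_variables",
    "evaluate_model",
    "choose_model",
    "DEFAULT_CLASS_SETS",
]


# ---------------------------------------------------------------------------
# Replicates


@dataclass
class ReplicateSplit:
    """One bootstrap replicate: indices into the occurrence table.

    ``test`` is the random holdout (25% by default); ``train_pool`` the
    remaining records; ``train`` a with-replacement resample of the pool to
    its own size.
    """

    index: int
    train_pool: np.ndarray
    train: np.ndarray
    test: np.ndarray
    seed: int


def make_replicates(
    n_records: int, n_rep: int = 10, test_frac: float = 0.25, seed: int = 0
) -> list[ReplicateSplit]:
    """Bootstrap-style replicate splits over ``n_records`` occurrence rows."""
    if n_records < 8:
        raise ValueError("need at least 8 records to form replicates")
    rng = np.random.default_rng(seed)
    n_test = max(1, round(test_frac * n_records))
    splits = []
    for r in range(n_rep):
        perm = rng.permutation(n_records)
        test = np.sort(perm[:n_test])
        pool = np.sort(perm[n_test:])
        train = rng.choice(pool, size=pool.size, replace=True)
        splits.append(ReplicateSplit(index=r, train_pool=pool, train=train, test=test, seed=seed))
    return splits


# ---------------------------------------------------------------------------
# Discrimination metrics


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with midrank tie handling."""
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pres, back]))
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * back.size))


def max_sss_threshold(
    train_presence_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the union of observed presence and background scores;
    sensitivity counts presences >= t, specificity counts background < t.
    Ties break toward the smallest threshold for reproducibility.
    """
    pres = np.sort(np.asarray(train_presence_scores, dtype=float))
    back = np.sort(np.asarray(background_scores, dtype=float))
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([pres, back]))
    sens = 1.0 - np.searchsorted(pres, cand, side="left") / pres.size
    spec = np.searchsorted(back, cand, side="left") / back.size
    total = sens + spec
    # smallest threshold among the (float-tolerant) maximizers
    best = np.where(total >= total.max() - 1e-12)[0][0]
    return float(cand[best])


def omission_rate(test_presence_scores: np.ndarray, t: float) -> tuple[float, bool]:
    """Fraction of test presences scoring below ``t``; flag rates > 0.1.

    Omission above 0.1 is the conventional mark of a likely-overfitted model.
    """
    scores = np.asarray(test_presence_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("test score set must be non-empty")
    rate = float((scores < t).mean())
    return rate, rate > 0.1


# ---------------------------------------------------------------------------
# Partial ROC


def partial_roc(
    test_presence_scores: np.ndarray,
    background_scores: np.ndarray,
    E: float = 0.05,
    iterations: int = 500,
    resample_frac: float = 0.5,
    seed: int = 0,
    replace: bool = False,
) -> dict:
    """Resampled partial-ROC test (AUC-ratio against the chance line).

    The ROC here plots sensitivity (fraction of test presences >= t) against
    the proportion of background scoring >= t. The integration region — the
    thresholds at which the full test set's sensitivity is >= 1 - E (omission
    <= E) — is fixed once from the observed curve; each iteration then
    resamples ``resample_frac`` of the test presences and integrates the
    resampled curve and the chance diagonal over that region. The statistic is
    their ratio; the p-value is the proportion of resampled ratios <= 1.

    Two design choices keep the null p-values approximately uniform: the
    region is a property of the model under test rather than of each resample
    (a per-resample region conditions on the resampled curve being high, which
    biases the ratio upward), and resamples are drawn *without* replacement by
    default (a half-sample without replacement matches the variance of the
    full-sample statistic, whereas a half-size bootstrap with replacement
    doubles it and makes the test conservative). ``replace=True`` switches to
    the bootstrap flavor used by some niche-modeling toolboxes.

    Returns a dict with ``mean_auc_ratio``, ``p_value`` and the per-iteration
    ``ratios`` (NaN if the scores are degenerate).
    """
    pres = np.asarray(test_presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size < 10:
        raise ValueError("partial ROC needs at least 10 test presences")
    if np.unique(np.concatenate([pres, back])).size < 2:
        return {"mean_auc_ratio": float("nan"), "p_value": float("nan"),
                "ratios": np.full(iterations, np.nan), "E": E}

    rng = np.random.default_rng(seed)
    # Thresholds from the background distribution, descending x as t rises.
    thresholds = np.unique(back)
    back_sorted = np.sort(back)
    x = 1.0 - np.searchsorted(back_sorted, thresholds, side="left") / back.size
    # Ascending-x order; append the (x=1, t=-inf) endpoint.
    order = np.argsort(x)
    x = np.concatenate([x[order], [1.0]])
    thr = np.concatenate([thresholds[order], [-np.inf]])

    # Fix the omission <= E region from the full test set's curve.
    pres_sorted = np.sort(pres)
    sens_full = 1.0 - np.searchsorted(pres_sorted, thr, side="left") / pres.size
    keep = sens_full >= 1.0 - E
    if keep.sum() < 2:
        return {"mean_auc_ratio": float("nan"), "p_value": float("nan"),
                "ratios": np.full(iterations, np.nan), "E": E}
    xs, thr_keep = x[keep], thr[keep]
    null_area = np.trapezoid(xs, xs)
    if null_area <= 0:
        return {"mean_auc_ratio": float("nan"), "p_value": float("nan"),
                "ratios": np.full(iterations, np.nan), "E": E}

    n_res = max(1, round(resample_frac * pres.size))
    if replace:
        samples = rng.choice(pres, size=(iterations, n_res), replace=True)
    else:
        samples = np.stack(
            [rng.choice(pres, size=n_res, replace=False) for _ in range(iterations)]
        )
    samples.sort(axis=1)
    ratios = np.empty(iterations)
    for i in range(iterations):
        ys = 1.0 - np.searchsorted(samples[i], thr_keep, side="left") / n_res
        ratios[i] = np.trapezoid(ys, xs) / null_area
    valid = ratios[~np.isnan(ratios)]
    if valid.size == 0:  # pragma: no cover - defensive
        return {"mean_auc_ratio": float("nan"), "p_value": float("nan"),
                "ratios": ratios, "E": E}
    return {
        "mean_auc_ratio": float(valid.mean()),
        "p_value": float((valid <= 1.0).mean()),
        "ratios": ratios,
        "E": E,
    }


# ---------------------------------------------------------------------------
# AICc


def aicc(model: MaxentModel, occurrences: SWDTable, stack: LayerStack) -> tuple[float, int]:
    """Small-sample corrected AIC of a model over the study grid.

    Raw predictions are renormalized to sum 1 over all complete grid cells;
    the log likelihood is the sum of log raw probabilities at the occurrence
    cells; k counts nonzero coefficients. Models with k >= n - 1 are invalid
    (returns (inf, k)) and excluded from tuning comparisons; so are models
    placing an occurrence at zero probability.
    """
    n = len(occurrences)
    k = model.n_nonzero
    if k >= n - 1:
        return float("inf"), k
    mask = np.ones((stack.spec.nrows, stack.spec.ncols), dtype=bool)
    for v in model.variables:
        mask &= stack.layers[v].mask
    X_grid = np.column_stack([stack.layers[v].values[mask] for v in model.variables])
    eta_grid = model.linear_predictor(X_grid, clamp=True)
    logZ_grid = logsumexp(eta_grid)
    X_occ = occurrences.data[model.variables].to_numpy(dtype=float)
    eta_occ = model.linear_predictor(X_occ, clamp=True)
    lnL = float(np.sum(eta_occ - logZ_grid))
    if not np.isfinite(lnL):
        return float("inf"), k
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1), k


# ---------------------------------------------------------------------------
# Tuning over feature classes and multipliers


@dataclass
class TuningResult:
    """AICc per (feature class set, regularization multiplier) combination."""

    table: pd.DataFrame  # columns: classes, rm, k, aicc, valid, best_in_class, best
    best_classes: str
    best_rm: float

    @property
    def best_row(self) -> pd.Series:
        return self.table[self.table["best"]].iloc[0]


def tune(
    presence: SWDTable,
    background: SWDTable,
    stack: LayerStack,
    class_sets: Sequence[str] = DEFAULT_CLASS_SETS,
    rm_range: Sequence[float] = (1, 2, 3, 4, 5, 6),
    n_knots: int = 50,
    fit_kwargs: dict | None = None,
) -> TuningResult:
    """Fit every (class set, rm) combination and rank by AICc.

    With the defaults this evaluates 36 combinations (six class sets times
    multipliers 1..6) and marks the AICc-minimum per class set and overall.
    """
    fit_kwargs = fit_kwargs or {}
    rows = []
    for classes in class_sets:
        fm = build_feature_map(background, classes, n_knots=n_knots)
        for rm in rm_range:
            try:
                model = maxent.fit(presence, background, fm, rm=float(rm), **fit_kwargs)
                a, k = aicc(model, presence, stack)
            except maxent.MaxentConvergenceError as exc:
                logger.warning("tune: %s rm=%s failed: %s", classes, rm, exc)
                a, k = float("inf"), -1
            rows.append({"classes": classes, "rm": float(rm), "k": k, "aicc": a,
                         "valid": np.isfinite(a)})
    table = pd.DataFrame(rows)
    if not table["valid"].any():
        raise ValueError("all tuning combinations were invalid (k >= n - 1 everywhere?)")
    table["best_in_class"] = False
    for classes in class_sets:
        sub = table[(table["classes"] == classes) & table["valid"]]
        if len(sub):
            table.loc[sub["aicc"].idxmin(), "best_in_class"] = True
    table["best"] = False
    best_idx = table.loc[table["valid"], "aicc"].idxmin()
    table.loc[best_idx, "best"] = True
    best = table.loc[best_idx]
    return TuningResult(table=table, best_classes=str(best["classes"]), best_rm=float(best["rm"]))


# ---------------------------------------------------------------------------
# Variable selection


def select_variables(
    presence: SWDTable,
    background: SWDTable,
    stack: LayerStack,
    contribution_min: float = 5.0,
    correlation_max: float = 0.9,
    classes: str = "LQ",
    rm: float = 1.0,
    class_sets: Sequence[str] = DEFAULT_CLASS_SETS,
    rm_range: Sequence[float] = (1, 2, 3, 4, 5, 6),
    n_knots: int = 50,
    max_rounds: int = 20,
    tune_at_end: bool = True,
    fit_kwargs: dict | None = None,
) -> tuple[list[str], TuningResult | None, list[dict]]:
    """Iterative contribution/correlation variable filtering.

    Each round fits a model (``classes``/``rm``) on the current variables,
    drops variables whose percent contribution falls below
    ``contribution_min``, and, for each pair correlated beyond
    ``correlation_max`` (|r|), drops the lower-contribution member. Repeats to
    a fixed point, then (optionally) runs the full AICc tuning on the retained
    set. Returns (retained variables, tuning result, elimination trace).
    """
    if len(presence.variables) < 2:
        raise ValueError("variable selection needs at least 2 variables")
    variables = list(presence.variables)
    trace: list[dict] = []
    fit_kwargs = fit_kwargs or {}

    def subset(swd: SWDTable, keep: list[str]) -> SWDTable:
        return SWDTable(data=swd.data[["species", "lon", "lat", *keep]].copy(),
                        n_excluded=swd.n_excluded)

    for round_no in range(max_rounds):
        pres_s, back_s = subset(presence, variables), subset(background, variables)
        fm = build_feature_map(back_s, classes, n_knots=n_knots)
        model = maxent.fit(pres_s, back_s, fm, rm=rm, **fit_kwargs)
        imp = maxent.variable_importance(model, pres_s, back_s, seed=0)
        contrib = dict(zip(imp["variable"], imp["percent_contribution"]))

        drop: set[str] = {v for v in variables if contrib[v] < contribution_min}
        from .rasters import correlation_matrix

        corr, flagged = correlation_matrix(back_s, threshold=correlation_max)
        for a, b, r in flagged:
            if a in drop or b in drop:
                continue
            loser = a if contrib[a] <= contrib[b] else b
            drop.add(loser)
            trace.append({"round": round_no, "dropped": loser, "reason": f"|r|>={correlation_max} with {b if loser == a else a}", "r": r})
        for v in sorted(drop - {t["dropped"] for t in trace if t["round"] == round_no}):
            trace.append({"round": round_no, "dropped": v,
                          "reason": f"contribution {contrib[v]:.2f} < {contribution_min}",
                          "r": float("nan")})
        remaining = [v for v in variables if v not in drop]
        if not remaining:
            raise ValueError(f"all variables eliminated; trace: {trace}")
        if len(remaining) == len(variables):
            break
        variables = remaining
        if len(variables) == 1:
            break

    tuning = None
    if tune_at_end:
        pres_s, back_s = subset(presence, variables), subset(background, variables)
        tuning = tune(pres_s, back_s, stack, class_sets=class_sets, rm_range=rm_range,
                      n_knots=n_knots, fit_kwargs=fit_kwargs)
    return variables, tuning, trace


# ---------------------------------------------------------------------------
# Replicate evaluation and candidate choice


@dataclass
class EvalReport:
    """Per-replicate evaluation of one model configuration."""

    label: str
    replicates: pd.DataFrame  # columns: replicate, train_auc, test_auc, auc_diff,
    #                                    threshold, omission, overfit, proc_ratio, proc_p

    @property
    def mean_test_omission(self) -> float:
        return float(self.replicates["omission"].mean())

    @property
    def mean_auc_diff(self) -> float:
        return float(self.replicates["auc_diff"].abs().mean())

    @property
    def mean_test_auc(self) -> float:
        return float(self.replicates["test_auc"].mean())


def evaluate_model(
    presence: SWDTable,
    background: SWDTable,
    feature_map: FeatureMap,
    rm: float,
    label: str = "",
    n_rep: int = 10,
    test_frac: float = 0.25,
    seed: int = 0,
    partial_roc_kwargs: dict | None = None,
    fit_kwargs: dict | None = None,
) -> EvalReport:
    """Bootstrap-replicate evaluation of a (feature map, rm) configuration.

    Per replicate: fit on the resampled training pool, score train/test
    presences and background on the cloglog scale, take the maxSSS threshold
    from the training presences, and record train/test AUC, their difference,
    the test omission rate with its overfitting flag, and (when the test set
    is large enough) the partial ROC ratio and p-value.
    """
    fit_kwargs = fit_kwargs or {}
    proc_kwargs = {"E": 0.05, "iterations": 500, "resample_frac": 0.5}
    proc_kwargs.update(partial_roc_kwargs or {})
    splits = make_replicates(len(presence), n_rep=n_rep, test_frac=test_frac, seed=seed)
    Xb = background.data[presence.variables].to_numpy(dtype=float)
    rows = []
    for sp in splits:
        train = SWDTable(data=presence.data.iloc[sp.train].reset_index(drop=True))
        test = SWDTable(data=presence.data.iloc[sp.test].reset_index(drop=True))
        model = maxent.fit(train, background, feature_map, rm=rm, **fit_kwargs)
        s_train = model.predict_cloglog(train)
        s_test = model.predict_cloglog(test)
        s_back = model.predict_cloglog(Xb)
        t = max_sss_threshold(s_train, s_back)
        om, overfit = omission_rate(s_test, t)
        train_auc = auc(s_train, s_back)
        test_auc = auc(s_test, s_back)
        if s_test.size >= 10:
            proc = partial_roc(s_test, s_back, seed=sp.seed + sp.index, **proc_kwargs)
            ratio, pval = proc["mean_auc_ratio"], proc["p_value"]
        else:
            ratio, pval = float("nan"), float("nan")
        rows.append({
            "replicate": sp.index,
            "train_auc": train_auc,
            "test_auc": test_auc,
            "auc_diff": train_auc - test_auc,
            "threshold": t,
            "omission": om,
            "overfit": overfit,
            "proc_ratio": ratio,
            "proc_p": pval,
        })
    return EvalReport(label=label, replicates=pd.DataFrame(rows))


def choose_model(reports: Sequence[EvalReport]) -> EvalReport:
    """Lexicographic choice prioritizing low omission.

    Orders candidates by mean test omission, then mean |train - test| AUC
    difference, then (descending) mean test AUC; exact ties fall back to input
    order, which is logged.
    """
    if not reports:
        raise ValueError("need at least one candidate report")
    keys = [
        (r.mean_test_omission, r.mean_auc_diff, -r.mean_test_auc, i)
        for i, r in enumerate(reports)
    ]
    best = min(keys)
    ties = [k for k in keys if k[:3] == best[:3]]
    if len(ties) > 1:
        logger.info("choose_model: %d candidates tied; keeping input order", len(ties))
    return reports[best[3]]
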