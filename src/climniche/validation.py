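"""Packaged validation experiments with known ground truth.

These are the standard checks a practitioner runs before trusting the
pipeline on real data: virtual-species recovery (does the tuned model find
the planted niche and its occupied area?), null calibration of the partial
ROC test, and the constructed warming scenario (does a warm-adapted species'
modeled range shift poleward under a uniform warming?). Each experiment is a
pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import areas as areas_mod
from . import evaluation as ev
from . import maxent
from .rasters import SWDTable
from .synthetic import recovery_scenario, warming_scenario

__all__ = [
    "RecoveryResult",
    "recovery_run",
    "null_partial_roc_calibration",
    "warming_polar_shift",
]


@dataclass
class RecoveryResult:
    seed: int
    best_classes: str
    best_rm: float
    heldout_auc: float
    estimated_area_km2: float
    true_area_km2: float

    @property
    def area_error_frac(self) -> float:
        return self.estimated_area_km2 / self.true_area_km2 - 1.0


def recovery_run(seed: int, n_knots: int = 8, test_frac: float = 0.25) -> RecoveryResult:
    """One virtual-species recovery experiment.

    Generates the standard recovery scenario (200 presences, 2000 background
    on a 100 x 100 grid), tunes over the six feature-class sets x multipliers
    1-6 by AICc, refits the winning configuration on a 75% training split,
    and measures the held-out AUC and the maxSSS-thresholded suitable area
    against the species' true occupied area.
    """
    sc = recovery_scenario(seed=seed)
    pres, bg = sc.presence_swd, sc.background_swd
    tuning = ev.tune(pres, bg, sc.stack, n_knots=n_knots)

    rng = np.random.default_rng(seed + 10)
    n = len(pres)
    perm = rng.permutation(n)
    n_test = round(test_frac * n)
    test = SWDTable(data=pres.data.iloc[perm[:n_test]].reset_index(drop=True))
    train = SWDTable(data=pres.data.iloc[perm[n_test:]].reset_index(drop=True))

    fm = maxent.build_feature_map(bg, tuning.best_classes, n_knots=n_knots)
    model = maxent.fit(train, bg, fm, rm=tuning.best_rm)
    s_train = model.predict_cloglog(train)
    s_test = model.predict_cloglog(test)
    s_bg = model.predict_cloglog(bg)
    auc = ev.auc(s_test, s_bg)
    t = ev.max_sss_threshold(s_train, s_bg)
    suit = maxent.project(model, sc.stack)
    est = areas_mod.regional_areas(areas_mod.threshold_map(suit, t))["total"]
    return RecoveryResult(
        seed=seed,
        best_classes=tuning.best_classes,
        best_rm=tuning.best_rm,
        heldout_auc=auc,
        estimated_area_km2=est,
        true_area_km2=sc.true_area_km2,
    )


def null_partial_roc_calibration(
    master_seed: int = 0,
    n_datasets: int = 200,
    n_presences: int = 400,
    n_background: int = 2000,
    iterations: int = 500,
) -> dict:
    """Partial-ROC behavior when scores carry no information.

    Draws ``n_datasets`` null datasets (presence and background scores from
    the same uniform distribution) and runs the partial ROC test on each.
    Returns the mean AUC ratio, the per-dataset p-values, and the
    Kolmogorov-Smirnov p-value of those p-values against the uniform
    distribution (a calibrated test yields approximately uniform p-values).
    """
    from scipy import stats

    rng = np.random.default_rng(master_seed)
    ratios = np.empty(n_datasets)
    pvals = np.empty(n_datasets)
    for d in range(n_datasets):
        pres = rng.uniform(0, 1, n_presences)
        back = rng.uniform(0, 1, n_background)
        out = ev.partial_roc(pres, back, iterations=iterations,
                             seed=int(rng.integers(2**31)))
        ratios[d] = out["mean_auc_ratio"]
        pvals[d] = out["p_value"]
    ks = stats.kstest(pvals, "uniform")
    return {
        "mean_ratio": float(np.nanmean(ratios)),
        "p_values": pvals,
        "ks_uniform_p": float(ks.pvalue),
    }


def warming_polar_shift(seed: int = 0, warming: float = 2.0,
                        n_presence: int = 200, n_background: int = 2000) -> dict:
    """Fit a warm-adapted virtual species and project under uniform warming.

    Returns the modeled suitable area above the Arctic Circle for the baseline
    and warmed stacks (and the true suitability areas for reference). Under
    the construction, warming moves the species' suitable band poleward, so
    the polar area increases.
    """
    stack, warmed, species = warming_scenario(seed=seed, warming=warming)
    from .rasters import extract_swd
    from .synthetic import sample_presences

    occ = sample_presences(species, stack, n=n_presence, seed=seed + 1)
    pres = extract_swd(stack, occ.coords(), label=species.name)
    rng = np.random.default_rng(seed + 2)
    mask = stack.complete_mask()
    valid = np.where(mask.ravel())[0]
    idx = rng.choice(valid, n_background)
    r, c = np.unravel_index(idx, mask.shape)
    bg = extract_swd(stack, np.column_stack(
        [stack.spec.lon_centers()[c], stack.spec.lat_centers()[r]]), "background")

    fm = maxent.build_feature_map(bg, "LQ")
    model = maxent.fit(pres, bg, fm, rm=1.0)
    t = ev.max_sss_threshold(model.predict_cloglog(pres), model.predict_cloglog(bg))
    out = {}
    for label, stk in (("baseline", stack), ("warmed", warmed)):
        suit = maxent.project(model, stk)
        out[label] = areas_mod.regional_areas(areas_mod.threshold_map(suit, t))
    cutoff = float(np.nanmean(species.suitability(stack).values))
    out["true_baseline_polar"] = areas_mod.regional_areas(
        areas_mod.threshold_map(species.suitability(stack), cutoff))["polar"]
    out["true_warmed_polar"] = areas_mod.regional_areas(
        areas_mod.threshold_map(species.suitability(warmed), cutoff))["polar"]
    out["threshold"] = t
    return out
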