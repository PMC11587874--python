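"""Configuration-driven orchestration of the full modeling workflow.

``run_enm`` chains the presence-only stages for each species — thinning, bias
surface, background sampling, variable selection and AICc tuning, bootstrap
replicate evaluation, model choice, projection to every period, thresholding,
regional area accounting and climatic-range extraction. ``run_differentiation``
runs the niche-comparison stages — full and per-pair PCA with broken-stick
retention and ANOVA/Tukey, condition-number/VIF subset selection, and the
cross-validated L2 logistic discrimination with attributions.

Every stochastic stage draws its seed deterministically from the master seed,
so a rerun with the same configuration reproduces every table byte for byte.
Inputs may come from files named in the config or be handed over in memory.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import areas as areas_mod
from . import evaluation as ev
from . import maxent
from .occurrences import OccurrenceSet, kde_bias_surface, load_occurrences, sample_background, thin
from .rasters import LayerStack, Raster, SWDTable, crop, extract_swd, read_ascii_grid
from .differentiation import (
    anova_tukey,
    classification_metrics,
    fit_l2_logistic_cv,
    linear_shap,
    pca,
    split_train_test,
    subset_select_condition_vif,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_enm", "run_differentiation"]


@dataclass
class RunConfig:
    """All tunables of the workflow; defaults follow the standard protocol
    (50 km thinning with recency preference, 10 000 background points, six
    feature-class sets x multipliers 1-6, ten bootstrap replicates with 25%
    test, maxSSS thresholding, Ural/Arctic regional splits)."""

    species: list[str] = field(default_factory=list)
    occurrence_files: dict[str, str] = field(default_factory=dict)
    stack_dirs: dict[str, str] = field(default_factory=dict)  # period -> directory of .asc
    training_period: str = "current"
    bbox: tuple[float, float, float, float] | None = None
    thin_km: float = 50.0
    prefer: str = "recent"
    background_n: int = 10_000
    class_sets: tuple[str, ...] = ev.DEFAULT_CLASS_SETS
    rm_range: tuple[float, ...] = (1, 2, 3, 4, 5, 6)
    n_knots: int = 50
    do_variable_selection: bool = True
    contribution_min: float = 5.0
    correlation_max: float = 0.9
    n_replicates: int = 10
    test_frac: float = 0.25
    partial_roc_E: float = 0.05
    meridian: float = areas_mod.URAL_MERIDIAN_E
    polar_lat: float = areas_mod.ARCTIC_CIRCLE_N
    pca_alpha: float = 0.001
    train_frac: float = 0.8
    vif_max: float = 10.0
    seed: int = 0
    output_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["class_sets"] = list(self.class_sets)
        doc["rm_range"] = list(self.rm_range)
        doc["bbox"] = list(self.bbox) if self.bbox else None
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("bbox"):
            doc["bbox"] = tuple(doc["bbox"])
        if doc.get("class_sets"):
            doc["class_sets"] = tuple(doc["class_sets"])
        if doc.get("rm_range"):
            doc["rm_range"] = tuple(doc["rm_range"])
        return cls(**doc)


def _load_stacks(config: RunConfig) -> dict[str, LayerStack]:
    stacks = {}
    for period, d in config.stack_dirs.items():
        d = Path(d)
        layers = {}
        for f in sorted(d.glob("*.asc")):
            layers[f.stem] = read_ascii_grid(f)
        if not layers:
            raise ValueError(f"no .asc layers found in {d}")
        stacks[period] = LayerStack(layers=layers, period=period)
    return stacks


def _maybe_write(df: pd.DataFrame, config: RunConfig, name: str) -> None:
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)


def run_enm(
    config: RunConfig,
    occurrences: Mapping[str, OccurrenceSet] | None = None,
    stacks: Mapping[str, LayerStack] | None = None,
) -> dict[str, dict]:
    """Run the full niche-modeling workflow for every configured species.

    ``occurrences`` and ``stacks`` may be supplied in memory; otherwise they
    are loaded from the paths in the config. Returns, per species, the thinned
    occurrence set, tuning table, evaluation reports, chosen configuration,
    final model, per-period suitability rasters, the regional area table and
    the training-period climatic ranges.
    """
    if stacks is None:
        stacks = _load_stacks(config)
    if config.training_period not in stacks:
        raise ValueError(f"training period {config.training_period!r} has no stack")
    if config.bbox is not None:
        stacks = {k: crop(s, config.bbox) for k, s in stacks.items()}
    train_stack = stacks[config.training_period]

    results: dict[str, dict] = {}
    area_rows = []
    for si, species in enumerate(config.species):
        seed = config.seed + 1000 * si
        if occurrences is not None and species in occurrences:
            occ = occurrences[species]
        else:
            occ = load_occurrences(config.occurrence_files[species], species)
        n_raw = len(occ)
        thinned = thin(occ, min_distance_km=config.thin_km, prefer=config.prefer)
        logger.info("%s: %d records loaded, %d retained after %g km thinning",
                    species, n_raw, len(thinned), config.thin_km)

        bias = kde_bias_surface(thinned, train_stack.spec, mask=train_stack.complete_mask())
        bg_pts = sample_background(bias, n=config.background_n, seed=seed)
        background = extract_swd(train_stack, bg_pts, label="background")
        presence = extract_swd(train_stack, thinned.coords(), label=species)
        logger.info("%s: %d presence SWD rows (%d excluded), %d background rows",
                    species, len(presence), presence.n_excluded, len(background))

        if config.do_variable_selection and len(presence.variables) > 2:
            variables, tuning, trace = ev.select_variables(
                presence, background, train_stack,
                contribution_min=config.contribution_min,
                correlation_max=config.correlation_max,
                class_sets=config.class_sets, rm_range=config.rm_range,
                n_knots=config.n_knots,
            )
            keep = ["species", "lon", "lat", *variables]
            presence = SWDTable(data=presence.data[keep].copy())
            background = SWDTable(data=background.data[keep].copy())
        else:
            variables = list(presence.variables)
            tuning = ev.tune(presence, background, train_stack,
                             class_sets=config.class_sets, rm_range=config.rm_range,
                             n_knots=config.n_knots)
            trace = []
        _maybe_write(tuning.table, config, f"{species}_tuning.csv")

        # Evaluate the AICc-best multiplier of each class set; choose by omission.
        reports = []
        candidates = tuning.table[tuning.table["best_in_class"]]
        for _, row in candidates.iterrows():
            fm = maxent.build_feature_map(background, row["classes"], n_knots=config.n_knots)
            rep = ev.evaluate_model(
                presence, background, fm, rm=row["rm"],
                label=f"{row['classes']}_rm{row['rm']:g}",
                n_rep=config.n_replicates, test_frac=config.test_frac, seed=seed + 1,
                partial_roc_kwargs={"E": config.partial_roc_E},
            )
            reports.append(rep)
        chosen = ev.choose_model(reports)
        eval_table = pd.concat(
            [r.replicates.assign(candidate=r.label, chosen=(r.label == chosen.label))
             for r in reports],
            ignore_index=True,
        )
        _maybe_write(eval_table, config, f"{species}_evaluation.csv")

        chosen_classes, chosen_rm = chosen.label.rsplit("_rm", 1)
        fm = maxent.build_feature_map(background, chosen_classes, n_knots=config.n_knots)
        # Replicate-averaged projections: mean cloglog map over bootstrap fits.
        splits = ev.make_replicates(len(presence), n_rep=config.n_replicates,
                                    test_frac=config.test_frac, seed=seed + 1)
        rep_models = []
        thresholds = []
        Xb = background.data[presence.variables].to_numpy(dtype=float)
        for sp in splits:
            tr = SWDTable(data=presence.data.iloc[sp.train].reset_index(drop=True))
            m = maxent.fit(tr, background, fm, rm=float(chosen_rm))
            rep_models.append(m)
            thresholds.append(ev.max_sss_threshold(m.predict_cloglog(tr), m.predict_cloglog(Xb)))
        t_mean = float(np.mean(thresholds))

        projections: dict[str, Raster] = {}
        for period, stack in stacks.items():
            maps = [maxent.project(m, stack) for m in rep_models]
            mean_map = Raster(spec=stack.spec,
                              values=np.nanmean(np.stack([r.values for r in maps]), axis=0))
            projections[period] = mean_map
            tmap = areas_mod.threshold_map(mean_map, t_mean, species=species, period=period,
                                           climate_model=stack.climate_model)
            row = areas_mod.regional_areas(tmap, meridian=config.meridian,
                                           polar_lat=config.polar_lat)
            area_rows.append({"species": species, "period": period,
                              "climate_model": stack.climate_model, "threshold": t_mean,
                              "total_km2": row["total"], "europe_km2": row["europe"],
                              "asia_km2": row["asia"], "polar_km2": row["polar"]})

        train_tmap = areas_mod.threshold_map(projections[config.training_period], t_mean,
                                             species=species, period=config.training_period)
        ranges = areas_mod.variable_ranges(train_tmap, train_stack)
        _maybe_write(ranges, config, f"{species}_variable_ranges.csv")

        final_model = maxent.fit(presence, background, fm, rm=float(chosen_rm))
        importance = maxent.variable_importance(final_model, presence, background, seed=seed + 2)
        _maybe_write(importance, config, f"{species}_importance.csv")

        results[species] = {
            "occurrences_raw": n_raw,
            "occurrences_thinned": thinned,
            "variables": variables,
            "selection_trace": trace,
            "tuning": tuning,
            "reports": reports,
            "chosen": chosen,
            "threshold": t_mean,
            "model": final_model,
            "projections": projections,
            "variable_ranges": ranges,
            "importance": importance,
        }

    area_table = pd.DataFrame(area_rows)
    _maybe_write(area_table, config, "area_series.csv")
    results["area_series"] = area_table
    return results


def run_differentiation(
    config: RunConfig,
    tables: Mapping[str, pd.DataFrame] | None = None,
) -> dict:
    """Niche comparison across species: PCA + per-pair discrimination.

    ``tables`` maps species to feature tables (``species`` column + variable
    columns, one row per record); when omitted they are built from the
    configured occurrence files and training stack. Requires >= 2 species.
    """
    if tables is None:
        stacks = _load_stacks(config)
        if config.bbox is not None:
            stacks = {k: crop(s, config.bbox) for k, s in stacks.items()}
        train_stack = stacks[config.training_period]
        tables = {}
        for species in config.species:
            occ = load_occurrences(config.occurrence_files[species], species)
            thinned = thin(occ, min_distance_km=config.thin_km, prefer=config.prefer)
            tables[species] = extract_swd(train_stack, thinned.coords(), label=species).data
    species = list(tables)
    if len(species) < 2:
        raise ValueError("niche differentiation needs at least 2 species")

    full = pd.concat(tables.values(), ignore_index=True)
    full_pca = pca(full)
    k = max(1, full_pca.retained)
    anova_tab, tukey_tab = anova_tukey(
        full_pca.scores, full["species"], components=range(k), alpha_report=config.pca_alpha
    )
    loadings = pd.DataFrame(
        full_pca.loadings[:, :k], index=full_pca.variables,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    _maybe_write(loadings.reset_index(names="variable"), config, "pca_loadings.csv")
    _maybe_write(anova_tab, config, "pca_anova.csv")
    _maybe_write(tukey_tab, config, "pca_tukey.csv")

    pair_results = {}
    coef_rows = []
    for pi, (a, b) in enumerate(itertools.combinations(species, 2)):
        pair = (a, b)
        sub = pd.concat([tables[a], tables[b]], ignore_index=True)
        pair_pca = pca(sub)
        selection = subset_select_condition_vif(sub, vif_max=config.vif_max)
        cols = ["species", *selection.final_subset]
        train, test = split_train_test(sub[cols], train_frac=config.train_frac,
                                       seed=config.seed + 10 * pi)
        model = fit_l2_logistic_cv(train, selection.final_subset, pair,
                                   seed=config.seed + 10 * pi + 1)
        metrics = classification_metrics(model, test)
        phi, base = linear_shap(model, test)
        pair_results[pair] = {
            "pca": pair_pca,
            "selection": selection,
            "model": model,
            "metrics": metrics,
            "shap": phi,
            "shap_base": base,
        }
        for v, c in zip(model.variables, model.coefficients):
            coef_rows.append({"pair": f"{a}-{b}", "variable": v, "coefficient": float(c),
                              "lambda_pen": model.lambda_pen, **metrics})
    coef_table = pd.DataFrame(coef_rows)
    _maybe_write(coef_table, config, "logistic_coefficients.csv")

    return {
        "pca": full_pca,
        "anova": anova_tab,
        "tukey": tukey_tab,
        "loadings": loadings,
        "pairs": pair_results,
        "coefficients": coef_table,
    }
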