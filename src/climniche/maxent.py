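"""Presence-background maximum-entropy modeling (MaxEnt).

The model places a Gibbs distribution over background cells,
``raw(x) = exp(eta(x)) / Z`` with ``eta(x) = sum_j lambda_j f_j(x)``, where the
features f_j are transforms (linear, quadratic, product, hinge, threshold) of
environmental variables min-max scaled to [0, 1] by their background range.
Coefficients maximize the L1-penalized log likelihood

    (1/m) sum_presence eta(x) - log sum_background exp(eta(x)) - sum_j beta_j |lambda_j|

with per-feature penalties ``beta_j = rm * base(class, m) * sd_j(presences)``
(``rm`` the regularization multiplier, ``base`` the class-dependent default
table, ``sd_j`` floored at 1e-3). The objective is concave; it is solved by an
accelerated proximal-gradient loop with backtracking, then polished to high
accuracy by an active-set Newton step with KKT screening.

Prediction scales: ``raw`` (sums to 1 over the training background) and
``cloglog(x) = 1 - exp(-exp(H) * raw(x))`` where H is the entropy of the
fitted raw distribution — an occupancy-probability-like rescaling in (0, 1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, softmax

from .rasters import LayerStack, Raster, SWDTable

logger = logging.getLogger(__name__)

FEATURE_CLASSES = "LQHPT"

__all__ = [
    "FeatureMap",
    "MaxentModel",
    "MaxentConvergenceError",
    "build_feature_map",
    "fit",
    "predict_raw",
    "predict_cloglog",
    "project",
    "variable_importance",
]


class MaxentConvergenceError(RuntimeError):
    """Raised when the optimizer hits its iteration cap without converging."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class Feature:
    """One derived feature: class tag, variable index (pair for products), knot."""

    cls: str  # one of L Q H R T (R = reverse hinge)
    var: int
    var2: int = -1  # second variable for products
    knot: float = float("nan")

    @property
    def penalty_class(self) -> str:
        # Forward and reverse hinges share the hinge penalty class.
        return {"L": "L", "Q": "Q", "P": "P", "H": "H", "R": "H", "T": "T"}[self.cls]


@dataclass
class FeatureMap:
    """Variable scaling plus the derived feature list for a class combination."""

    variables: list[str]
    classes: str
    mins: np.ndarray
    maxs: np.ndarray
    features: list[Feature]
    n_knots: int = 50

    @property
    def n_features(self) -> int:
        return len(self.features)

    def scale(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Min-max scale raw variable values to [0, 1] by the background range.

        Constant variables scale to 0. With ``clamp``, values outside the
        training range are clipped to the range boundary.
        """
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        Z = (X - self.mins) / safe
        Z[:, span <= 0] = 0.0
        if clamp:
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Expand raw variable values (n, n_vars) into the feature matrix (n, p)."""
        Z = self.scale(X, clamp=clamp)
        n = Z.shape[0]
        out = np.empty((n, len(self.features)), dtype=float)
        for j, f in enumerate(self.features):
            z = Z[:, f.var]
            if f.cls == "L":
                out[:, j] = z
            elif f.cls == "Q":
                out[:, j] = z * z
            elif f.cls == "P":
                out[:, j] = z * Z[:, f.var2]
            elif f.cls == "H":
                out[:, j] = np.maximum(0.0, z - f.knot) / (1.0 - f.knot)
            elif f.cls == "R":
                out[:, j] = np.maximum(0.0, f.knot - z) / f.knot
            elif f.cls == "T":
                out[:, j] = (z > f.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature class {f.cls}")
        return out

    def feature_variables(self, j: int) -> list[int]:
        f = self.features[j]
        return [f.var, f.var2] if f.cls == "P" else [f.var]


def build_feature_map(
    background: SWDTable, classes: str, n_knots: int = 50
) -> FeatureMap:
    """Derive the feature list for ``classes`` (subset of L, Q, H, P, T).

    Variable ranges come from the background sample; hinge and threshold knots
    are evenly spaced strictly inside the scaled (0, 1) range. Nonlinear
    features of constant variables are skipped with a warning.
    """
    classes = "".join(dict.fromkeys(classes.upper()))
    if not classes or any(c not in FEATURE_CLASSES for c in classes):
        raise ValueError(f"classes must be a non-empty subset of {FEATURE_CLASSES!r}")
    if len(background) == 0:
        raise ValueError("background table is empty")
    X = background.values
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    nvar = X.shape[1]
    variable_ok = maxs > mins
    for v, ok in enumerate(variable_ok):
        if not ok:
            warnings.warn(
                f"variable {background.variables[v]!r} is constant over the background; "
                "its nonlinear features are skipped",
                stacklevel=2,
            )
    knots = (np.arange(1, n_knots + 1) / (n_knots + 1)).tolist()
    features: list[Feature] = []
    if "L" in classes:
        features += [Feature("L", v) for v in range(nvar)]
    if "Q" in classes:
        features += [Feature("Q", v) for v in range(nvar) if variable_ok[v]]
    if "P" in classes:
        features += [
            Feature("P", a, var2=b)
            for a in range(nvar)
            for b in range(a + 1, nvar)
            if variable_ok[a] and variable_ok[b]
        ]
    if "H" in classes:
        for v in range(nvar):
            if variable_ok[v]:
                features += [Feature("H", v, knot=k) for k in knots]
                features += [Feature("R", v, knot=k) for k in knots]
    if "T" in classes:
        for v in range(nvar):
            if variable_ok[v]:
                features += [Feature("T", v, knot=k) for k in knots]
    return FeatureMap(
        variables=list(background.variables),
        classes=classes,
        mins=mins,
        maxs=maxs,
        features=features,
        n_knots=n_knots,
    )


# ---------------------------------------------------------------------------
# Penalties

# Default per-class base penalties; linear/quadratic/product interpolate on the
# presence count m, hinge is constant 0.5, threshold constant 1.0.
_LQP_TABLE_M = np.array([0.0, 10.0, 30.0, 100.0])
_LQP_TABLE_B = np.array([1.0, 1.0, 0.2, 0.05])


def _base_penalty(penalty_class: str, m: int) -> float:
    if penalty_class in ("L", "Q", "P"):
        return float(np.interp(m, _LQP_TABLE_M, _LQP_TABLE_B))
    if penalty_class == "H":
        return 0.5
    if penalty_class == "T":
        return 1.0
    raise ValueError(penalty_class)  # pragma: no cover


def penalty_weights(feature_map: FeatureMap, F_presence: np.ndarray, rm: float) -> np.ndarray:
    """beta_j = rm * base(class, m) * sd_j(presence features), sd floored at 1e-3."""
    m = F_presence.shape[0]
    sd = np.maximum(F_presence.std(axis=0), 1e-3)
    base = np.array([_base_penalty(f.penalty_class, m) for f in feature_map.features])
    return rm * base * sd


# ---------------------------------------------------------------------------
# Model


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    ``lam`` are coefficients per feature, ``beta`` the per-feature penalty
    weights, ``logZ`` the log normalizer over the training background, ``H``
    the entropy of the fitted raw distribution (both enter the cloglog
    transform).
    """

    feature_map: FeatureMap
    lam: np.ndarray
    beta: np.ndarray
    logZ: float
    H: float
    rm: float
    n_presence: int
    n_background: int
    converged: bool = True
    n_iter: int = 0

    @property
    def variables(self) -> list[str]:
        return self.feature_map.variables

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.lam))

    def linear_predictor(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        return self.feature_map.transform(X, clamp=clamp) @ self.lam

    def _values_from(self, swd: SWDTable | np.ndarray) -> np.ndarray:
        if isinstance(swd, SWDTable):
            missing = [v for v in self.variables if v not in swd.variables]
            if missing:
                raise ValueError(f"SWD table is missing model variable(s): {missing}")
            return swd.data[self.variables].to_numpy(dtype=float)
        return np.asarray(swd, dtype=float)

    def predict_raw(self, swd: SWDTable | np.ndarray, clamp: bool = False) -> np.ndarray:
        """Gibbs weights exp(eta - logZ); sum to 1 over the training background."""
        eta = self.linear_predictor(self._values_from(swd), clamp=clamp)
        return np.exp(eta - self.logZ)

    def predict_cloglog(self, swd: SWDTable | np.ndarray, clamp: bool = False) -> np.ndarray:
        """Cloglog suitability 1 - exp(-e^H * raw), strictly increasing in raw."""
        raw = self.predict_raw(swd, clamp=clamp)
        return 1.0 - np.exp(-np.exp(self.H) * raw)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        fm = self.feature_map
        doc = {
            "variables": fm.variables,
            "classes": fm.classes,
            "n_knots": fm.n_knots,
            "mins": fm.mins.tolist(),
            "maxs": fm.maxs.tolist(),
            "features": [
                {"cls": f.cls, "var": f.var, "var2": f.var2, "knot": f.knot}
                for f in fm.features
            ],
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "logZ": self.logZ,
            "H": self.H,
            "rm": self.rm,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        doc = json.loads(Path(path).read_text())
        fm = FeatureMap(
            variables=doc["variables"],
            classes=doc["classes"],
            mins=np.array(doc["mins"]),
            maxs=np.array(doc["maxs"]),
            features=[
                Feature(d["cls"], d["var"], var2=d["var2"], knot=d["knot"])
                for d in doc["features"]
            ],
            n_knots=doc["n_knots"],
        )
        return cls(
            feature_map=fm,
            lam=np.array(doc["lam"]),
            beta=np.array(doc["beta"]),
            logZ=doc["logZ"],
            H=doc["H"],
            rm=doc["rm"],
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
        )


# ---------------------------------------------------------------------------
# Fitting


def _objective(lam, Fp_mean, Fb, beta):
    eta_b = Fb @ lam
    return float(-(Fp_mean @ lam) + logsumexp(eta_b) + beta @ np.abs(lam))


def _smooth_grad(lam, Fp_mean, Fb):
    pi = softmax(Fb @ lam)
    return -Fp_mean + Fb.T @ pi, pi


def _fista(Fp_mean, Fb, beta, tol, max_iter):
    """Accelerated proximal gradient with backtracking and adaptive restart."""
    p = Fp_mean.shape[0]
    lam = np.zeros(p)
    y = lam.copy()
    t = 1.0
    # Initial step scale from the typical curvature of logsumexp at uniform pi.
    col_norm = np.linalg.norm(Fb, axis=0).max()
    L = max(col_norm**2 / Fb.shape[0], 1e-8)

    def smooth_val(x):
        return float(-(Fp_mean @ x) + logsumexp(Fb @ x))

    f_prev = _objective(lam, Fp_mean, Fb, beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g, _ = _smooth_grad(y, Fp_mean, Fb)
        sy = smooth_val(y)
        while True:  # backtracking on the smooth majorization
            step = 1.0 / L
            cand = np.sign(y - step * g) * np.maximum(np.abs(y - step * g) - step * beta, 0.0)
            diff = cand - y
            if smooth_val(cand) <= sy + g @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
        f_new = _objective(cand, Fp_mean, Fb, beta)
        if f_new > f_prev:  # adaptive restart: drop momentum
            y = lam.copy()
            t = 1.0
            L *= 2.0
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = cand + ((t - 1.0) / t_new) * (cand - lam)
        lam, t = cand, t_new
        if abs(f_prev - f_new) < tol * (abs(f_prev) + 1e-12):
            return lam, f_new, n_iter, True
        f_prev = f_new
        L = max(L / 2.0, 1e-8)  # allow the step to grow again
    return lam, f_prev, n_iter, False


def _polish_active_set(lam, Fp_mean, Fb, beta, max_rounds=40):
    """Active-set Newton refinement with KKT screening.

    On the active set the penalty is smooth (fixed signs), so damped Newton
    converges quadratically; features whose smooth gradient violates the KKT
    bound |g_j| <= beta_j are added between rounds. Coefficients that cross
    zero are pruned. Returns the refined coefficients.
    """
    lam = lam.copy()
    p = lam.size
    for _ in range(max_rounds):
        g, pi = _smooth_grad(lam, Fp_mean, Fb)
        active = lam != 0.0
        viol = (~active) & (np.abs(g) > beta + 1e-9)
        if viol.any():
            # admit the worst violators (working-set growth)
            idx = np.argsort(np.abs(g[viol]) - beta[viol])[::-1]
            cand = np.where(viol)[0][idx[:50]]
            active[cand] = True
            # give new entries the descent sign
            lam[cand] = 0.0
        A = np.where(active)[0]
        if A.size == 0:
            return lam
        signs = np.sign(lam[A])
        signs[signs == 0] = -np.sign(g[A][signs == 0])
        converged_inner = False
        for _ in range(60):
            eta = Fb @ lam
            pi = softmax(eta)
            FA = Fb[:, A]
            gA = -Fp_mean[A] + FA.T @ pi + beta[A] * signs
            if np.max(np.abs(gA)) < 1e-11:
                converged_inner = True
                break
            W = FA * pi[:, None]
            Hess = FA.T @ W - np.outer(FA.T @ pi, FA.T @ pi)
            Hess[np.diag_indices_from(Hess)] += 1e-10
            try:
                step = np.linalg.solve(Hess, gA)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hess, gA, rcond=None)[0]
            # damped Newton with simple halving on the penalized objective
            f0 = _objective(lam, Fp_mean, Fb, beta)
            alpha = 1.0
            for _ in range(40):
                trial = lam.copy()
                trial[A] = lam[A] - alpha * step
                # freeze sign pattern: crossings are clipped to zero
                crossed = np.sign(trial[A]) * signs < 0
                trial[A[crossed]] = 0.0
                if _objective(trial, Fp_mean, Fb, beta) <= f0 + 1e-14:
                    lam = trial
                    break
                alpha *= 0.5
            else:
                converged_inner = True
                break
            pruned = lam[A] == 0.0
            if pruned.any():
                break  # active set changed; restart outer round
        g, _ = _smooth_grad(lam, Fp_mean, Fb)
        kkt_ok = np.all(np.abs(g[lam == 0.0]) <= beta[lam == 0.0] + 1e-8)
        active_ok = (
            np.max(np.abs(g[lam != 0.0] + beta[lam != 0.0] * np.sign(lam[lam != 0.0])), initial=0.0)
            < 1e-8
        )
        if converged_inner and kkt_ok and active_ok:
            break
    return lam


def fit(
    presence: SWDTable,
    background: SWDTable,
    feature_map: FeatureMap,
    rm: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 5000,
    polish: bool = True,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``rm`` is the regularization multiplier scaling every per-feature penalty.
    Deterministic for fixed inputs. Raises :class:`MaxentConvergenceError` if
    the proximal loop hits ``max_iter`` without meeting the relative-objective
    tolerance.
    """
    if len(presence) < 2:
        raise ValueError("need at least 2 presence rows")
    Xp = presence.data[feature_map.variables].to_numpy(dtype=float)
    Xb = background.data[feature_map.variables].to_numpy(dtype=float)
    Fp = feature_map.transform(Xp)
    Fb = feature_map.transform(Xb)
    beta = penalty_weights(feature_map, Fp, rm)
    Fp_mean = Fp.mean(axis=0)

    lam, f_val, n_iter, ok = _fista(Fp_mean, Fb, beta, tol=tol, max_iter=max_iter)
    if polish:
        lam = _polish_active_set(lam, Fp_mean, Fb, beta)
        ok = True
    if not ok:
        raise MaxentConvergenceError(
            f"maxent fit did not converge in {max_iter} iterations",
            diagnostics={"iterations": n_iter, "objective": f_val, "rm": rm,
                         "n_features": feature_map.n_features},
        )
    eta_b = Fb @ lam
    logZ = float(logsumexp(eta_b))
    raw = np.exp(eta_b - logZ)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-np.sum(np.where(raw > 0, raw * np.log(raw), 0.0)))
    return MaxentModel(
        feature_map=feature_map,
        lam=lam,
        beta=beta,
        logZ=logZ,
        H=H,
        rm=rm,
        n_presence=len(presence),
        n_background=len(background),
        n_iter=n_iter,
    )


# Functional aliases mirroring the operation names.


def predict_raw(model: MaxentModel, swd: SWDTable | np.ndarray, clamp: bool = False) -> np.ndarray:
    return model.predict_raw(swd, clamp=clamp)


def predict_cloglog(model: MaxentModel, swd: SWDTable | np.ndarray, clamp: bool = False) -> np.ndarray:
    return model.predict_cloglog(swd, clamp=clamp)


def project(model: MaxentModel, stack: LayerStack, clamp: bool = True) -> Raster:
    """Project the model onto a layer stack as a cloglog suitability raster.

    With ``clamp`` (the default), scaled feature values outside the training
    [0, 1] range are clipped to the boundary; the number of clamped cells is
    logged.
    """
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing model layer(s): {missing}")
    mask = np.ones((stack.spec.nrows, stack.spec.ncols), dtype=bool)
    for v in model.variables:
        mask &= stack.layers[v].mask
    X = np.column_stack([stack.layers[v].values[mask] for v in model.variables])
    Z = model.feature_map.scale(X)
    n_out = int(np.any((Z < 0) | (Z > 1), axis=1).sum())
    if n_out:
        logger.info(
            "projection onto %s: %d/%d cells outside the training range (%s)",
            stack.period, n_out, X.shape[0], "clamped" if clamp else "extrapolated",
        )
    vals = np.full((stack.spec.nrows, stack.spec.ncols), np.nan)
    vals[mask] = model.predict_cloglog(X, clamp=clamp)
    return Raster(spec=stack.spec, values=vals)


def variable_importance(
    model: MaxentModel,
    presence: SWDTable,
    background: SWDTable,
    seed: int = 0,
    highlight_min: float = 10.0,
) -> "pd.DataFrame":
    """Percent contribution (PC) and permutation importance (PI) per variable.

    PC allocates |lambda_j| * sd_j(background features) to each feature's
    variable(s) (products split evenly) and normalizes to 100. PI permutes a
    variable's values across presence + background (fixed seed), measures the
    drop in training AUC, and normalizes the non-negative drops to 100.
    Variables with PC or PI >= ``highlight_min`` (percent) carry a highlight
    flag, the convention for "highly contributing" variables.
    """
    import pandas as pd

    from .evaluation import auc  # local import to avoid a module cycle

    nvar = len(model.variables)
    if nvar < 2:
        contrib = np.array([100.0]) if nvar == 1 else np.array([])
    Xp = presence.data[model.variables].to_numpy(dtype=float)
    Xb = background.data[model.variables].to_numpy(dtype=float)
    Fb = model.feature_map.transform(Xb)
    sd_b = Fb.std(axis=0)
    raw_contrib = np.zeros(nvar)
    for j, f in enumerate(model.feature_map.features):
        c = abs(model.lam[j]) * sd_b[j]
        vars_j = model.feature_map.feature_variables(j)
        for v in vars_j:
            raw_contrib[v] += c / len(vars_j)
    pc = 100.0 * raw_contrib / raw_contrib.sum() if raw_contrib.sum() > 0 else np.zeros(nvar)

    rng = np.random.default_rng(seed)
    base_auc = auc(model.predict_cloglog(Xp), model.predict_cloglog(Xb))
    drops = np.zeros(nvar)
    X_all = np.vstack([Xp, Xb])
    m = Xp.shape[0]
    for v in range(nvar):
        Xs = X_all.copy()
        Xs[:, v] = rng.permutation(Xs[:, v])
        scores = model.predict_cloglog(Xs)
        drops[v] = max(0.0, base_auc - auc(scores[:m], scores[m:]))
    pi = 100.0 * drops / drops.sum() if drops.sum() > 0 else np.zeros(nvar)

    return pd.DataFrame(
        {
            "variable": model.variables,
            "percent_contribution": pc,
            "permutation_importance": pi,
            "highlight": (pc >= highlight_min) | (pi >= highlight_min),
        }
    )
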