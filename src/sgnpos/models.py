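"""Prediction models for synaptic contact position.

Implements the model-building procedure used to predict normalized basal
position (NBP) from biophysical features:

1. screen candidate features by significant Pearson correlation with NBP;
2. remove highly collinear features by iterative variance-inflation-factor
   (VIF) pruning, VIF = 1/(1 - R_n^2) with a cutoff of 4.0;
3. backward stepping: repeatedly drop the variable whose removal gives the
   best adjusted R^2 (RMSE as tie-break), stopping when no removal improves;
4. refit the surviving set by ordinary least squares.

Also provides the reciprocal-law fit y = K/x (current threshold vs latency,
latency vs conductance) and the constrained face-binned age-gradient fit for
steady-state conductance, whose inverse gives the developmental latency
curves L = K / g_max(age).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats

__all__ = [
    "RegressionModel",
    "InverseLawFit",
    "AgeGradientFit",
    "ols_fit",
    "vif",
    "prune_collinear",
    "backward_step",
    "build_position_model",
    "fit_inverse_law",
    "fit_age_gradients",
    "latency_curve",
    "SPIKING_CANDIDATES",
    "POOLED_CANDIDATES",
]

VIF_THRESHOLD = 4.0
SCREEN_ALPHA = 0.05

#: candidate predictors when the analysis is restricted to spiking neurons
SPIKING_CANDIDATES = (
    "i_threshold", "v_threshold", "first_spike_latency", "ahp_tau",
    "resting_potential", "ap_height", "g_max", "g_minus30", "v_half",
    "tau_inact",
)
#: candidates when spiking and non-spiking neurons are pooled: only features
#: measurable without an action potential; response latency replaces current
#: threshold
POOLED_CANDIDATES = (
    "response_latency", "resting_potential", "g_max", "g_minus30", "v_half",
    "tau_inact",
)


@dataclass
class RegressionModel:
    variables: list
    beta: np.ndarray
    beta0: float
    vif: np.ndarray
    adj_r2: float
    rmse: float
    p_value: float
    n: int
    residuals: np.ndarray
    selection: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.vif = np.asarray(self.vif, dtype=float)
        if not (len(self.beta) == len(self.variables) == len(self.vif)):
            raise ValueError("variables, beta and vif must have equal length")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X, self.variables)
        return self.beta0 + X[self.variables].to_numpy() @ self.beta

    def to_json(self) -> str:
        return json.dumps({
            "variables": list(self.variables),
            "beta": self.beta.tolist(),
            "beta0": self.beta0,
            "vif": self.vif.tolist(),
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "p_value": self.p_value,
            "n": self.n,
            "selection": self.selection,
        }, indent=1, sort_keys=True)


@dataclass
class InverseLawFit:
    constant: float
    fit_r2: float


@dataclass
class AgeGradientFit:
    slope_modiolar: float
    intercept_modiolar: float
    slope_pillar: float
    intercept_pillar: float
    intersect_age: float | None = None

    def __post_init__(self):
        if self.intersect_age is not None and not 0.0 <= self.intersect_age <= 3.0:
            raise ValueError("intersect_age outside the [0, 3] constraint window")

    def gmax(self, age, face: str) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if face == "modiolar":
            return self.slope_modiolar * age + self.intercept_modiolar
        if face == "pillar":
            return self.slope_pillar * age + self.intercept_pillar
        raise ValueError(f"unknown face {face!r}")


def _as_frame(X, names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = names if names is not None else [f"x{i + 1}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(cols))


def ols_fit(X, y, rmse_population: bool = False) -> RegressionModel:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    RMSE uses residual degrees of freedom, sqrt(SSE/(n - p - 1)), by default;
    ``rmse_population=True`` switches to sqrt(SSE/n).
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values in the design")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than p + 1 = {p + 1} rows, got {n}")
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    sse = float(res.ssr)
    denom = n if rmse_population else n - p - 1
    return RegressionModel(
        variables=list(X.columns),
        beta=res.params[1:],
        beta0=float(res.params[0]),
        vif=vif(X) if p >= 2 else np.ones(p),
        adj_r2=float(res.rsquared_adj),
        rmse=float(np.sqrt(sse / denom)),
        p_value=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else np.nan,
        n=n,
        residuals=np.asarray(res.resid),
    )


def vif(X) -> np.ndarray:
    """Variance inflation factors, 1/(1 - R_n^2), one per column.

    R_n^2 is from regressing the n-th column on all the others (with
    intercept).  Perfectly collinear columns get infinite VIF.
    """
    X = _as_frame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    arr = X.to_numpy(dtype=float)
    out = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        others = sm.add_constant(np.delete(arr, j, axis=1), has_constant="add")
        r2 = sm.OLS(arr[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else max(1.0, 1.0 / (1.0 - r2))
    return out


def prune_collinear(X, threshold: float = VIF_THRESHOLD):
    """Iteratively drop the highest-VIF column until all VIFs <= threshold.

    Returns ``(retained_column_names, removal_log)`` where the log lists
    ``(name, vif_at_removal)`` in removal order.  A single surviving variable
    always passes.
    """
    X = _as_frame(X)
    cols = list(X.columns)
    removed = []
    while len(cols) >= 2:
        values = vif(X[cols])
        worst = int(np.argmax(values))
        if values[worst] <= threshold:
            break
        removed.append((cols[worst], float(values[worst])))
        cols.pop(worst)
    return cols, removed


def _objective(model: RegressionModel) -> tuple:
    # adjusted R^2 primary, lower RMSE as tie-break
    return (model.adj_r2, -model.rmse)


def backward_step(X, y) -> RegressionModel:
    """Backward elimination on adjusted R^2 (RMSE tie-break).

    At each round the variable whose removal gives the best objective is
    dropped if that beats the current model; stops otherwise, or at one
    remaining variable.  The final model is refit by :func:`ols_fit` and
    carries the removal log in ``selection``.
    """
    X = _as_frame(X)
    cols = list(X.columns)
    current = ols_fit(X[cols], y)
    dropped = []
    while len(cols) > 1:
        candidates = []
        for name in cols:
            trial = [c for c in cols if c != name]
            candidates.append((name, ols_fit(X[trial], y)))
        name, best = max(candidates, key=lambda kv: _objective(kv[1]))
        if _objective(best) > _objective(current):
            cols.remove(name)
            dropped.append(name)
            current = best
        else:
            break
    current.selection = dict(current.selection, backward_dropped=dropped)
    return current


def build_position_model(features: pd.DataFrame, subset: str = "spiking_only",
                         age_range: tuple = (3, 10),
                         screen_alpha: float = SCREEN_ALPHA,
                         min_neurons: int = 10) -> RegressionModel:
    """Full position-prediction pipeline on a per-neuron feature table.

    ``subset`` is ``"spiking_only"`` (spike-dependent candidates allowed) or
    ``"pooled"`` (spiking + non-spiking; candidates restricted to features
    measurable without an action potential, with response latency standing in
    for current threshold).  Type II neurons and neurons without a measured
    NBP are excluded; missing values are deleted list-wise within the final
    candidate set.
    """
    if subset not in ("spiking_only", "pooled"):
        raise ValueError("subset must be 'spiking_only' or 'pooled'")
    df = features.copy()
    if "fiber_type" in df.columns:
        df = df[df["fiber_type"] != "type_II"]
    df = df[df["nbp"].notna()]
    df = df[(df["age"] >= age_range[0]) & (df["age"] <= age_range[1])]
    if subset == "spiking_only":
        df = df[df["spiking"].astype(bool)]
        candidates = [c for c in SPIKING_CANDIDATES if c in df.columns]
    else:
        candidates = [c for c in POOLED_CANDIDATES if c in df.columns]

    screened, screen_log = [], {}
    for col in candidates:
        sub = df[[col, "nbp"]].dropna()
        if len(sub) < 3 or sub[col].nunique() < 2:
            continue
        r, p = _stats.pearsonr(sub[col], sub["nbp"])
        screen_log[col] = {"r": float(r), "p": float(p), "n": int(len(sub))}
        if p < screen_alpha:
            screened.append(col)
    if not screened:
        raise ValueError("no candidate feature is significantly correlated "
                         "with NBP")

    data = df[screened + ["nbp"]].dropna()
    if len(data) < min_neurons:
        raise ValueError(f"only {len(data)} complete neurons after filtering; "
                         f"need >= {min_neurons}")

    retained, vif_removed = prune_collinear(data[screened])
    # current threshold and response latency are reciprocally coupled (both
    # reflect the same input conductance), so a model never carries both:
    # when collinearity pruning leaves the pair, the one less correlated with
    # NBP is treated as redundant and eliminated
    latency_name = ("first_spike_latency" if subset == "spiking_only"
                    else "response_latency")
    if "i_threshold" in retained and latency_name in retained:
        weaker = min(("i_threshold", latency_name),
                     key=lambda c: abs(screen_log[c]["r"]))
        retained.remove(weaker)
        vif_removed.append((weaker, np.nan))
    model = backward_step(data[retained], data["nbp"].to_numpy())
    model.selection = dict(
        model.selection,
        subset=subset, age_range=list(age_range),
        screen=screen_log, screened_in=screened,
        vif_removed=[name for name, _ in vif_removed],
    )
    return model


def fit_inverse_law(x, y) -> InverseLawFit:
    """Least-squares constant K in y = K/x (closed form).

    Minimizing sum (y - K/x)^2 gives K = sum(y/x) / sum(1/x^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("reciprocal-law fit requires strictly positive x")
    k = float(np.sum(y / x) / np.sum(1.0 / x**2))
    resid = y - k / x
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    return InverseLawFit(constant=k, fit_r2=r2)


def fit_age_gradients(g_max, age, face, constraint_window: tuple = (0.0, 3.0),
                      grid_step: float = 0.1) -> AgeGradientFit:
    """Face-binned linear fits of steady-state conductance against age.

    The two face lines are fit jointly under the constraint that they
    intersect at some age inside ``constraint_window``: the intersection age
    is scanned on a grid, a weighted least-squares problem with a shared
    value at the intersection is solved at each candidate, and the candidate
    with minimal weighted SSE is kept.  Weights are 1/fitted^2 because the
    conductance dispersion is multiplicative (constant CV).
    """
    g_max = np.asarray(g_max, dtype=float)
    age = np.asarray(age, dtype=float)
    face = np.asarray(face)
    for f in ("modiolar", "pillar"):
        ages_f = np.unique(age[face == f])
        if ages_f.size < 3:
            raise ValueError(f"{f} face must be represented across >= 3 ages")

    mod = face == "modiolar"
    am, gm = age[mod], g_max[mod]
    ap, gp = age[~mod], g_max[~mod]

    def joint_fit(t):
        """Shared value g0 at the intersection age t, separate slopes.

        Weighted LS in (g0, b_m, b_p); weights refined from fitted values.
        """
        xm, xp = am - t, ap - t
        wm = np.ones_like(gm)
        wp = np.ones_like(gp)
        for _ in range(3):
            # normal equations for g = g0 + b_f * (age - t) per face
            a11 = wm.sum() + wp.sum()
            a12, a13 = wm @ xm, wp @ xp
            a22, a33 = wm @ xm**2, wp @ xp**2
            A = np.array([[a11, a12, a13], [a12, a22, 0.0], [a13, 0.0, a33]])
            rhs = np.array([wm @ gm + wp @ gp, wm @ (xm * gm), wp @ (xp * gp)])
            g0, bm, bp = np.linalg.solve(A, rhs)
            wm = 1.0 / np.maximum(g0 + bm * xm, 1.0) ** 2
            wp = 1.0 / np.maximum(g0 + bp * xp, 1.0) ** 2
        sse = float(wm @ (gm - g0 - bm * xm) ** 2 + wp @ (gp - g0 - bp * xp) ** 2)
        return sse, g0, bm, bp

    lo, hi = constraint_window
    best = None
    for t in np.arange(lo, hi + grid_step / 2, grid_step):
        sse, g0, bm, bp = joint_fit(t)
        if best is None or sse < best[0]:
            best = (sse, t, g0, bm, bp)
    _, t, g0, slope_m, slope_p = best
    return AgeGradientFit(
        slope_modiolar=float(slope_m), intercept_modiolar=float(g0 - slope_m * t),
        slope_pillar=float(slope_p), intercept_pillar=float(g0 - slope_p * t),
        intersect_age=float(t),
    )


def latency_curve(fit: AgeGradientFit, constant: float, age, face: str):
    """Developmental latency curve L(age) = K / g_max(age) for one face."""
    return constant / fit.gmax(age, face)
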