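"""Least-squares RT models and model comparison.

Reaction times (single-trial or median) are regressed on a statistical
predictor with either a straight line or a four-parameter logistic
(sigmoid), both by least squares; models and predictors are compared on
explained variance R^2 = 1 - RSS/TSS.  For nonlinear fits R^2 can be
negative and is reported as-is.

The sigmoid is fitted by multi-start nonlinear least squares: the
asymptotes start at the 5th/95th RT percentiles, the mid-point at the
predictor median, the slope at one sixth of the predictor range, plus a
fixed list of seeded jittered restarts; the lowest residual sum of squares
wins.  Any parameter (canonically the slope) can be held fixed.  Standard
errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .rt_synth import SigmoidParams

__all__ = [
    "FitResult",
    "fit_linear",
    "fit_sigmoid",
    "compare_predictors_trialwise",
    "compare_predictors_sessionwise",
    "blockwise_sigmoid",
    "median_rt",
    "ANALYSIS_WINDOW",
    "window_mask",
]

# Pooled-trial analysis window: skips the fast-changing early training
# blocks; trials 442..1078 inclusive equal blocks 10..22 of the standard
# 25x49 session.
ANALYSIS_WINDOW = (442, 1078)

SIGMOID_PARAM_NAMES = ("xhalf", "ymax", "ymin", "slope")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit."""

    function_kind: str                      # "linear" | "sigmoid"
    params: Mapping[str, float]
    r_squared: float
    rss: float
    n_points: int
    converged: bool
    param_se: Mapping[str, float] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=dict)
    orientation: str | None = None
    message: str = ""

    def sigmoid_params(self) -> SigmoidParams:
        if self.function_kind != "sigmoid":
            raise ValueError("not a sigmoid fit")
        return SigmoidParams(**{k: self.params[k] for k in SIGMOID_PARAM_NAMES})


def _r_squared(y: np.ndarray, resid: np.ndarray) -> tuple[float, float]:
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return r2, rss


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares line, closed form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x is constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2, rss = _r_squared(y, resid)
    # classical OLS standard errors
    dof = max(x.size - 2, 1)
    s2 = rss / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / x.size + x.mean() ** 2 / sxx))
    return FitResult(function_kind="linear",
                     params={"slope": float(slope), "intercept": float(intercept)},
                     r_squared=r2, rss=rss, n_points=int(x.size), converged=True,
                     param_se={"slope": float(se_slope),
                               "intercept": float(se_intercept)})


def _sigmoid_eval(x: np.ndarray, theta: np.ndarray, orientation: str) -> np.ndarray:
    xhalf, ymax, ymin, slope = theta
    sign = -1.0 if orientation == "increasing" else 1.0
    z = np.clip(sign * (x - xhalf) / slope, -500, 500)
    return ymin + (ymax - ymin) / (1.0 + np.exp(z))


def _initial_guesses(x: np.ndarray, y: np.ndarray, n_restarts: int,
                     restart_seed: int) -> list[np.ndarray]:
    ymax0 = float(np.percentile(y, 95))
    ymin0 = float(np.percentile(y, 5))
    if ymax0 <= ymin0:
        ymax0 = ymin0 + max(1e-6, abs(ymin0) * 1e-3 + 1e-6)
    xhalf0 = float(np.median(x))
    slope0 = float(np.ptp(x)) / 6.0 or 1.0
    base = np.array([xhalf0, ymax0, ymin0, slope0])
    guesses = [base]
    rng = np.random.default_rng(restart_seed)
    for _ in range(n_restarts):
        jit = base * (1.0 + rng.uniform(-0.3, 0.3, size=4))
        jit[0] = base[0] + rng.uniform(-0.5, 0.5) * (np.ptp(x) or 1.0)
        jit[3] = abs(jit[3]) or slope0
        if jit[1] <= jit[2]:
            jit[1], jit[2] = max(jit[1], jit[2]) + 1e-6, min(jit[1], jit[2])
        guesses.append(jit)
    return guesses


def fit_sigmoid(x, y, fixed: Mapping[str, float] | None = None,
                orientation: str = "increasing",
                n_restarts: int = 5, restart_seed: int = 1234) -> FitResult:
    """Four-parameter logistic fit by multi-start nonlinear least squares.

    ``fixed`` holds parameters at given values (e.g. ``{"slope": 1.0}`` for
    stable block-wise fits).  Non-convergence across all starts is flagged
    in ``converged``, never silently reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fixed = dict(fixed or {})
    n_free = 4 - len(fixed)
    if x.size < max(n_free, 3):
        raise ValueError(f"need at least {max(n_free, 3)} points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x spans zero range")
    if orientation not in ("increasing", "decreasing"):
        raise ValueError(f"bad orientation {orientation!r}")

    free_idx = [i for i, nm in enumerate(SIGMOID_PARAM_NAMES) if nm not in fixed]
    theta_full = np.zeros(4)
    for i, nm in enumerate(SIGMOID_PARAM_NAMES):
        if nm in fixed:
            theta_full[i] = fixed[nm]

    def residuals(free: np.ndarray) -> np.ndarray:
        th = theta_full.copy()
        th[free_idx] = free
        return _sigmoid_eval(x, th, orientation) - y

    best = None
    for guess in _initial_guesses(x, y, n_restarts, restart_seed):
        g = guess[free_idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.least_squares(residuals, g, method="lm",
                                             max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol

    if best is None:
        return FitResult(function_kind="sigmoid", params={}, r_squared=np.nan,
                         rss=np.nan, n_points=int(x.size), converged=False,
                         fixed=fixed, orientation=orientation,
                         message="all starts failed")

    theta = theta_full.copy()
    theta[free_idx] = best.x
    resid = best.fun
    r2, rss = _r_squared(y, resid)
    params = dict(zip(SIGMOID_PARAM_NAMES, map(float, theta)))

    # standard errors from the Jacobian at the optimum
    se = {}
    dof = max(x.size - len(free_idx), 1)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * rss / dof
        diag = np.clip(np.diag(cov), 0, None)
        for j, i in enumerate(free_idx):
            se[SIGMOID_PARAM_NAMES[i]] = float(np.sqrt(diag[j]))
    except np.linalg.LinAlgError:
        pass

    degenerate = params["ymax"] <= params["ymin"]
    return FitResult(function_kind="sigmoid", params=params, r_squared=r2,
                     rss=rss, n_points=int(x.size),
                     converged=bool(best.success and not degenerate),
                     param_se=se, fixed=fixed, orientation=orientation,
                     message="degenerate: ymax <= ymin" if degenerate else "")


def window_mask(trials: pd.DataFrame,
                window: tuple[int, int] | None = ANALYSIS_WINDOW,
                blocks: Sequence[int] | None = None) -> pd.Series:
    """Boolean mask selecting correct trials inside the analysis window
    (session-global trial indices, inclusive) or an explicit block range."""
    m = trials["correct"].astype(bool)
    if blocks is not None:
        m &= trials["block"].isin(list(blocks))
    elif window is not None:
        m &= trials["trial"].between(window[0], window[1])
    return m


def _grid_fit(x: np.ndarray, y: np.ndarray, function: str,
              orientation: str) -> float:
    try:
        if function == "linear":
            return fit_linear(x, y).r_squared
        res = fit_sigmoid(x, y, orientation=orientation)
        return res.r_squared if res.converged else np.nan
    except ValueError:
        return np.nan


def compare_predictors_trialwise(
    trials: pd.DataFrame,
    n_prev_range: Sequence[int] = (1, 2, 3, 4),
    window: tuple[int, int] | None = ANALYSIS_WINDOW,
) -> pd.DataFrame:
    """R^2 grid of {JP, CP} x {linear, sigmoid} x history length on
    single-trial RTs.

    ``trials`` must carry per-trial predictor columns ``jp_<k>`` / ``cp_<k>``
    for each history length ``k``.  Fits use correct trials in the pooled
    analysis window; every cell for a given ``k`` uses the identical point
    set.  Probability predictors use the decreasing sigmoid orientation.
    """
    m = window_mask(trials, window)
    if not m.any():
        raise ValueError("empty analysis window")
    rows = []
    for k in n_prev_range:
        jp_col, cp_col = f"jp_{k}", f"cp_{k}"
        if jp_col not in trials or cp_col not in trials:
            raise ValueError(f"trials lack predictor columns for n_prev={k}")
        sub = trials.loc[m, [jp_col, cp_col, "rt_ms"]].dropna()
        y = sub["rt_ms"].to_numpy()
        for pred, col in (("JP", jp_col), ("CP", cp_col)):
            x = sub[col].to_numpy()
            for fn in ("linear", "sigmoid"):
                rows.append({"predictor": pred, "function": fn, "n_prev": k,
                             "r_squared": _grid_fit(x, y, fn, "decreasing"),
                             "n_points": len(sub)})
    return pd.DataFrame(rows)


def compare_predictors_sessionwise(
    units: pd.DataFrame,
    n_prev_range: Sequence[int] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """R^2 grid of {JE, CE} x {linear, sigmoid} x history length on median
    RTs per unit (subject or session).

    ``units`` needs one row per unit with columns ``median_rt`` and
    ``je_<k>`` / ``ce_<k>`` per history length.  Entropy predictors use the
    increasing orientation.  Degenerate columns (constant predictor, e.g.
    CE of an all-deterministic sequence set) yield NaN cells, flagged not
    raised.
    """
    if len(units) < 4:
        raise ValueError("need at least 4 units for the session-wise grid")
    rows = []
    y = units["median_rt"].to_numpy(dtype=float)
    for k in n_prev_range:
        for pred in ("JE", "CE"):
            col = f"{pred.lower()}_{k}"
            if col not in units:
                raise ValueError(f"units lack column {col}")
            x = units[col].to_numpy(dtype=float)
            for fn in ("linear", "sigmoid"):
                rows.append({"predictor": pred, "function": fn, "n_prev": k,
                             "r_squared": _grid_fit(x, y, fn, "increasing"),
                             "n_points": len(units)})
    return pd.DataFrame(rows)


def median_rt(trials: pd.DataFrame, group_by: Sequence[str] | str,
              correct_only: bool = True) -> pd.DataFrame:
    """Median RT per grouping unit (correct trials only by default).

    Empty groups are omitted with a warning rather than erroring."""
    df = trials[trials["correct"].astype(bool)] if correct_only else trials
    if isinstance(group_by, str):
        group_by = [group_by]
    out = (df.groupby(list(group_by), observed=True)["rt_ms"]
             .median().rename("median_rt").reset_index())
    n_expected = trials.groupby(list(group_by), observed=True).ngroups
    if len(out) < n_expected:
        warnings.warn(f"{n_expected - len(out)} group(s) had no usable trials "
                      "and were omitted")
    return out


def blockwise_sigmoid(
    trials: pd.DataFrame,
    je_per_unit: Mapping | pd.Series,
    blocks: Sequence[int] = tuple(range(5, 23)),
    unit_col: str = "unit",
) -> pd.DataFrame:
    """Per-block sigmoid of median RT against joint entropy, slope fixed
    at 1.

    ``je_per_unit`` maps each unit (subject or session identifier in
    ``trials[unit_col]``) to the joint entropy of the sequence it trained.
    For every block the median correct-trial RT of each unit is fitted
    against these entropies with the increasing sigmoid; non-converged
    blocks are flagged (``converged=False``) so trajectory plots can drop
    them.  Returns one row per block with xhalf/ymax/ymin and standard
    errors.
    """
    je = pd.Series(dict(je_per_unit)) if not isinstance(je_per_unit, pd.Series) \
        else je_per_unit
    if je.nunique() < 4:
        raise ValueError("need at least 4 distinct joint entropy values")
    rows = []
    for b in blocks:
        sub = trials[(trials["block"] == b) & trials["correct"].astype(bool)]
        med = sub.groupby(unit_col, observed=True)["rt_ms"].median()
        med = med[med.index.isin(je.index)]
        x = je.loc[med.index].to_numpy(dtype=float)
        y = med.to_numpy(dtype=float)
        row = {"block": b, "n_units": len(med)}
        try:
            res = fit_sigmoid(x, y, fixed={"slope": 1.0},
                              orientation="increasing")
        except ValueError:
            res = None
        if res is None or not res.converged:
            row.update({"xhalf": np.nan, "ymax": np.nan, "ymin": np.nan,
                        "xhalf_se": np.nan, "ymax_se": np.nan, "ymin_se": np.nan,
                        "r_squared": np.nan, "converged": False})
        else:
            row.update({"xhalf": res.params["xhalf"], "ymax": res.params["ymax"],
                        "ymin": res.params["ymin"],
                        "xhalf_se": res.param_se.get("xhalf", np.nan),
                        "ymax_se": res.param_se.get("ymax", np.nan),
                        "ymin_se": res.param_se.get("ymin", np.nan),
                        "r_squared": res.r_squared, "converged": True})
        rows.append(row)
    return pd.DataFrame(rows)
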