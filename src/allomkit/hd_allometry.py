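"""Candidate height-diameter models, nonlinear fitting, and ranking.

Ten functional forms from the forest-science literature relate total tree
height H (m) to diameter at breast height D (cm).  All carry additive error
on the natural height scale, so every model — including the log-scale
quadratic, written H = exp(a + b·lnD + c·ln²D) + ε — is fitted by
unweighted nonlinear least squares on untransformed heights.

Selection statistics follow the mainstream conventions:

* RSE = sqrt(SSE / (N − K)) with K the number of regression parameters;
* adjusted pseudo-R² = R² − ((K − 1)/(N − K))·(1 − R²), R² = 1 − SSE/SST;
* AIC = 2k − 2 lnL with a Gaussian likelihood, counting the error variance
  as an estimated parameter (k = K + 1) by default.

Models are ranked lexicographically: adjusted pseudo-R² descending, then
RSE ascending, then AIC ascending; non-converged fits sort last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data_model_io import DataError, ForestDataset

__all__ = [
    "HDModelSpec",
    "HDFit",
    "FitOptions",
    "model_registry",
    "get_model",
    "fit_model",
    "fit_all_models",
    "aic",
    "adj_pseudo_r2",
    "rank_models",
    "ranking_table",
]

MODEL_ORDER = (
    "quadratic",
    "michaelis_menten",
    "weibull",
    "exp3",
    "exp2",
    "gompertz",
    "power",
    "mod_exp2",
    "logistic",
    "log_linear",
)


@dataclass(frozen=True)
class HDModelSpec:
    """A candidate height-diameter functional form."""

    name: str
    arity: int
    form: Callable[[np.ndarray, np.ndarray], np.ndarray]  # (params, D) -> H
    init: Callable[[np.ndarray, np.ndarray], np.ndarray]  # (D, H) -> start params
    description: str = ""
    monotone_domain: Callable[[np.ndarray], tuple[float, float]] | None = None

    def __call__(self, params: Sequence[float], dbh) -> np.ndarray:
        return self.form(np.asarray(params, dtype=float), np.asarray(dbh, dtype=float))


# ---------------------------------------------------------------------------
# model forms


def _f_quadratic(p, D):
    lnD = np.log(D)
    return np.exp(p[0] + p[1] * lnD + p[2] * lnD**2)


def _f_mm(p, D):
    return p[0] * D / (p[1] + D)


def _f_weibull(p, D):
    return p[0] * (1.0 - np.exp(-p[1] * D ** p[2]))


def _f_exp3(p, D):
    return p[0] - p[1] * np.exp(-p[2] * D)


def _f_exp2(p, D):
    return p[0] * (1.0 - np.exp(-p[1] * D))


def _f_gompertz(p, D):
    return p[0] * np.exp(-p[1] * np.exp(-p[2] * D))


def _f_power(p, D):
    return p[0] * D ** p[1]


def _f_mod_exp2(p, D):
    return p[0] * np.exp(p[1] / D)


def _f_logistic(p, D):
    return p[0] / (1.0 + p[1] * np.exp(-p[2] * D))


def _f_log_linear(p, D):
    return p[0] + p[1] * np.log(D)


# ---------------------------------------------------------------------------
# deterministic, data-driven starting values


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _i_quadratic(D, H):
    lnD = np.log(D)
    lnH = np.log(np.clip(H, 0.1, None))
    return _ols(np.column_stack([np.ones_like(lnD), lnD, lnD**2]), lnH)


def _i_mm(D, H):
    # Lineweaver-Burk linearization: 1/H = 1/a + (b/a)(1/D)
    a0 = 1.05 * H.max()
    beta = _ols(np.column_stack([np.ones_like(D), 1.0 / D]), 1.0 / np.clip(H, 0.1, None))
    if beta[0] > 0:
        a_lb = 1.0 / beta[0]
        b0 = beta[1] * a_lb
    else:
        b0 = np.median(D)
    return np.array([a0, max(b0, 1e-3)])


def _sat_y(D, H, a0):
    frac = np.clip(H / a0, 1e-6, 1 - 1e-6)
    return -np.log(1.0 - frac)


def _i_weibull(D, H):
    a0 = 1.05 * H.max()
    y = np.log(_sat_y(D, H, a0))
    beta = _ols(np.column_stack([np.ones_like(D), np.log(D)]), y)
    return np.array([a0, max(math.exp(beta[0]), 1e-6), np.clip(beta[1], 0.05, 3.0)])


def _i_exp3(D, H):
    a0 = 1.05 * H.max()
    b0 = max(a0 - H.min(), 1e-3)
    z = np.log(np.clip((a0 - H) / b0, 1e-6, None))
    c0 = max(-_ols(D[:, None], z)[0], 1e-4)
    return np.array([a0, b0, c0])


def _i_exp2(D, H):
    a0 = 1.05 * H.max()
    y = _sat_y(D, H, a0)
    return np.array([a0, max(np.median(y / D), 1e-4)])


def _i_gompertz(D, H):
    a0 = 1.05 * H.max()
    z = np.log(np.clip(np.log(a0 / np.clip(H, 0.1, None)), 1e-6, None))
    beta = _ols(np.column_stack([np.ones_like(D), D]), z)
    return np.array([a0, max(math.exp(beta[0]), 1e-3), max(-beta[1], 1e-4)])


def _i_power(D, H):
    beta = _ols(np.column_stack([np.ones_like(D), np.log(D)]),
                np.log(np.clip(H, 0.1, None)))
    return np.array([math.exp(beta[0]), beta[1]])


def _i_mod_exp2(D, H):
    beta = _ols(np.column_stack([np.ones_like(D), 1.0 / D]),
                np.log(np.clip(H, 0.1, None)))
    return np.array([math.exp(beta[0]), beta[1]])


def _i_logistic(D, H):
    a0 = 1.05 * H.max()
    z = np.log(np.clip(a0 / np.clip(H, 0.1, None) - 1.0, 1e-6, None))
    beta = _ols(np.column_stack([np.ones_like(D), D]), z)
    return np.array([a0, max(math.exp(beta[0]), 1e-3), max(-beta[1], 1e-4)])


def _i_log_linear(D, H):
    return _ols(np.column_stack([np.ones_like(D), np.log(D)]), H)


def _dom_quadratic(p):
    # H rises up to D* = exp(-b/(2c)) when the curvature c is negative
    if p[2] < 0:
        return (0.0, float(np.exp(-p[1] / (2.0 * p[2]))))
    return (0.0, float("inf"))


def _dom_all(_p):
    return (0.0, float("inf"))


def _dom_mod_exp2(p):
    # increasing on (0, inf) when b < 0
    return (0.0, float("inf")) if p[1] < 0 else (float("inf"), float("inf"))


_REGISTRY: tuple[HDModelSpec, ...] = (
    HDModelSpec("quadratic", 3, _f_quadratic, _i_quadratic,
                "H = exp(a + b lnD + c ln²D) + ε", _dom_quadratic),
    HDModelSpec("michaelis_menten", 2, _f_mm, _i_mm,
                "H = a·D/(b + D) + ε", _dom_all),
    HDModelSpec("weibull", 3, _f_weibull, _i_weibull,
                "H = a(1 − exp(−b·D^c)) + ε", _dom_all),
    HDModelSpec("exp3", 3, _f_exp3, _i_exp3,
                "H = a − b·exp(−c·D) + ε", _dom_all),
    HDModelSpec("exp2", 2, _f_exp2, _i_exp2,
                "H = a(1 − exp(−b·D)) + ε", _dom_all),
    HDModelSpec("gompertz", 3, _f_gompertz, _i_gompertz,
                "H = a·exp(−b·exp(−c·D)) + ε", _dom_all),
    HDModelSpec("power", 2, _f_power, _i_power,
                "H = a·D^b + ε", _dom_all),
    HDModelSpec("mod_exp2", 2, _f_mod_exp2, _i_mod_exp2,
                "H = a·exp(b/D) + ε", _dom_mod_exp2),
    HDModelSpec("logistic", 3, _f_logistic, _i_logistic,
                "H = a/(1 + b·exp(−c·D)) + ε", _dom_all),
    HDModelSpec("log_linear", 2, _f_log_linear, _i_log_linear,
                "H = a + b·lnD + ε", _dom_all),
)


def model_registry() -> tuple[HDModelSpec, ...]:
    """The ten candidate models, in canonical order."""
    return _REGISTRY


def get_model(name: str) -> HDModelSpec:
    for spec in _REGISTRY:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown height-diameter model {name!r}; "
                   f"choose from {', '.join(MODEL_ORDER)}")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    max_iter: int = 2000
    tol: float = 1e-14        # ftol/xtol/gtol for the LM solver
    restarts: int = 5
    seed: int = 0             # jitter stream for restarts
    min_dbh: float | None = None
    count_sigma_in_k: bool = True  # AIC parameter count k = arity + 1


@dataclass
class HDFit:
    """A fitted height-diameter model with its selection statistics."""

    spec: HDModelSpec
    params: np.ndarray
    param_se: np.ndarray
    rse: float
    adj_pseudo_r2: float
    aic: float
    n: int
    converged: bool
    residuals: np.ndarray
    sse: float = field(default=float("nan"))
    loglik: float = field(default=float("nan"))
    message: str = ""

    def predict(self, dbh) -> np.ndarray:
        return self.spec(self.params, dbh)

    @property
    def name(self) -> str:
        return self.spec.name


def _gaussian_loglik(n: int, sse: float) -> float:
    return -0.5 * n * (math.log(2.0 * math.pi) + math.log(sse / n) + 1.0)


def aic(fit: HDFit, count_sigma_in_k: bool = True) -> float:
    """AIC = 2k − 2 lnL; k counts regression parameters plus, by default,
    the Gaussian error variance."""
    if not fit.converged:
        raise DataError(f"{fit.name}: AIC undefined for a non-converged fit")
    k = fit.spec.arity + (1 if count_sigma_in_k else 0)
    return 2.0 * k - 2.0 * fit.loglik


def adj_pseudo_r2(r2: float, n: int, k: int) -> float:
    """Adjusted pseudo-R²: R² − ((K−1)/(N−K))·(1 − R²)."""
    if n <= k:
        raise DataError("adjusted pseudo-R² requires N > K")
    return r2 - ((k - 1) / (n - k)) * (1.0 - r2)


def fit_model(ds: ForestDataset, spec: HDModelSpec | str,
              options: FitOptions | None = None) -> HDFit:
    """Fit one model by iterative nonlinear least squares on (D, H) pairs.

    Minimizes Σ(H − f(θ, D))² on the untransformed height scale.  The
    deterministic data-driven start is followed by up to ``restarts``
    jittered restarts; the best optimum is kept.  Non-convergence is
    reported via ``converged=False``, never by raising.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    opt = options or FitOptions()
    pairs = [(r.dbh, r.height) for r in ds.records
             if r.height is not None and (opt.min_dbh is None or r.dbh >= opt.min_dbh)]
    if len(pairs) < spec.arity + 2:
        raise DataError(f"{spec.name}: need ≥ {spec.arity + 2} trees with height, "
                        f"got {len(pairs)}")
    D = np.array([p[0] for p in pairs], dtype=float)
    H = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(H) == 0.0:
        raise DataError(f"{spec.name}: heights are constant; degenerate data")
    n = len(D)

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            r = spec.form(theta, D) - H
        return np.where(np.isfinite(r), r, 1e6)

    x0 = np.asarray(spec.init(D, H), dtype=float)
    rng = np.random.default_rng(opt.seed)
    best = None
    starts = [x0]
    for _ in range(opt.restarts):
        starts.append(x0 * (1.0 + 0.3 * rng.standard_normal(x0.shape))
                      + 0.01 * rng.standard_normal(x0.shape))
    for start in starts:
        try:
            sol = least_squares(resid, start, method="lm",
                                xtol=opt.tol, ftol=opt.tol, gtol=opt.tol,
                                max_nfev=opt.max_iter)
        except Exception:  # singular Jacobian at a bad start, keep trying
            continue
        # prefer the deterministic start on (floating-point) ties
        if best is None or sol.cost < best.cost * (1.0 - 1e-12):
            best = sol
    if best is None:
        nan = np.full(spec.arity, np.nan)
        return HDFit(spec, nan, nan, float("nan"), float("nan"), float("nan"),
                     n, False, np.full(n, np.nan), message="all starts failed")

    theta = best.x
    res = spec.form(theta, D) - H
    sse = float(res @ res)
    k = spec.arity
    rse = math.sqrt(sse / (n - k))
    sst = float(np.sum((H - H.mean()) ** 2))
    r2 = 1.0 - sse / sst
    adj = adj_pseudo_r2(r2, n, k)
    loglik = _gaussian_loglik(n, sse) if sse > 0 else float("inf")
    # parameter covariance from the Gauss-Newton Hessian approximation
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * sse / (n - k)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    converged = bool(best.status > 0 and np.all(np.isfinite(theta)))
    fit = HDFit(spec, theta, se, rse, adj, float("nan"), n, converged, res,
                sse=sse, loglik=loglik, message=best.message)
    if converged and sse > 0:
        fit.aic = aic(fit, opt.count_sigma_in_k)
    return fit


def fit_all_models(ds: ForestDataset, options: FitOptions | None = None,
                   names: Sequence[str] | None = None) -> list[HDFit]:
    specs = [get_model(n) for n in names] if names else list(model_registry())
    return [fit_model(ds, s, options) for s in specs]


def rank_models(fits: Sequence[HDFit]) -> list[HDFit]:
    """Rank by adjusted pseudo-R² (desc), then RSE (asc), then AIC (asc);
    non-converged fits rank last."""
    if not fits:
        raise DataError("rank_models: no fits supplied")

    def key(f: HDFit):
        if not f.converged:
            return (1, 0.0, 0.0, 0.0)
        return (0, -f.adj_pseudo_r2, f.rse, f.aic)

    return sorted(fits, key=key)


def ranking_table(fits: Sequence[HDFit]):
    """Ranked selection statistics as a DataFrame mirroring the standard
    model-selection table layout (one row per parameter)."""
    import pandas as pd

    rows = []
    for rank, f in enumerate(rank_models(fits), start=1):
        for i, pname in enumerate("abc"[: f.spec.arity]):
            rows.append({
                "rank": rank,
                "model": f.name,
                "parameter": pname,
                "estimate": f.params[i] if f.converged else float("nan"),
                "se": f.param_se[i] if f.converged else float("nan"),
                "rse": f.rse if i == 0 else float("nan"),
                "adj_pseudo_r2": f.adj_pseudo_r2 if i == 0 else float("nan"),
                "aic": f.aic if i == 0 else float("nan"),
                "n": f.n,
                "converged": f.converged,
            })
    return pd.DataFrame(rows)
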