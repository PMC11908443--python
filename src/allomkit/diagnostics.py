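"""Observed-vs-predicted validation and taxonomic/phylogenetic diagnostics.

Three families of checks on a fitted height model:

* **Graybill's test** — a simultaneous F test that the OLS regression of
  observed on predicted heights has intercept 0 and slope 1,
  F = (β̂−θ)ᵀ XᵀX (β̂−θ) / (2·MSE) on (2, n−2) df.

* **Theil-style error decomposition** — the total squared prediction error
  Σ(obs−pred)² splits exactly into a bias term n(ō−p̄)², a consistency
  (slope) term (b̂−1)²·Σ(pred−p̄)², and the residual lack-of-fit of the
  obs-on-pred regression.  Bias and consistency are each F-tested (1 df)
  against the regression residual MS; the overall model lack-of-fit tests
  SS_total/n against the same MS on (n, n−2) df; the regression
  lack-of-fit component is probed for curvature (non-linear deviation) by
  adding a quadratic term to the obs-on-pred regression.

* **Species / phylogeny effects** — a linear mixed model of H on lnD
  (optionally ln²D) with a species random intercept, summarized by
  marginal and conditional R² (fixed vs fixed+random variance shares),
  and phylogenetic generalized least squares of per-species maxima under
  a Brownian-motion covariance, with an optional Pagel's λ signal
  estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_model_io import DataError, ForestDataset

__all__ = [
    "ObsPredRegression",
    "TheilDecomposition",
    "MixedFitResult",
    "PGLSResult",
    "obs_vs_pred",
    "graybill_test",
    "theil_decomposition",
    "fit_species_mixed",
    "taxon_maxima",
    "phylo_covariance",
    "pgls_fit",
    "pagel_lambda",
]


@dataclass
class ObsPredRegression:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    residual_ms: float
    n: int
    pred: np.ndarray
    obs: np.ndarray


def obs_vs_pred(obs, pred) -> ObsPredRegression:
    """OLS of observed values on predicted values."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise DataError("obs and pred must have equal length")
    n = obs.size
    if n < 3:
        raise DataError("obs_vs_pred needs at least 3 pairs")
    if np.ptp(pred) == 0.0:
        raise DataError("predicted values are constant; regression is degenerate")
    X = sm.add_constant(pred)
    res = sm.OLS(obs, X).fit()
    return ObsPredRegression(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        intercept_se=float(res.bse[0]), slope_se=float(res.bse[1]),
        residual_ms=float(res.ssr / (n - 2)), n=n, pred=pred, obs=obs,
    )


def graybill_test(reg: ObsPredRegression) -> tuple[float, float]:
    """Simultaneous F test of H0: (intercept, slope) = (0, 1)."""
    X = np.column_stack([np.ones(reg.n), reg.pred])
    delta = np.array([reg.intercept, reg.slope - 1.0])
    num = float(delta @ (X.T @ X) @ delta)
    # exact obs ≡ pred leaves both numerator and MSE at rounding level
    scale = float(np.sum(reg.obs**2)) + 1e-300
    if reg.residual_ms <= 1e-14 * scale / reg.n:
        return (0.0, 1.0) if num <= 1e-14 * scale else (float("inf"), 0.0)
    F = num / (2.0 * reg.residual_ms)
    p = float(stats.f.sf(F, 2, reg.n - 2))
    return F, p


@dataclass
class TheilDecomposition:
    ss_total_lack_of_fit: float
    ss_bias: float
    ss_consistency: float
    ss_regression_lack_of_fit: float
    f_model: float
    p_model: float
    f_bias: float
    p_bias: float
    f_consistency: float
    p_consistency: float
    f_regression: float
    p_regression: float
    n: int

    component_names = ("model lack-of-fit", "no bias", "consistency",
                       "regression lack-of-fit")


def theil_decomposition(obs, pred) -> TheilDecomposition:
    """Partition Σ(obs−pred)² into bias, consistency and residual terms."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    n = obs.size
    if n <= 3:
        raise DataError("theil_decomposition needs n > 3")
    reg = obs_vs_pred(obs, pred)
    ss_total = float(np.sum((obs - pred) ** 2))
    ss_bias = n * (obs.mean() - pred.mean()) ** 2
    ss_cons = (reg.slope - 1.0) ** 2 * float(np.sum((pred - pred.mean()) ** 2))
    ss_resid = reg.residual_ms * (n - 2)
    mse = reg.residual_ms
    if mse == 0.0:
        zero = TheilDecomposition(ss_total, ss_bias, ss_cons, ss_resid,
                                  0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, n)
        return zero
    f_bias = ss_bias / mse
    f_cons = ss_cons / mse
    f_model = (ss_total / n) / mse
    # curvature probe for non-linear deviations of obs about the fitted line
    X2 = np.column_stack([np.ones(n), pred, pred**2])
    res2 = sm.OLS(obs, X2).fit()
    ss_drop = ss_resid - float(res2.ssr)
    mse2 = float(res2.ssr) / (n - 3)
    f_regr = ss_drop / mse2 if mse2 > 0 else 0.0
    return TheilDecomposition(
        ss_total_lack_of_fit=ss_total, ss_bias=ss_bias, ss_consistency=ss_cons,
        ss_regression_lack_of_fit=ss_resid,
        f_model=f_model, p_model=float(stats.f.sf(f_model, n, n - 2)),
        f_bias=f_bias, p_bias=float(stats.f.sf(f_bias, 1, n - 2)),
        f_consistency=f_cons, p_consistency=float(stats.f.sf(f_cons, 1, n - 2)),
        f_regression=f_regr, p_regression=float(stats.f.sf(f_regr, 1, n - 3)),
        n=n,
    )


# ---------------------------------------------------------------------------
# species random effects


@dataclass
class MixedFitResult:
    fixed_effects: dict[str, float]
    species_variance: float
    residual_variance: float
    r2_marginal: float
    r2_conditional: float
    aic: float
    n: int
    n_species: int


def fit_species_mixed(ds: ForestDataset, form: str = "log_linear") -> MixedFitResult:
    """Linear mixed model of H on lnD (and ln²D) with a species random
    intercept, fitted by REML.

    Marginal and conditional R² follow the variance-share formulation:
    R²m = σ²_fixed / (σ²_fixed + σ²_species + σ²_resid) and
    R²c = (σ²_fixed + σ²_species) / (same denominator), where σ²_fixed is
    the population variance of the fixed-effect predictions.
    """
    if form not in ("log_linear", "quadratic_lnD"):
        raise ValueError("form must be 'log_linear' or 'quadratic_lnD'")
    rows = [(r.binomial, r.dbh, r.height) for r in ds.records
            if r.height is not None and r.is_identified]
    df = pd.DataFrame(rows, columns=["species", "dbh", "height"])
    counts = df.groupby("species").size()
    usable = counts[counts >= 2]
    if len(usable) < 2:
        raise DataError(
            "need ≥2 species with ≥2 trees each; fit a fixed-effects model instead"
        )
    df["lnD"] = np.log(df["dbh"])
    df["lnD2"] = df["lnD"] ** 2
    formula = "height ~ lnD" if form == "log_linear" else "height ~ lnD + lnD2"
    model = smf.mixedlm(formula, df, groups=df["species"])
    res = model.fit(reml=True)
    sigma2_species = float(res.cov_re.iloc[0, 0])
    sigma2_resid = float(res.scale)
    fixed_pred = np.asarray(res.model.exog @ res.fe_params)
    sigma2_fixed = float(np.var(fixed_pred))
    denom = sigma2_fixed + sigma2_species + sigma2_resid
    r2m = sigma2_fixed / denom
    r2c = (sigma2_fixed + sigma2_species) / denom
    return MixedFitResult(
        fixed_effects={k: float(v) for k, v in res.fe_params.items()},
        species_variance=sigma2_species,
        residual_variance=sigma2_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        aic=float(res.aic) if res.aic is not None else float("nan"),
        n=len(df),
        n_species=int(df["species"].nunique()),
    )


def taxon_maxima(ds: ForestDataset) -> pd.DataFrame:
    """Per-species maximum observed diameter and height (indet excluded).

    Maxima are per-trait: Dmax and Hmax may come from different stems.
    """
    rows = [(r.binomial, r.dbh, r.height) for r in ds.records
            if r.height is not None and r.is_identified]
    if not rows:
        return pd.DataFrame(columns=["species", "dmax", "hmax"]).set_index("species")
    df = pd.DataFrame(rows, columns=["species", "dbh", "height"])
    out = df.groupby("species").agg(dmax=("dbh", "max"), hmax=("height", "max"))
    return out


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSResult:
    coefficients: np.ndarray
    coef_se: np.ndarray
    rse: float
    adj_pseudo_r2: float
    aic: float
    lam: float | None
    n: int


def phylo_covariance(tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C[i,j] = shared root-to-MRCA path length.

    ``tree`` is a dendropy Tree with positive branch lengths; taxa are
    matched against tip labels.
    """
    tip = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label:
            tip[label] = leaf
    missing = [t for t in taxa if t not in tip]
    if missing:
        raise DataError(f"taxa missing from the phylogeny: {missing}")
    depth: dict[int, float] = {}

    def node_depth(node):
        key = id(node)
        if key not in depth:
            depth[key] = (0.0 if node.parent_node is None
                          else node_depth(node.parent_node) + (node.edge.length or 0.0))
        return depth[key]

    # ancestor sets for MRCA lookup
    anc: dict[str, list] = {}
    for t in taxa:
        chain = []
        node = tip[t]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[t] = chain
    C = np.empty((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        C[i, i] = node_depth(tip[ti])
        set_i = {id(x) for x in anc[ti]}
        for j in range(i + 1, len(taxa)):
            mrca = next(x for x in anc[taxa[j]] if id(x) in set_i)
            C[i, j] = C[j, i] = node_depth(mrca)
    return C


def pgls_fit(maxima: pd.DataFrame, tree=None, form: str = "quadratic_lnD",
             covariance: np.ndarray | None = None,
             lam: float | None = None) -> PGLSResult:
    """GLS of Hmax on lnDmax (and ln²Dmax) under a phylogenetic covariance.

    Pass either a dendropy ``tree`` or a precomputed ``covariance``
    (identity reproduces OLS exactly).  ``lam`` scales the off-diagonal
    covariance (Pagel's λ); None keeps the Brownian matrix as-is.
    """
    taxa = list(maxima.index)
    n = len(taxa)
    if n < 4:
        raise DataError("pgls_fit needs at least 4 taxa")
    if covariance is None:
        if tree is None:
            raise ValueError("supply a tree or a covariance matrix")
        covariance = phylo_covariance(tree, taxa)
    C = np.array(covariance, dtype=float)
    if lam is not None:
        off = ~np.eye(n, dtype=bool)
        C = C.copy()
        C[off] *= lam
    if not np.allclose(C, C.T):
        raise DataError("covariance matrix must be symmetric")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise DataError("covariance matrix is singular or not positive definite")
    lnD = np.log(maxima["dmax"].to_numpy(dtype=float))
    y = maxima["hmax"].to_numpy(dtype=float)
    X = (np.column_stack([np.ones(n), lnD, lnD**2]) if form == "quadratic_lnD"
         else np.column_stack([np.ones(n), lnD]))
    k = X.shape[1]
    res = sm.GLS(y, X, sigma=C).fit()
    resid = y - X @ res.params
    Cinv = np.linalg.inv(C)
    sse = float(resid @ Cinv @ resid)  # generalized SSE
    rse = math.sqrt(sse / (n - k))
    # pseudo-R² against the GLS intercept-only model
    res0 = sm.GLS(y, np.ones((n, 1)), sigma=C).fit()
    resid0 = y - np.full(n, float(res0.params[0]))
    sst = float(resid0 @ Cinv @ resid0)
    r2 = 1.0 - sse / sst
    adj = r2 - ((k - 1) / (n - k)) * (1.0 - r2)
    sign, logdet = np.linalg.slogdet(C)
    loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sse / n) + logdet + n)
    aic_value = 2.0 * (k + 1) - 2.0 * loglik
    return PGLSResult(
        coefficients=np.asarray(res.params), coef_se=np.asarray(res.bse),
        rse=rse, adj_pseudo_r2=adj, aic=aic_value, lam=lam, n=n,
    )


def pagel_lambda(maxima: pd.DataFrame, tree, form: str = "quadratic_lnD") -> float:
    """Maximum-likelihood Pagel's λ on [0, 1] for the PGLS residuals."""
    taxa = list(maxima.index)
    C = phylo_covariance(tree, taxa)
    n = len(taxa)
    lnD = np.log(maxima["dmax"].to_numpy(dtype=float))
    y = maxima["hmax"].to_numpy(dtype=float)
    X = (np.column_stack([np.ones(n), lnD, lnD**2]) if form == "quadratic_lnD"
         else np.column_stack([np.ones(n), lnD]))

    def negloglik(lam):
        Cl = C.copy()
        off = ~np.eye(n, dtype=bool)
        Cl[off] *= lam
        try:
            L = np.linalg.cholesky(Cl)
        except np.linalg.LinAlgError:
            return 1e12
        Cinv = np.linalg.inv(Cl)
        beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ y)
        r = y - X @ beta
        sse = float(r @ Cinv @ r)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return 0.5 * (n * math.log(2 * math.pi) + n * math.log(sse / n) + logdet + n)

    res = minimize_scalar(negloglik, bounds=(1e-6, 1.0), method="bounded")
    return float(res.x)
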