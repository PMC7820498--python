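"""Pedigree-based quantitative genetics on derived phenotypes.

Univariate and bivariate animal models estimate additive-genetic and
residual (co)variances by AI-REML with the pedigree relationship matrix
entering through its sparse inverse.  Derived quantities:

* heritability ``h2 = sigma2_a / (sigma2_a + sigma2_e)`` per trait,
* genetic correlation ``r_A = sigma_a12 / sqrt(sigma2_a1 sigma2_a2)``,
* phenotypic correlation
  ``r_P = (sigma_a12 + sigma_e12) / sqrt(p1 p2)`` with
  ``p_t = sigma2_at + sigma2_et``,

with standard errors by the delta method from the inverse
average-information matrix.  Significance uses a two-tailed Student t on
``estimate/SE`` (residual degrees of freedom) and, for the animal
variance itself, a likelihood-ratio test against the no-animal model
with the 50:50 chi-square mixture null that accounts for the zero
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .mixedmodel import (
    MixedModelFit,
    MultiTraitResidual,
    RandomTerm,
    design_from_factors,
    fit_reml,
)
from .pedigree import Pedigree, build_a_inverse

__all__ = [
    "GeneticEstimate",
    "reml_univariate",
    "reml_bivariate",
    "significance",
]


@dataclass
class GeneticEstimate:
    """REML variance components and derived genetic parameters."""

    traits: tuple[str, ...]
    g: np.ndarray            # additive-genetic (co)variance matrix
    e: np.ndarray            # residual (co)variance matrix
    h2: np.ndarray           # per trait
    se_h2: np.ndarray
    r_a: float | None = None
    se_ra: float | None = None
    r_p: float | None = None
    se_rp: float | None = None
    loglik: float = np.nan
    loglik_no_animal: float | None = None
    lrt: float | None = None
    p_lrt: float | None = None
    p_h2: np.ndarray | None = None
    p_ra: float | None = None
    p_rp: float | None = None
    df_resid: int = 0
    n_obs: int = 0
    boundary: bool = False
    converged: bool = True
    clamped: bool = False    # |r| > 1 from rounding was clamped
    fit: MixedModelFit | None = field(default=None, repr=False)

    def stars(self, p: float | None) -> str:
        return "*" if p is not None and p < 0.01 else ""

    def summary_row(self, season: str = "") -> dict:
        row = {"trait": "-".join(self.traits), "season": season}
        for t, h, s, p in zip(self.traits, self.h2, self.se_h2,
                              self.p_h2 if self.p_h2 is not None
                              else [None] * len(self.h2)):
            row[f"h2_{t}"] = h
            row[f"se_h2_{t}"] = s
            row[f"stars_h2_{t}"] = self.stars(p)
        if self.r_a is not None:
            row.update(rA=self.r_a, se_rA=self.se_ra,
                       stars_rA=self.stars(self.p_ra),
                       rP=self.r_p, se_rP=self.se_rp,
                       stars_rP=self.stars(self.p_rp))
        return row


def _t_pvalue(estimate: float, se: float, df: int) -> float | None:
    if se is None or not np.isfinite(se) or se <= 0:
        return None
    t = estimate / se
    return float(2.0 * stats.t.sf(abs(t), max(df, 1)))


def _animal_term(df: pd.DataFrame, pedigree: Pedigree, ainv, m: int,
                 trait_col: np.ndarray | None, k_start=None) -> RandomTerm:
    groups = np.array([pedigree.index_of(a) for a in df["animal_id"]],
                      dtype=np.int64)
    if m == 1:
        design = np.ones((len(df), 1))
    else:
        design = np.zeros((len(df), m))
        design[np.arange(len(df)), trait_col] = 1.0
    return RandomTerm(
        name="animal", groups=groups, design=design,
        n_levels=len(pedigree), corr_inv=ainv,
        corr_logdet=pedigree.log_det_a(), k_start=k_start)


def reml_univariate(
    data: pd.DataFrame,
    pedigree: Pedigree,
    response: str = "value",
    fixed_factors: list[str] = (),
    fixed_covariates: list[str] = (),
    ainv: sp.spmatrix | None = None,
    lrt: bool = True,
    trait_name: str | None = None,
) -> GeneticEstimate:
    """Single-trait animal model: ``y = Xb + a + e``, ``a ~ N(0, A sigma2_a)``.

    ``data`` must contain ``animal_id``, the response column, and any
    fixed-effect columns; every phenotyped animal must be in the
    pedigree.
    """
    if ainv is None:
        ainv = build_a_inverse(pedigree)
    y = np.asarray(data[response], dtype=float)
    x, _ = design_from_factors(data, list(fixed_factors),
                               list(fixed_covariates))
    term = _animal_term(data, pedigree, ainv, 1, None,
                        k_start=np.array([[0.3 * np.var(y)]]))
    fit = fit_reml(y, x, [term])
    s2a = float(fit.k_hats[0][0, 0])
    s2e = float(fit.r_hat[0, 0])
    tot = s2a + s2e
    h2 = s2a / tot
    grad = np.array([s2e, -s2a]) / tot**2
    se_h2 = float(np.sqrt(max(grad @ fit.theta_cov @ grad, 0.0)))
    df_resid = fit.n_obs - fit.rank_x
    est = GeneticEstimate(
        traits=(trait_name or response,),
        g=np.array([[s2a]]), e=np.array([[s2e]]),
        h2=np.array([h2]), se_h2=np.array([se_h2]),
        p_h2=np.array([_t_pvalue(h2, se_h2, df_resid)], dtype=object),
        loglik=fit.loglik, df_resid=df_resid, n_obs=fit.n_obs,
        boundary=fit.boundary, converged=fit.converged, fit=fit)
    if lrt:
        null_fit = fit_reml(y, x, [])
        est = significance(est, fit.loglik, null_fit.loglik)
    return est


def reml_bivariate(
    data1: pd.DataFrame,
    data2: pd.DataFrame,
    pedigree: Pedigree,
    response: str = "value",
    fixed_factors: list[str] = (),
    fixed_covariates: list[str] = (),
    ainv: sp.spmatrix | None = None,
    trait_names: tuple[str, str] = ("trait1", "trait2"),
) -> GeneticEstimate:
    """Two-trait animal model with unstructured 2x2 G and R.

    The two frames carry one trait each (same column layout as the
    univariate case); animals present in both contribute a residual
    covariance, animals with one trait enter through a reduced residual
    block.  Fixed effects are nested within trait.
    """
    if ainv is None:
        ainv = build_a_inverse(pedigree)
    frames = []
    for t, df in enumerate((data1, data2)):
        f = df.copy()
        f["_trait"] = t
        frames.append(f)
    stacked = pd.concat(frames, ignore_index=True)
    # unit = animal; sort by unit then trait as the residual structure needs
    animals = pd.unique(stacked["animal_id"])
    unit_of = {a: i for i, a in enumerate(animals)}
    stacked["_unit"] = stacked["animal_id"].map(unit_of)
    stacked = stacked.sort_values(["_unit", "_trait"], kind="stable",
                                  ignore_index=True)

    # standardise responses per trait for numerical balance, then back-scale
    scales = np.ones(2)
    y = np.asarray(stacked[response], dtype=float)
    for t in range(2):
        mask = stacked["_trait"] == t
        scales[t] = np.std(y[mask]) or 1.0
        y[mask] = y[mask] / scales[t]

    xs = []
    for t in range(2):
        sub = stacked[stacked["_trait"] == t]
        xt, _ = design_from_factors(sub, list(fixed_factors),
                                    list(fixed_covariates))
        xs.append(xt)
    ncol = xs[0].shape[1] + xs[1].shape[1]
    rows, cols, vals = [], [], []
    for t, xt in enumerate(xs):
        rmap = np.asarray(stacked["_trait"] == t).nonzero()[0]
        coo = xt.tocoo()
        rows.append(rmap[coo.row])
        cols.append(coo.col + (0 if t == 0 else xs[0].shape[1]))
        vals.append(coo.data)
    x = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(stacked), ncol)).tocsr()

    trait_col = np.asarray(stacked["_trait"], dtype=np.int64)
    vary = float(np.var(y))
    term = _animal_term(stacked, pedigree, ainv, 2, trait_col,
                        k_start=np.eye(2) * 0.3 * vary)
    resid = MultiTraitResidual(
        units=np.asarray(stacked["_unit"]), traits=trait_col, n_traits=2,
        r_start=np.eye(2) * 0.5 * vary)
    fit = fit_reml(y, x, [term], residual=resid)

    scale_mat = np.outer(scales, scales)
    g = fit.k_hats[0] * scale_mat
    e = fit.r_hat * scale_mat
    # delta-method SEs in the standardised scale (correlations and h2 are
    # scale-invariant, so no back-transformation is needed for them)
    gs, es = fit.k_hats[0], fit.r_hat
    cov = fit.theta_cov  # order: g11, g21, g22, e11, e21, e22
    p1, p2 = gs[0, 0] + es[0, 0], gs[1, 1] + es[1, 1]

    h2 = np.array([gs[0, 0] / p1, gs[1, 1] / p2])
    se_h2 = np.empty(2)
    for t, (gt, et, pt, ig, ie) in enumerate(
            [(gs[0, 0], es[0, 0], p1, 0, 3), (gs[1, 1], es[1, 1], p2, 2, 5)]):
        grad = np.zeros(6)
        grad[ig] = et / pt**2
        grad[ie] = -gt / pt**2
        se_h2[t] = np.sqrt(max(grad @ cov @ grad, 0.0))

    clamped = False
    denom_a = np.sqrt(max(gs[0, 0] * gs[1, 1], 1e-300))
    r_a = gs[0, 1] / denom_a
    grad_a = np.zeros(6)
    grad_a[1] = 1.0 / denom_a
    grad_a[0] = -r_a / (2 * gs[0, 0]) if gs[0, 0] > 0 else 0.0
    grad_a[2] = -r_a / (2 * gs[1, 1]) if gs[1, 1] > 0 else 0.0
    se_ra = float(np.sqrt(max(grad_a @ cov @ grad_a, 0.0)))
    if abs(r_a) > 1.0:
        r_a = float(np.clip(r_a, -1.0, 1.0))
        clamped = True

    denom_p = np.sqrt(p1 * p2)
    r_p = (gs[0, 1] + es[0, 1]) / denom_p
    grad_p = np.zeros(6)
    grad_p[1] = grad_p[4] = 1.0 / denom_p
    grad_p[0] = grad_p[3] = -r_p / (2 * p1)
    grad_p[2] = grad_p[5] = -r_p / (2 * p2)
    se_rp = float(np.sqrt(max(grad_p @ cov @ grad_p, 0.0)))
    if abs(r_p) > 1.0:
        r_p = float(np.clip(r_p, -1.0, 1.0))
        clamped = True

    df_resid = fit.n_obs - fit.rank_x
    est = GeneticEstimate(
        traits=trait_names, g=g, e=e, h2=h2, se_h2=se_h2,
        r_a=float(r_a), se_ra=se_ra, r_p=float(r_p), se_rp=se_rp,
        p_h2=np.array([_t_pvalue(h2[t], se_h2[t], df_resid)
                       for t in range(2)], dtype=object),
        p_ra=_t_pvalue(r_a, se_ra, df_resid),
        p_rp=_t_pvalue(r_p, se_rp, df_resid),
        loglik=fit.loglik, df_resid=df_resid, n_obs=fit.n_obs,
        boundary=fit.boundary, converged=fit.converged,
        clamped=clamped, fit=fit)
    return est


def significance(
    estimate: GeneticEstimate,
    model_loglik_with: float,
    model_loglik_without: float,
) -> GeneticEstimate:
    """Annotate an estimate with the animal-effect likelihood-ratio test.

    The LRT statistic ``2 (l_with - l_without)`` is referred to the
    0.5*chi2(0) + 0.5*chi2(1) mixture appropriate for a variance tested
    on its zero boundary, so identical log-likelihoods give p = 0.5.
    Negative statistics (rounding) are truncated at zero.
    """
    lrt = max(2.0 * (model_loglik_with - model_loglik_without), 0.0)
    p = float(0.5 * stats.chi2.sf(lrt, 1)) if lrt > 0 else 0.5
    estimate.loglik_no_animal = model_loglik_without
    estimate.lrt = lrt
    estimate.p_lrt = p
    return estimate
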