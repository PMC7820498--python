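"""Reaction-norm models and slope-based resilience phenotypes.

Test-day milk yield is regressed on an environmental covariate
(air temperature or THI, same-day or week-preceding average) with a
second-degree Legendre polynomial: a population curve common to all
animals, plus a per-animal random curve expressed as a deviation from
it.  The mixed model is

    y = X b + Phi(x) beta + Z (Phi(x) a_i) + e,

with the animals' coefficient 3-vectors ``a_i`` i.i.d. N(0, G0)
(unstructured 3x3) and i.i.d. residuals; G0 and sigma2_e by REML.
Genetic structure deliberately does not enter at this stage — the
pedigree acts on the *derived* slope phenotypes in the quantgen module,
mirroring a two-step design.

An animal's resilience phenotype is the derivative of its curve at a
stated temperature (10 degC for cold, 25 degC for heat stress), in kg
milk per degC: values near zero mean performance insensitive to weather
fluctuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .legendre import LegendreBasis
from .mixedmodel import MixedModelFit, RandomTerm, design_from_factors, fit_reml

__all__ = [
    "ReactionNormFit",
    "fit_reaction_norm",
    "slope_at",
    "derive_phenotypes",
    "phenotype_summary",
    "DEFAULT_FIXED_FACTORS",
]

DEFAULT_FIXED_FACTORS = (
    "flock_id", "lactation_number", "lambing_year", "lambing_month",
    "dim_class",
)

#: label prefix per covariate column, matching the field's trait naming
TRAIT_PREFIX = {"tavg": "Tavg", "tavg_lag7": "Tavg", "thi": "THI",
                "thi_lag7": "THI"}


@dataclass
class ReactionNormFit:
    """Population curve, per-animal deviations and their components."""

    season: str
    covariate_tag: str
    basis: LegendreBasis
    animal_ids: list
    beta: np.ndarray                 # population curve coefficients (3,)
    a: np.ndarray                    # per-animal deviations, (n_animals, 3)
    g0: np.ndarray                   # 3x3 covariance of random coefficients
    sigma2_e: float
    fixed_names: list[str]
    fixed_solution: np.ndarray
    mean_fixed: float                # average fixed-effect contribution
    loglik: float
    n_iter: int
    converged: bool
    n_records: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    def population_curve(self, x) -> np.ndarray:
        """Expected milk yield at covariate ``x`` for the average record."""
        phi = self.basis.evaluate(x)
        return self.mean_fixed + phi @ self.beta

    def animal_curve(self, animal_id, x) -> np.ndarray:
        phi = self.basis.evaluate(x)
        i = self._animal_index(animal_id)
        return self.mean_fixed + phi @ (self.beta + self.a[i])

    def _animal_index(self, animal_id) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise KeyError(
                f"animal {animal_id!r} has no records in this fit") from None

    def to_summary(self) -> dict:
        return {
            "season": self.season,
            "covariate": self.covariate_tag,
            "beta": self.beta.tolist(),
            "G0": self.g0.tolist(),
            "sigma2_e": self.sigma2_e,
            "loglik": self.loglik,
            "n_iterations": self.n_iter,
            "n_records": self.n_records,
            "n_animals": len(self.animal_ids),
            "x_range": [self.basis.x_min, self.basis.x_max],
        }


def fit_reaction_norm(
    records: pd.DataFrame,
    covariate: str = "tavg",
    season: str = "",
    basis: LegendreBasis | None = None,
    fixed_factors=DEFAULT_FIXED_FACTORS,
    response: str = "milk_kg",
) -> ReactionNormFit:
    """Fit the population + individual Legendre reaction norm by REML.

    ``records`` needs ``animal_id``, the response, the covariate column
    and the fixed-effect columns (a ``dim_class`` of 30-day days-in-milk
    bins is derived from ``dim`` when absent).  The basis range defaults
    to the observed covariate min/max, which is stored with the fit so
    later slope queries are validated against it.
    """
    df = records.copy()
    if "dim_class" in fixed_factors and "dim_class" not in df:
        df["dim_class"] = (df["dim"] // 30).astype(int)
    xvals = np.asarray(df[covariate], dtype=float)
    if np.unique(xvals).size < 2:
        raise ValueError("need at least two distinct covariate values")
    if basis is None:
        basis = LegendreBasis(float(xvals.min()), float(xvals.max()))

    factors = [f for f in fixed_factors if f in df.columns]
    x_fac, names = design_from_factors(df, factors, intercept=False)
    phi = basis.evaluate(xvals)
    x = sp.hstack([x_fac, sp.csr_matrix(phi)], format="csr")
    names = names + [f"leg{k}" for k in range(basis.n_coef)]

    animals = list(pd.unique(df["animal_id"]))
    idx = {a: i for i, a in enumerate(animals)}
    groups = np.array([idx[a] for a in df["animal_id"]], dtype=np.int64)
    vary = float(np.var(np.asarray(df[response], dtype=float)))
    term = RandomTerm(
        name="animal_curve", groups=groups, design=phi,
        n_levels=len(animals),
        k_start=np.eye(basis.n_coef) * (0.2 * vary / basis.n_coef))
    fit: MixedModelFit = fit_reml(
        np.asarray(df[response], dtype=float), x, [term])

    nb = basis.n_coef
    beta = fit.fixed[-nb:]
    fac_sol = fit.fixed[:-nb]
    mean_fixed = float((x_fac @ fac_sol).mean()) if x_fac.shape[1] else 0.0
    return ReactionNormFit(
        season=season, covariate_tag=covariate, basis=basis,
        animal_ids=animals, beta=np.asarray(beta),
        a=fit.random["animal_curve"], g0=fit.k_hats[0],
        sigma2_e=float(fit.r_hat[0, 0]),
        fixed_names=names[:-nb], fixed_solution=fac_sol,
        mean_fixed=mean_fixed, loglik=fit.loglik, n_iter=fit.n_iter,
        converged=fit.converged, n_records=len(df))


def slope_at(
    fit: ReactionNormFit,
    animal_id,
    x0: float,
    mode: str = "total",
) -> float:
    """Derivative of one animal's reaction norm at ``x0`` (kg per degC).

    ``total`` differentiates population + deviation curve; ``deviation``
    only the animal's deviation from the population curve.
    """
    if mode not in ("total", "deviation"):
        raise ValueError(f"unknown slope mode {mode!r}")
    dphi = fit.basis.derivative(x0)[0]
    i = fit._animal_index(animal_id)
    coef = fit.a[i] if mode == "deviation" else fit.beta + fit.a[i]
    return float(dphi @ coef)


def _slopes_all(fit: ReactionNormFit, x0: float, mode: str) -> np.ndarray:
    dphi = fit.basis.derivative(x0)[0]
    coef = fit.a if mode == "deviation" else fit.beta[None, :] + fit.a
    return coef @ dphi


def derive_phenotypes(
    fits: dict[tuple[str, str], ReactionNormFit],
    temperatures=(10.0, 25.0),
    mode: str = "total",
) -> pd.DataFrame:
    """Slope phenotypes per animal at the stated temperatures.

    ``fits`` maps ``(season, covariate_tag)`` to a fit.  Traits are
    labelled e.g. ``Tavg10`` (same-day) and ``Tavg10_lag7``
    (week-preceding average).  A temperature outside a fit's observed
    covariate range skips that trait for that season with a warning.
    """
    rows = []
    for (season, tag), fit in fits.items():
        prefix = TRAIT_PREFIX.get(tag, tag)
        suffix = "_lag7" if tag.endswith("_lag7") else ""
        for temp in temperatures:
            if not (fit.basis.x_min - 1e-9 <= temp <= fit.basis.x_max + 1e-9):
                warnings.warn(
                    f"{temp} degC outside observed range "
                    f"[{fit.basis.x_min:.1f}, {fit.basis.x_max:.1f}] for "
                    f"season {season!r} / {tag}; trait skipped", stacklevel=2)
                continue
            trait = f"{prefix}{temp:g}{suffix}"
            slopes = _slopes_all(fit, temp, mode)
            rows.append(pd.DataFrame({
                "animal_id": fit.animal_ids,
                "season": season,
                "trait": trait,
                "slope": slopes,
            }))
    if not rows:
        return pd.DataFrame(columns=["animal_id", "season", "trait", "slope"])
    return pd.concat(rows, ignore_index=True)


def phenotype_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of each trait by season — the descriptive-statistics table."""
    g = phenotypes.groupby(["trait", "season"])["slope"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"count": "n_animals"})
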