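import numpy as np
import pandas as pd
import pytest

from thermoresil import (
    LegendreBasis,
    ReactionNormFit,
    derive_phenotypes,
    fit_reaction_norm,
    phenotype_summary,
    slope_at,
)


def _make_fit(beta, a, basis=None, season="autumn", tag="tavg"):
    basis = basis or LegendreBasis(0.0, 30.0)
    a = np.atleast_2d(a)
    return ReactionNormFit(
        season=season, covariate_tag=tag, basis=basis,
        animal_ids=[f"e{i}" for i in range(len(a))],
        beta=np.asarray(beta, dtype=float), a=a,
        g0=np.eye(3) * 0.01, sigma2_e=0.05, fixed_names=[],
        fixed_solution=np.array([]), mean_fixed=1.5, loglik=0.0,
        n_iter=1, converged=True, n_records=len(a) * 5)


def test_slope_of_linear_curve_is_constant():
    basis = LegendreBasis(0.0, 30.0, normalization="standard")
    fit = _make_fit([0.0, 2.0, 0.0], np.zeros((1, 3)), basis=basis)
    # standard P1 slope: beta1 * 2/(x_max - x_min)
    expected = 2.0 * 2.0 / 30.0
    for x in (0.0, 11.3, 25.0, 30.0):
        assert slope_at(fit, "e0", x) == pytest.approx(expected)


def test_slope_matches_central_finite_difference():
    rng = np.random.default_rng(4)
    basis = LegendreBasis(3.0, 29.0)
    for _ in range(10):
        beta = rng.normal(0, 0.3, 3)
        a = rng.normal(0, 0.1, (2, 3))
        fit = _make_fit(beta, a, basis=basis)
        for x0 in rng.uniform(4, 28, 3):
            h = 0.01
            for animal in ("e0", "e1"):
                fd = (fit.animal_curve(animal, x0 + h)
                      - fit.animal_curve(animal, x0 - h))[0] / (2 * h)
                assert slope_at(fit, animal, x0) == pytest.approx(
                    fd, abs=1e-6)


def test_zero_coefficients_give_zero_slope_everywhere():
    fit = _make_fit(np.zeros(3), np.zeros((1, 3)))
    for x in (0.0, 10.0, 25.0):
        assert slope_at(fit, "e0", x) == 0.0


def test_total_slope_is_population_plus_deviation():
    rng = np.random.default_rng(9)
    fit = _make_fit(rng.normal(0, 0.2, 3), rng.normal(0, 0.1, (3, 3)))
    pop = _make_fit(fit.beta, np.zeros((1, 3)))
    for animal in fit.animal_ids:
        total = slope_at(fit, animal, 12.0, mode="total")
        dev = slope_at(fit, animal, 12.0, mode="deviation")
        assert total == pytest.approx(slope_at(pop, "e0", 12.0) + dev)


def test_unknown_animal_and_bad_mode_raise():
    fit = _make_fit(np.zeros(3), np.zeros((1, 3)))
    with pytest.raises(KeyError):
        slope_at(fit, "nobody", 10.0)
    with pytest.raises(ValueError):
        slope_at(fit, "e0", 10.0, mode="wiggle")


def _simulated_records(n_animals=60, noise=0.05, beta=(1.8, 0.4, -0.25),
                       u_sd=0.0, seed=0):
    """Records from a known curve on a fixed basis, few fixed effects."""
    rng = np.random.default_rng(seed)
    basis = LegendreBasis(0.0, 30.0)
    rows = []
    for i in range(n_animals):
        u = rng.normal(0, u_sd, 3)
        for x in rng.uniform(0.0, 30.0, 8):
            phi = basis.evaluate(x)[0]
            rows.append({
                "animal_id": f"e{i}", "flock_id": "F1", "dim": 100,
                "tavg": x,
                "milk_kg": float(phi @ (np.asarray(beta) + u)
                                 + rng.normal(0, noise))})
    return pd.DataFrame(rows), basis


def test_noiseless_population_curve_recovery():
    df, basis = _simulated_records(noise=1e-3, u_sd=0.0, seed=1)
    fit = fit_reaction_norm(df, covariate="tavg", basis=basis,
                            fixed_factors=())
    np.testing.assert_allclose(fit.beta, [1.8, 0.4, -0.25], atol=5e-3)
    assert np.abs(np.diag(fit.g0)).max() < 1e-3


def test_identical_animals_get_identical_phenotypes():
    df, basis = _simulated_records(n_animals=20, noise=0.1, u_sd=0.15,
                                   seed=2)
    clone = df[df["animal_id"] == "e0"].copy()
    clone["animal_id"] = "e_clone"
    fit = fit_reaction_norm(pd.concat([df, clone], ignore_index=True),
                            covariate="tavg", basis=basis,
                            fixed_factors=())
    assert slope_at(fit, "e0", 10.0) == pytest.approx(
        slope_at(fit, "e_clone", 10.0), abs=1e-8)


def test_deviation_phenotypes_center_near_zero():
    df, basis = _simulated_records(n_animals=80, noise=0.1, u_sd=0.15,
                                   seed=3)
    fit = fit_reaction_norm(df, covariate="tavg", basis=basis,
                            fixed_factors=(), season="autumn")
    phen = derive_phenotypes({("autumn", "tavg"): fit}, mode="deviation")
    for _, grp in phen.groupby("trait"):
        assert abs(grp["slope"].mean()) < 0.25 * grp["slope"].std()


def test_out_of_range_temperature_skips_trait_with_warning():
    df, _ = _simulated_records(seed=4)
    df["tavg"] = 5.0 + 4.0 * (df["tavg"] / 30.0)  # observed range ~[5, 9]
    fit = fit_reaction_norm(df, covariate="tavg", fixed_factors=(),
                            season="spring")
    with pytest.warns(UserWarning, match="outside observed range"):
        phen = derive_phenotypes({("spring", "tavg"): fit},
                                 temperatures=(25.0,))
    assert len(phen) == 0


def test_fit_requires_covariate_variation():
    df, _ = _simulated_records(seed=5)
    df["tavg"] = 10.0
    with pytest.raises(ValueError, match="distinct covariate"):
        fit_reaction_norm(df, covariate="tavg", fixed_factors=())


def test_component_recovery_on_simulated_animals():
    """With animal curve variation present, REML finds it (smoke scale)."""
    df, basis = _simulated_records(n_animals=150, noise=0.1, u_sd=0.2,
                                   seed=6)
    fit = fit_reaction_norm(df, covariate="tavg", basis=basis,
                            fixed_factors=())
    assert fit.converged
    # true coefficient covariance is 0.04 I; all three diagonals detected
    d = np.diag(fit.g0)
    assert np.all(d > 0.01) and np.all(d < 0.1)
    assert fit.sigma2_e == pytest.approx(0.01, rel=0.5)
    summary = phenotype_summary(derive_phenotypes(
        {("autumn", "tavg"): fit}))
    assert set(summary["trait"]) == {"Tavg10", "Tavg25"}
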