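import numpy as np
import pandas as pd
import pytest

from thermoresil import (
    SimConfig,
    simulate_breeding_values,
    simulate_direct_traits,
    simulate_pedigree,
    simulate_testdays,
    simulate_weather,
)

from conftest import tabular_a


def test_fixed_seed_reproduces_everything():
    cfg = SimConfig(seed=42, generation_sizes=(30, 60), n_sires=4,
                    n_years=2)
    outs = []
    for _ in range(2):
        streams = cfg.streams()
        ped, meta = simulate_pedigree(cfg, rng=streams["pedigree"])
        wx = simulate_weather(cfg, rng=streams["weather"])
        rec, _ = simulate_testdays(ped, meta, {"S1": wx}, cfg,
                                   rng_bv=streams["bv"],
                                   rng=streams["records"])
        outs.append((ped.ids, wx.frame, rec))
    assert outs[0][0] == outs[1][0]
    pd.testing.assert_frame_equal(outs[0][1], outs[1][1])
    pd.testing.assert_frame_equal(outs[0][2], outs[1][2])


def test_single_generation_pedigree_is_founders_only():
    cfg = SimConfig(generation_sizes=(40,))
    ped, meta = simulate_pedigree(cfg)
    assert len(ped) == 40
    assert (ped.sire == -1).all() and (ped.dam == -1).all()


def test_infeasible_sire_ratio_raises():
    cfg = SimConfig(generation_sizes=(4, 10), n_sires=10)
    with pytest.raises(ValueError, match="infeasible"):
        simulate_pedigree(cfg)


def test_offspring_sire_relationship_is_half():
    cfg = SimConfig(seed=8, generation_sizes=(40, 80), n_sires=5)
    ped, meta = simulate_pedigree(cfg)
    a = tabular_a(ped)
    rels = [a[i, ped.sire[i]] for i in range(len(ped)) if ped.sire[i] >= 0]
    # parents are unrelated founders here, so every offspring-sire
    # relationship is exactly 1/2
    assert np.allclose(rels, 0.5)


def test_zero_noise_weather_is_exact_sinusoid_peaking_in_summer():
    cfg = SimConfig(ar_sd=0.0, rh_sd=0.0)
    wx = simulate_weather(cfg, date_range=pd.date_range("2015-01-01",
                                                        "2015-12-31"))
    t = wx.frame["tavg"]
    assert t.max() == pytest.approx(cfg.t_mean + cfg.t_amplitude, abs=1e-6)
    peak_day = wx.frame.loc[t.idxmax(), "date"].dayofyear
    assert abs(peak_day - cfg.t_peak_doy) <= 1
    assert wx.frame["rhavg"].between(0, 100).all()


def test_weather_sample_mean_near_configured_mean():
    cfg = SimConfig(seed=2)
    wx = simulate_weather(cfg, date_range=pd.date_range("2000-01-01",
                                                        "2019-12-31"))
    n = len(wx.frame)
    # AR(1) long-run SE of the mean
    se = cfg.ar_sd / (1 - cfg.ar_phi) / np.sqrt(n / 30)
    assert abs(wx.frame["tavg"].mean() - cfg.t_mean) < 3 * max(se, 0.1)


def test_breeding_values_zero_g0_and_founder_covariance():
    from thermoresil import Pedigree
    founders = Pedigree.from_records(
        [(f"f{i}", None, None) for i in range(4000)])
    assert np.all(simulate_breeding_values(founders, np.zeros((2, 2))) == 0)
    g0 = np.array([[0.2, 0.05], [0.05, 0.1]])
    bv = simulate_breeding_values(founders, g0, seed=3)
    np.testing.assert_allclose(np.cov(bv.T), g0, atol=3 * 0.2 / np.sqrt(4000))


def test_full_sib_breeding_value_covariance():
    from thermoresil import Pedigree
    trios = [("s", None, None), ("d", None, None)]
    trios += [(f"k{i}", "s", "d") for i in range(2)]
    ped = Pedigree.from_records(trios)
    rng = np.random.default_rng(12)
    draws = np.array([simulate_breeding_values(ped, [[1.0]], rng=rng)[2:, 0]
                      for _ in range(8000)])
    cov = np.cov(draws.T)
    assert cov[0, 1] == pytest.approx(0.5, abs=0.05)   # full sibs: A = 1/2
    assert cov[0, 0] == pytest.approx(1.0, abs=0.06)


def test_testdays_deterministic_when_all_variances_zero():
    cfg = SimConfig(seed=3, generation_sizes=(20, 40), n_sires=3,
                    n_years=2, ar_sd=0.0, rh_sd=0.0,
                    flock_effect_sd=0.0, year_effect_sd=0.0,
                    residual_sd=0.0, k_total=np.zeros((3, 3)))
    streams = cfg.streams()
    ped, meta = simulate_pedigree(cfg, rng=streams["pedigree"])
    wx = {"S1": simulate_weather(cfg, rng=streams["weather"])}
    rec, truth = simulate_testdays(ped, meta, wx, cfg,
                                   rng_bv=streams["bv"],
                                   rng=streams["records"])
    a, b, c = cfg.wilmink
    basis = cfg.basis
    beta = np.asarray(cfg.beta)
    for row in rec.itertuples(index=False):
        t = wx["S1"].value(pd.Timestamp(row.test_date))
        phi = basis.evaluate(np.clip(t, basis.x_min, basis.x_max))[0]
        expected = (a + b * np.exp(-cfg.wilmink_k * row.dim) + c * row.dim
                    + phi @ beta)
        assert row.milk_kg == pytest.approx(expected, abs=1e-10)


def test_monthly_recording_yields_at_least_five_tests():
    cfg = SimConfig(seed=9, generation_sizes=(20, 40), n_sires=3,
                    lactation_length=(182, 183), n_years=2)
    streams = cfg.streams()
    ped, meta = simulate_pedigree(cfg, rng=streams["pedigree"])
    wx = {"S1": simulate_weather(cfg, rng=streams["weather"])}
    rec, _ = simulate_testdays(ped, meta, wx, cfg,
                               rng_bv=streams["bv"], rng=streams["records"])
    per_lact = rec.groupby(["animal_id", "lambing_date"]).size()
    assert (per_lact >= 5).all()
    months = pd.to_datetime(rec["lambing_date"]).dt.month
    assert not months.isin([6, 7, 8]).any()   # lambings fall Sep-May only
    assert (rec["dim"] >= 42).all()


def test_heat_stress_curve_declines_at_high_temperature():
    cfg = SimConfig(beta=(0.0, 0.0, -0.3))  # strong negative curvature
    basis = cfg.basis
    curve = basis.evaluate(np.array([20.0, 28.0])) @ np.asarray(cfg.beta)
    assert curve[1] < curve[0]


def test_direct_traits_h2_one_is_pure_breeding_value():
    from thermoresil import Pedigree
    ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(50)])
    df = simulate_direct_traits(ped, 0.999999, phenotyped=list(ped.ids),
                                n_groups=1, group_effect_sd=0.0, seed=5)
    np.testing.assert_allclose(df["value"] - df["value"].mean(),
                               df["true_bv"] - df["true_bv"].mean(),
                               atol=1e-2)


def test_direct_trait_pair_realises_requested_genetic_correlation():
    from thermoresil import Pedigree
    ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(5000)])
    df = simulate_direct_traits(ped, (0.15, 0.14), r_a=-0.27,
                                phenotyped=list(ped.ids), seed=6)
    r = np.corrcoef(df["true_bv1"], df["true_bv2"])[0, 1]
    se = (1 - 0.27**2) / np.sqrt(5000)
    assert r == pytest.approx(-0.27, abs=3 * se)


def test_direct_traits_validate_inputs():
    from thermoresil import Pedigree
    ped = Pedigree.from_records([("f0", None, None)])
    with pytest.raises(ValueError, match="heritabilities"):
        simulate_direct_traits(ped, 1.5)
    with pytest.raises(ValueError, match="inadmissible"):
        simulate_direct_traits(ped, (0.9, 0.9), r_a=-0.9, r_p=0.95)
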