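"""Synthetic study generator: pedigree, weather, test days, direct traits.

Emulates the design of a Mediterranean dairy-sheep recording scheme so
the whole pipeline runs with known ground truth: a multi-generation
pedigree under random mating with few sires; an annual temperature
sinusoid with AR(1) day-to-day noise and negatively correlated relative
humidity; lambings spread September-May with monthly test-day recording
from day 42 of 5-6-month lactations; and milk yields built from a flock
effect, a Wilmink lactation curve, a population Legendre reaction norm
plus animal-specific (genetic + permanent-environment) curve deviations,
and i.i.d. residuals.

``simulate_direct_traits`` bypasses the reaction-norm stage and draws
scalar phenotypes directly under the animal model at requested
heritabilities and genetic/phenotypic correlations — the ground truth
for parameter-recovery checks of the REML machinery.

Every sub-generator draws from its own stream spawned from the master
seed, so e.g. adding flocks cannot perturb the weather sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .legendre import LegendreBasis
from .pedigree import Pedigree
from .weather import WeatherSeries, compute_thi

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "simulate_weather",
    "simulate_breeding_values",
    "simulate_testdays",
    "simulate_direct_traits",
]

#: lambing-season shares, proportional to a realistic autumn:winter:spring
#: animal-count ratio of 17,899 : 24,837 : 8,363
SEASON_PROPORTIONS = {"autumn": 0.3503, "winter": 0.4861, "spring": 0.1636}

#: months lambings may fall in, per season
SEASON_MONTHS = {"autumn": (9, 10, 11), "winter": (12, 1, 2),
                 "spring": (3, 4, 5)}


def _default_k_total() -> np.ndarray:
    # coefficient SDs chosen so slope phenotypes have SD near 0.014 kg/degC
    return np.diag([0.35, 0.13, 0.07]) ** 2


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with field-realistic defaults."""

    seed: int = 1
    # pedigree
    generation_sizes: tuple = (150, 300, 450)
    n_sires: int = 12            # sires used per generation
    # flocks / stations
    n_flocks: int = 5
    n_stations: int = 3
    flock_effect_sd: float = 0.15
    # weather (daily mean air temperature, degC)
    t_mean: float = 16.5
    t_amplitude: float = 10.0
    t_peak_doy: int = 197        # mid-July
    ar_phi: float = 0.7
    ar_sd: float = 1.6
    rh_mean: float = 65.0
    rh_slope: float = -0.8       # percent RH per degC above t_mean
    rh_sd: float = 6.0
    # recording scheme
    start_year: int = 2014
    n_years: int = 4
    recording_interval: int = 30
    first_test_dim: int = 42
    lactation_length: tuple = (150, 210)
    season_proportions: dict = field(
        default_factory=lambda: dict(SEASON_PROPORTIONS))
    # lactation baseline (Wilmink): a + b*exp(-0.05 dim) + c*dim
    wilmink: tuple = (2.2, -1.0, -0.005)
    wilmink_k: float = 0.05
    # reaction norm (normalized Legendre basis over basis_range)
    basis_range: tuple = (-2.0, 34.0)
    beta: tuple = (0.0, 0.0522, -0.0540)
    g0_fraction: float = 0.3     # genetic share of coefficient covariance
    k_total: np.ndarray = field(default_factory=_default_k_total)
    residual_sd: float = 0.30
    year_effect_sd: float = 0.05

    def streams(self) -> dict:
        names = ("pedigree", "weather", "bv", "records", "traits")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}

    @property
    def g0(self) -> np.ndarray:
        return self.g0_fraction * np.asarray(self.k_total)

    @property
    def p0(self) -> np.ndarray:
        return (1.0 - self.g0_fraction) * np.asarray(self.k_total)

    @property
    def basis(self) -> LegendreBasis:
        return LegendreBasis(*self.basis_range)


# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig, rng=None):
    """Discrete-generation pedigree under random mating with few sires.

    Founders form generation 0; each later generation draws ``n_sires``
    sires at random from the previous generation's males and mates them
    to random previous-generation females.  Returns ``(Pedigree, meta)``
    with per-animal generation and sex.
    """
    rng = rng or config.streams()["pedigree"]
    sizes = config.generation_sizes
    if sizes[0] < 2 or len(sizes) < 1:
        raise ValueError("need >= 2 founders and >= 1 generation")
    trios, meta = [], []
    prev: list[tuple[str, str]] = []
    counter = 0
    for g, size in enumerate(sizes):
        cur = []
        if g > 0:
            males = [a for a, s in prev if s == "M"]
            females = [a for a, s in prev if s == "F"]
            if len(males) < config.n_sires or not females:
                raise ValueError(
                    f"generation {g}: infeasible sire:dam ratio "
                    f"({len(males)} males, {len(females)} females)")
            sires = list(rng.choice(males, size=config.n_sires,
                                    replace=False))
        for _ in range(size):
            counter += 1
            aid = f"A{counter:05d}"
            sex = "M" if rng.random() < 0.5 else "F"
            if g == 0:
                trios.append((aid, None, None))
            else:
                trios.append((aid, rng.choice(sires), rng.choice(females)))
            meta.append({"animal_id": aid, "generation": g, "sex": sex})
            cur.append((aid, sex))
        prev = cur
    ped = Pedigree.from_records(trios)
    return ped, pd.DataFrame(meta)


def simulate_weather(config: SimConfig, date_range=None, rng=None,
                     station_id: str = "S1") -> WeatherSeries:
    """Annual sinusoid + AR(1) temperature; RH anti-correlated, in [0,100]."""
    rng = rng or config.streams()["weather"]
    if date_range is None:
        date_range = pd.date_range(
            f"{config.start_year - 1}-01-01",
            f"{config.start_year + config.n_years}-12-31")
    dates = pd.DatetimeIndex(date_range)
    doy = dates.dayofyear.to_numpy()
    seasonal = config.t_mean + config.t_amplitude * np.cos(
        2 * np.pi * (doy - config.t_peak_doy) / 365.25)
    n = len(dates)
    noise = np.zeros(n)
    if config.ar_sd > 0:
        eps = rng.normal(0.0, config.ar_sd, size=n)
        # stationary start
        noise[0] = eps[0] / np.sqrt(1 - config.ar_phi**2)
        for i in range(1, n):
            noise[i] = config.ar_phi * noise[i - 1] + eps[i]
    tavg = seasonal + noise
    rh = (config.rh_mean + config.rh_slope * (tavg - config.t_mean)
          + rng.normal(0.0, config.rh_sd, size=n))
    rh = np.clip(rh, 0.0, 100.0)
    return WeatherSeries(station_id, pd.DataFrame(
        {"date": dates, "tavg": tavg, "rhavg": rh,
         "thi": compute_thi(tavg, rh)}))


def simulate_breeding_values(pedigree: Pedigree, g0: np.ndarray,
                             rng=None, seed: int = 0) -> np.ndarray:
    """Additive-genetic coefficient vectors down the pedigree.

    Founders ~ N(0, G0); descendants get the parent average plus
    Mendelian sampling with variance ``0.5 G0 (1 - (F_s + F_d)/2)``.
    Returns an (n_animals, m) array in pedigree order.
    """
    rng = rng or np.random.default_rng(seed)
    g0 = np.atleast_2d(np.asarray(g0, dtype=float))
    m = g0.shape[0]
    w, v = np.linalg.eigh(g0)
    if w.min() < -1e-10:
        raise ValueError("G0 must be positive semi-definite")
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    n = len(pedigree)
    f = pedigree.inbreeding()
    bv = np.zeros((n, m))
    z = rng.standard_normal((n, m))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            bv[i] = chol @ z[i]
        else:
            pa = np.zeros(m)
            var_factor = 1.0
            fs = f[s] if s >= 0 else 0.0
            fd = f[d] if d >= 0 else 0.0
            if s >= 0:
                pa += 0.5 * bv[s]
            if d >= 0:
                pa += 0.5 * bv[d]
            var_factor = 0.5 * (1.0 - 0.5 * (fs + fd))
            # unknown-parent side contributes its full founder variance half
            if s < 0 or d < 0:
                var_factor += 0.25
            bv[i] = pa + np.sqrt(var_factor) * (chol @ z[i])
    return bv


def _draw_lambing_date(rng, year: int, proportions: dict) -> pd.Timestamp:
    seasons = list(proportions)
    probs = np.array([proportions[s] for s in seasons], dtype=float)
    season = rng.choice(seasons, p=probs / probs.sum())
    month = int(rng.choice(SEASON_MONTHS[season]))
    day = int(rng.integers(1, 28))
    # winter wraps the calendar year: Dec belongs to the season's start year
    y = year if month >= 9 else year + 1
    if month in (1, 2, 3, 4, 5):
        y = year + 1
    return pd.Timestamp(year=y, month=month, day=day)


def simulate_testdays(
    pedigree: Pedigree,
    meta: pd.DataFrame,
    weather: dict[str, WeatherSeries],
    config: SimConfig,
    station_of_flock: dict[str, str] | None = None,
    rng_bv=None,
    rng=None,
) -> tuple[pd.DataFrame, dict]:
    """Monthly test-day milk records for all non-founder females.

    Yield = flock + lambing-year effect + Wilmink(dim)
    + Phi(tavg) (beta + g_i + pe_i) + e.  Returns the record table and a
    dict of ground truth (true coefficient vectors, effects).
    """
    streams = config.streams()
    rng = rng or streams["records"]
    rng_bv = rng_bv or streams["bv"]
    basis = config.basis
    beta = np.asarray(config.beta, dtype=float)

    flocks = [f"F{k + 1}" for k in range(config.n_flocks)]
    if station_of_flock is None:
        station_ids = sorted(weather)
        station_of_flock = {f: station_ids[k % len(station_ids)]
                            for k, f in enumerate(flocks)}
    flock_eff = dict(zip(flocks, rng.normal(0, config.flock_effect_sd,
                                            len(flocks))))
    years = list(range(config.start_year, config.start_year + config.n_years))
    year_eff = dict(zip(years, rng.normal(0, config.year_effect_sd,
                                          len(years))))

    gvec = simulate_breeding_values(pedigree, config.g0, rng=rng_bv)
    ewes = meta[(meta["sex"] == "F") & (meta["generation"] > 0)]
    pw, pv = np.linalg.eigh(config.p0)
    pe_chol = pv @ np.diag(np.sqrt(np.clip(pw, 0.0, None)))

    a, b, c = config.wilmink
    rows = []
    truth_u = {}
    for animal in ewes["animal_id"]:
        gi = gvec[pedigree.index_of(animal)]
        pei = pe_chol @ rng.standard_normal(3)
        truth_u[animal] = gi + pei
        flock = flocks[int(rng.integers(len(flocks)))]
        series = weather[station_of_flock[flock]]
        n_lact = 1 + int(rng.random() < 0.4)
        year0 = int(rng.choice(years[: max(1, len(years) - n_lact)]))
        for lact in range(1, n_lact + 1):
            lamb = _draw_lambing_date(rng, year0 + (lact - 1),
                                      config.season_proportions)
            length = int(rng.integers(*config.lactation_length))
            for dim in range(config.first_test_dim, length + 1,
                             config.recording_interval):
                test_date = lamb + pd.Timedelta(days=dim)
                t = series.value(test_date, "tavg")
                if np.isnan(t):
                    continue
                xc = float(np.clip(t, basis.x_min, basis.x_max))
                phi = basis.evaluate(xc)[0]
                y = (flock_eff[flock] + year_eff.get(lamb.year, 0.0)
                     + a + b * np.exp(-config.wilmink_k * dim) + c * dim
                     + phi @ (beta + truth_u[animal])
                     + rng.normal(0, config.residual_sd))
                rows.append({
                    "animal_id": animal, "flock_id": flock,
                    "lambing_date": lamb.date().isoformat(),
                    "test_date": test_date.date().isoformat(),
                    "lactation_number": lact, "dim": dim,
                    "milk_kg": float(y),
                })
    records = pd.DataFrame(rows)
    truth = {"beta": beta, "basis": basis, "u": truth_u,
             "flock_effects": flock_eff, "year_effects": year_eff,
             "g0": config.g0, "p0": config.p0,
             "sigma2_e": config.residual_sd**2}
    return records, truth


def simulate_direct_traits(
    pedigree: Pedigree,
    h2,
    r_a: float | None = None,
    r_p: float | None = None,
    phenotyped: list | None = None,
    n_groups: int = 10,
    group_effect_sd: float = 0.3,
    mean: float = 10.0,
    rng=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Scalar trait(s) under the animal model at unit phenotypic variance.

    ``h2`` is a float (one trait) or a pair; ``r_a`` sets the genetic
    correlation and ``r_p`` the phenotypic one (residual covariance
    derived as ``r_p - cov_a``; default independent residuals).  Columns:
    ``animal_id, group, value`` (+ ``value2``) and true breeding values.
    """
    rng = rng or np.random.default_rng(seed)
    h2_arr = np.atleast_1d(np.asarray(h2, dtype=float))
    nt = len(h2_arr)
    if np.any(h2_arr <= 0) or np.any(h2_arr >= 1):
        raise ValueError("heritabilities must lie in (0, 1)")
    if nt == 1:
        g0 = np.array([[h2_arr[0]]])
        e0 = np.array([[1.0 - h2_arr[0]]])
    else:
        if r_a is None:
            r_a = 0.0
        if abs(r_a) > 1:
            raise ValueError("|r_a| must be <= 1")
        ga = r_a * np.sqrt(h2_arr[0] * h2_arr[1])
        g0 = np.array([[h2_arr[0], ga], [ga, h2_arr[1]]])
        e1, e2 = 1.0 - h2_arr[0], 1.0 - h2_arr[1]
        ea = (r_p - ga) if r_p is not None else 0.0
        e0 = np.array([[e1, ea], [ea, e2]])
        if np.linalg.eigvalsh(e0).min() <= 0:
            raise ValueError(
                f"implied residual covariance {ea:.3f} inadmissible for "
                f"residual variances ({e1:.3f}, {e2:.3f})")
    bv = simulate_breeding_values(pedigree, g0, rng=rng)
    if phenotyped is None:
        phenotyped = [a for a in pedigree.ids
                      if pedigree.sire[pedigree.index_of(a)] >= 0
                      or pedigree.dam[pedigree.index_of(a)] >= 0]
    idx = np.array([pedigree.index_of(a) for a in phenotyped])
    groups = rng.integers(0, n_groups, size=len(idx))
    geff = rng.normal(0, group_effect_sd, size=n_groups)
    echol = np.linalg.cholesky(e0 + 1e-12 * np.eye(nt))
    resid = (echol @ rng.standard_normal((nt, len(idx)))).T
    out = pd.DataFrame({"animal_id": phenotyped, "group": groups})
    for t in range(nt):
        col = "value" if t == 0 else f"value{t + 1}"
        out[col] = mean + geff[groups] + bv[idx, t] + resid[:, t]
        out[f"true_bv{t + 1 if nt > 1 else ''}"] = bv[idx, t]
    return out
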