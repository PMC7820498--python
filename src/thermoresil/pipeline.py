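"""End-to-end orchestration: simulate -> weather -> prep -> fits -> genetics.

``run_pipeline`` executes every stage on one configuration and writes
all tabular outputs, fit summaries, an edit report, a run log and a
manifest (config hash, seed, file digests, per-stage record counts) so a
rerun with the same manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .prep import assign_season, edit_records, lifetime_table
from .quantgen import reml_bivariate, reml_univariate
from .reaction_norm import (
    derive_phenotypes,
    fit_reaction_norm,
    phenotype_summary,
)
from .pedigree import build_a_inverse
from .simulate import SimConfig, simulate_pedigree, simulate_testdays, \
    simulate_weather
from .weather import attach_covariates, match_station

__all__ = ["PipelineConfig", "run_pipeline", "RunManifest"]

log = logging.getLogger("thermoresil")

_FLOAT_FMT = "%.8g"

SEASONS = ("autumn", "winter", "spring")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-study run."""

    sim: SimConfig = field(default_factory=SimConfig)
    covariates: tuple = ("tavg", "tavg_lag7")
    temperatures: tuple = (10.0, 25.0)
    slope_mode: str = "total"
    lag_window: int = 7
    sd_within_flock: bool = False
    analyses: tuple = ("h2", "lifetime", "between_seasons", "daily_vs_lag7")
    resilience_fixed_factors: tuple = ("flock_id", "first_lambing_year",
                                      "first_lambing_month")
    resilience_fixed_covariates: tuple = ("total_lactations", "total_dim")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_kwargs = {}
        for k, v in d.pop("sim", {}).items():
            if k == "k_total":
                sim_kwargs[k] = np.asarray(v, dtype=float)
            elif isinstance(v, list):
                sim_kwargs[k] = tuple(v)
            else:
                sim_kwargs[k] = v
        listy = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in d.items()}
        return cls(sim=SimConfig(**sim_kwargs), **listy)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "sim"}
        sim = {k: v for k, v in self.sim.__dict__.items()}
        sim["k_total"] = np.asarray(sim["k_total"]).tolist()
        out["sim"] = sim
        return json.loads(json.dumps(out, default=list))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    file_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None
                 ) -> RunManifest:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    if seed is not None:
        config.sim.seed = int(seed)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        seed=config.sim.seed, version=__version__)
    counts = manifest.stage_counts

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _run_stages(config, out, counts)
    finally:
        log.removeHandler(handler)
        handler.close()

    for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json")):
        if p.name != "manifest.json":
            manifest.file_digests[str(p.relative_to(out))] = _digest(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return manifest


def _run_stages(config: PipelineConfig, out: Path, counts: dict):
    sim = config.sim
    streams = sim.streams()
    log.info("config: slope_mode=%s lag_window=%d sd_within_flock=%s "
             "analyses=%s", config.slope_mode, config.lag_window,
             config.sd_within_flock, ",".join(config.analyses))

    # --- simulate ---------------------------------------------------------
    ped, meta = simulate_pedigree(sim, rng=streams["pedigree"])
    wrng = streams["weather"]
    weather = {}
    for k in range(sim.n_stations):
        sid = f"S{k + 1}"
        weather[sid] = simulate_weather(sim, rng=wrng, station_id=sid)
    # planar coordinates (km): stations on a line, flocks scattered
    stations = pd.DataFrame({
        "id": sorted(weather),
        "lat": [20.0 * k for k in range(sim.n_stations)],
        "lon": [0.0] * sim.n_stations})
    flocks = [f"F{k + 1}" for k in range(sim.n_flocks)]
    frng = np.random.default_rng(np.random.SeedSequence(sim.seed + 977))
    farms = pd.DataFrame({
        "id": flocks,
        "lat": frng.uniform(-5, 20.0 * sim.n_stations, size=sim.n_flocks),
        "lon": frng.uniform(-5, 5, size=sim.n_flocks)})
    smap = match_station(farms, stations, metric="euclidean")
    station_of_flock = dict(zip(smap["farm_id"], smap["station_id"]))
    records, truth = simulate_testdays(
        ped, meta, weather, sim, station_of_flock=station_of_flock,
        rng_bv=streams["bv"], rng=streams["records"])
    counts["simulated_records"] = len(records)
    counts["pedigree_animals"] = len(ped)
    log.info("simulated %d records for %d pedigree animals",
             len(records), len(ped))

    ped_df = pd.DataFrame({
        "animal": ped.ids,
        "sire": [ped.ids[s] if s >= 0 else 0 for s in ped.sire],
        "dam": [ped.ids[d] if d >= 0 else 0 for d in ped.dam]})
    _write_csv(ped_df, out / "pedigree.csv")
    wx = pd.concat([s.frame.assign(station_id=sid)
                    for sid, s in weather.items()])
    _write_csv(wx[["station_id", "date", "tavg", "rhavg", "thi"]],
               out / "weather.csv")
    _write_csv(stations, out / "stations.csv")
    _write_csv(farms, out / "farms.csv")
    _write_csv(smap, out / "station_map.csv")
    _write_csv(records, out / "testday_raw.csv")

    # --- weather covariates ----------------------------------------------
    with_cov, wreport = attach_covariates(
        records, weather, smap, variables=("tavg", "thi"),
        lag_window=config.lag_window)
    counts["weather_matched"] = wreport["n_output"]
    log.info("weather covariates: %s", wreport)
    _write_csv(with_cov, out / "testday_covariates.csv")

    # --- prep -------------------------------------------------------------
    edited, ereport = edit_records(with_cov,
                                   sd_within_flock=config.sd_within_flock)
    edited["season"] = pd.to_datetime(edited["lambing_date"]).map(assign_season)
    edited = edited[edited["season"].notna()].reset_index(drop=True)
    edited["lambing_year"] = pd.to_datetime(edited["lambing_date"]).dt.year
    edited["lambing_month"] = pd.to_datetime(edited["lambing_date"]).dt.month
    counts["edited_records"] = len(edited)
    (out / "edit_report.json").write_text(
        json.dumps(ereport.to_dict(), indent=2))
    log.info("edits: %s", ereport.to_dict())
    _write_csv(edited, out / "testday_edited.csv")

    lifetime = lifetime_table(edited)
    counts["lifetime_rows"] = len(lifetime)
    _write_csv(lifetime, out / "lifetime.csv")

    # --- reaction norms ---------------------------------------------------
    fits = {}
    curves = []
    for season in SEASONS:
        sub = edited[edited["season"] == season]
        if len(sub) < 50:
            log.info("season %s: only %d records, skipped", season, len(sub))
            continue
        for cov in config.covariates:
            fit = fit_reaction_norm(sub, covariate=cov, season=season)
            fits[(season, cov)] = fit
            (out / "fits" / f"fit_{season}_{cov}.json").write_text(
                json.dumps(fit.to_summary(), indent=2))
            grid = np.linspace(fit.basis.x_min, fit.basis.x_max, 61)
            curves.append(pd.DataFrame({
                "season": season, "covariate": cov, "x": grid,
                "milk_kg": fit.population_curve(grid)}))
            log.info("fit %s/%s: ll=%.2f iters=%d", season, cov,
                     fit.loglik, fit.n_iter)
    _write_csv(pd.concat(curves, ignore_index=True),
               out / "population_curves.csv")

    # --- phenotypes -------------------------------------------------------
    phen = derive_phenotypes(fits, temperatures=config.temperatures,
                             mode=config.slope_mode)
    counts["phenotype_rows"] = len(phen)
    phen = phen.sort_values(["trait", "season", "animal_id"],
                            ignore_index=True)
    _write_csv(phen, out / "phenotypes.csv")
    _write_csv(phenotype_summary(phen), out / "phenotype_summary.csv")

    # --- quantgen ---------------------------------------------------------
    ainv = build_a_inverse(ped)
    ctx = phen.merge(lifetime, on=["animal_id", "season"], how="left")
    ctx = ctx.rename(columns={"slope": "value"})
    ff = [f for f in config.resilience_fixed_factors]
    fc = [c for c in config.resilience_fixed_covariates]

    def sub_trait(trait, season):
        s = ctx[(ctx["trait"] == trait) & (ctx["season"] == season)]
        return s.dropna(subset=["value"] + ff + fc).reset_index(drop=True)

    traits = sorted(phen["trait"].unique())
    seasons_present = [s for s in SEASONS
                      if any((s, c) in fits for c in config.covariates)]

    if "h2" in config.analyses or "lifetime" in config.analyses:
        rows = []
        for trait in traits:
            for season in seasons_present:
                s1 = sub_trait(trait, season)
                if len(s1) < 30:
                    continue
                row = {"trait": trait, "season": season}
                if "h2" in config.analyses:
                    est = reml_univariate(
                        s1, ped, fixed_factors=ff, fixed_covariates=fc,
                        ainv=ainv, trait_name=trait)
                    row.update(h2=est.h2[0], se_h2=est.se_h2[0],
                               stars_h2=est.stars(est.p_h2[0]),
                               lrt=est.lrt, p_lrt=est.p_lrt)
                    log.info("h2 %s/%s = %.3f (%.3f)", trait, season,
                             est.h2[0], est.se_h2[0])
                if "lifetime" in config.analyses:
                    s2 = (lifetime[lifetime["season"] == season]
                          .rename(columns={"lifetime_milk_kg": "value"}))
                    s2 = s2.dropna(subset=["value"] + ff + fc)
                    s2 = s2.reset_index(drop=True)
                    best = reml_bivariate(
                        s1, s2, ped, fixed_factors=ff, fixed_covariates=fc,
                        ainv=ainv, trait_names=(trait, "lifetime_milk"))
                    row.update(rP=best.r_p, se_rP=best.se_rp,
                               stars_rP=best.stars(best.p_rp),
                               rA=best.r_a, se_rA=best.se_ra,
                               stars_rA=best.stars(best.p_ra))
                rows.append(row)
        _write_csv(pd.DataFrame(rows), out / "genetic_h2_lifetime.csv")

    if "between_seasons" in config.analyses:
        rows = []
        pairs = [("autumn", "spring", "A-S"), ("autumn", "winter", "A-W"),
                 ("winter", "spring", "W-S")]
        for trait in traits:
            for s1n, s2n, label in pairs:
                a, b = sub_trait(trait, s1n), sub_trait(trait, s2n)
                if len(a) < 30 or len(b) < 30:
                    continue
                est = reml_bivariate(
                    a, b, ped, fixed_factors=ff, fixed_covariates=fc,
                    ainv=ainv, trait_names=(f"{trait}_{s1n}",
                                            f"{trait}_{s2n}"))
                rows.append({"trait": trait, "seasons": label,
                             "rP": est.r_p, "se_rP": est.se_rp,
                             "stars_rP": est.stars(est.p_rp),
                             "rA": est.r_a, "se_rA": est.se_ra,
                             "stars_rA": est.stars(est.p_ra)})
                log.info("between-season %s %s: rA=%.2f", trait, label,
                         est.r_a)
        _write_csv(pd.DataFrame(rows), out / "genetic_between_seasons.csv")

    if "daily_vs_lag7" in config.analyses:
        rows = []
        for season in seasons_present:
            for base in ["Tavg10", "Tavg25", "THI10", "THI25"]:
                t1, t2 = base, f"{base}_lag7"
                if t1 not in traits or t2 not in traits:
                    continue
                a, b = sub_trait(t1, season), sub_trait(t2, season)
                if len(a) < 30 or len(b) < 30:
                    continue
                est = reml_bivariate(
                    a, b, ped, fixed_factors=ff, fixed_covariates=fc,
                    ainv=ainv, trait_names=(t1, t2))
                rows.append({"season": season, "phenotypes": f"{t1}-{t2}",
                             "rP": est.r_p, "se_rP": est.se_rp,
                             "stars_rP": est.stars(est.p_rp),
                             "rA": est.r_a, "se_rA": est.se_ra,
                             "stars_rA": est.stars(est.p_ra)})
        _write_csv(pd.DataFrame(rows), out / "genetic_daily_lag7.csv")

    # ground truth for validation
    truth_out = {
        "beta": np.asarray(truth["beta"]).tolist(),
        "basis_range": [truth["basis"].x_min, truth["basis"].x_max],
        "g0": np.asarray(truth["g0"]).tolist(),
        "p0": np.asarray(truth["p0"]).tolist(),
        "sigma2_e": truth["sigma2_e"],
    }
    (out / "truth.json").write_text(json.dumps(truth_out, indent=2))
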