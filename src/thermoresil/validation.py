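"""Parameter-recovery experiments for the REML machinery.

Each experiment simulates a three-generation pedigree with a realistic
sire:dam ratio, draws direct scalar phenotypes under the animal model at
stated generating parameters, re-estimates them with the package's own
AI-REML, and repeats over replicates.  The mean estimate over replicates
is the recovery statistic: an unbiased estimator should land on the
generating value up to Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np

from .quantgen import reml_bivariate, reml_univariate
from .simulate import SimConfig, simulate_direct_traits, simulate_pedigree

__all__ = ["recovery_h2", "recovery_ra", "replicate_seeds"]

#: three-generation design with ~3,000 phenotyped animals (the two
#: non-founder generations) and ~2% of males used as sires
DEFAULT_SIZES = (600, 1200, 1800)
LARGE_SIZES = (1000, 2000, 3000)  # ~5,000 phenotyped
N_SIRES = 25


def replicate_seeds(master_seed: int, n_reps: int) -> list[tuple[int, int]]:
    """(pedigree_seed, trait_seed) per replicate, all below 2**31."""
    out = []
    for r in range(1, n_reps + 1):
        ped_seed = (master_seed * 100003 + 7919 * r) % (2**31)
        trait_seed = (master_seed * 200003 + 104729 * r + 1) % (2**31)
        out.append((ped_seed, trait_seed))
    return out


def _pedigree(seed: int, sizes) -> tuple:
    cfg = SimConfig(seed=seed, generation_sizes=tuple(sizes), n_sires=N_SIRES)
    return simulate_pedigree(cfg)


def recovery_h2(
    h2_true: float,
    master_seed: int = 1,
    n_reps: int = 10,
    sizes=DEFAULT_SIZES,
) -> dict:
    """Univariate heritability recovery; returns per-replicate and mean."""
    ests = []
    for ped_seed, trait_seed in replicate_seeds(master_seed, n_reps):
        ped, _ = _pedigree(ped_seed, sizes)
        df = simulate_direct_traits(ped, h2_true, seed=trait_seed)
        est = reml_univariate(df, ped, fixed_factors=["group"], lrt=False)
        ests.append(float(est.h2[0]))
    arr = np.asarray(ests)
    return {"true": h2_true, "estimates": ests, "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)), "n_phenotyped": sum(sizes[1:]),
            "n_reps": n_reps}


def recovery_ra(
    h2_pair: tuple[float, float],
    ra_true: float,
    rp_true: float | None,
    master_seed: int = 1,
    n_reps: int = 10,
    sizes=DEFAULT_SIZES,
) -> dict:
    """Bivariate genetic-correlation recovery; returns mean r_A-hat."""
    ests = []
    for ped_seed, trait_seed in replicate_seeds(master_seed, n_reps):
        ped, _ = _pedigree(ped_seed, sizes)
        df = simulate_direct_traits(ped, h2_pair, r_a=ra_true, r_p=rp_true,
                                    seed=trait_seed)
        d1 = df[["animal_id", "group", "value"]]
        d2 = df[["animal_id", "group", "value2"]].rename(
            columns={"value2": "value"})
        est = reml_bivariate(d1, d2, ped, fixed_factors=["group"])
        ests.append(float(est.r_a))
    arr = np.asarray(ests)
    return {"true": ra_true, "estimates": ests, "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)), "n_phenotyped": sum(sizes[1:]),
            "n_reps": n_reps}
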