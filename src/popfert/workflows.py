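"""End-to-end study drivers on synthetic countries.

These functions freeze the study conditions used for parameter-recovery
and calibration checks: a 1950-2000 country with a refugee-style
migration wave (Gaussian in time, centred 1975 with a 4-year sd, peaked
at ages around 25) observed by four decennial censuses for the balancing
recovery study; and 1950-1990 countries with seeded random migration
waves and four censuses for the out-of-sample uncertainty study.
"""

from __future__ import annotations

import numpy as np

from . import balance, ccmpp, synthetic, uncertainty
from .census_prep import CensusObservation

BALANCE_CENSUS_YEARS = (1960, 1970, 1980, 1990)
BUMP_CENTER, BUMP_SD, BUMP_AMPLITUDE = 1975, 4.0, 0.012
CALIBRATION_CENSUS_YEARS = (1955, 1963, 1975, 1985)


def exact_census(truth, year: int) -> CensusObservation:
    """Noise-free enumeration in 5-year groups (completeness 1, no
    heaping), with adjusted counts set; the balancing model's likelihood
    input under ideal observation."""
    starts, ends, grouped = synthetic._group_counts(
        truth.true_pop.at(year), "five")
    c = CensusObservation(location="synthetic", year=float(year),
                          age_start=starts, age_end=ends, counts=grouped)
    c.adjusted = c.counts
    return c


def back_projected_init(truth, anchor_year: int) -> np.ndarray:
    """Initial 1950 baseline: zero-migration back-projection of the
    oldest census year's counts (measured with substantial error)."""
    grid = ccmpp.back_project(truth.true_pop.at(anchor_year), anchor_year,
                              truth.survivorship,
                              anchor_year - int(truth.years[0]))
    return grid.at(int(truth.years[0]))


def migration_bump_truth(seed: int = 5) -> "synthetic.SyntheticTruth":
    shocks = {y: BUMP_AMPLITUDE * np.exp(-0.5 * ((y - BUMP_CENTER)
                                                 / BUMP_SD) ** 2)
              for y in range(BUMP_CENTER - 12, BUMP_CENTER + 13)}
    sc = synthetic.CountryScenario(
        year_start=1950, year_end=2000, mig_shocks=shocks,
        mig_age_mode=25, mig_age_sd=6)
    return synthetic.make_true_country(sc, seed=seed)


def balance_recovery_study(seed: int = 5,
                           config: balance.BalanceConfig | None = None
                           ) -> dict:
    """Fit the balancing model on the migration-bump country and report
    recovery metrics against the known truth."""
    truth = migration_bump_truth(seed)
    censuses = [exact_census(truth, y) for y in BALANCE_CENSUS_YEARS]
    init = back_projected_init(truth, BALANCE_CENSUS_YEARS[0])
    cfg = config or balance.BalanceConfig()
    fit = balance.fit_map(censuses, truth.years, truth.true_asfr,
                          truth.true_srb, truth.survivorship, init, cfg)
    w_t = slice(BUMP_CENTER - 8 - 1950, BUMP_CENTER + 9 - 1950)
    w_a = slice(15, 40)
    r = float(np.corrcoef(
        truth.true_mig.data[w_t, :, w_a].ravel(),
        fit.migration.data[w_t, :, w_a].ravel())[0, 1])
    rmse_ratio = float(np.std(fit.migration.data - truth.true_mig.data)
                       / np.std(truth.true_mig.data))
    census_pop_err = max(
        abs(fit.trajectory.total(y) / truth.true_pop.total(y) - 1.0)
        for y in BALANCE_CENSUS_YEARS)
    return {"truth": truth, "censuses": censuses, "fit": fit,
            "r2": fit.r2, "bump_pearson_r": r, "mig_rmse_ratio": rmse_ratio,
            "census_pop_err": census_pop_err}


def _calibration_replicate(seed: int):
    sc = synthetic.CountryScenario(year_start=1950, year_end=1990,
                                   mig_random_sd=0.004, perturb_sd=0.03)
    truth = synthetic.make_true_country(sc, seed=seed)
    censuses = [exact_census(truth, y) for y in CALIBRATION_CENSUS_YEARS]
    return truth, censuses


def _calibration_config() -> balance.BalanceConfig:
    # coarser knots than the recovery study: many refits, and only the
    # size of held-out errors matters here, not fine migration structure
    return balance.BalanceConfig(knot_age_step=5, knot_time_step=5)


def _refit(truth, kept):
    cfg = _calibration_config()
    init = back_projected_init(truth, kept[0].mid_year)
    fit = balance.fit_map(kept, truth.years, truth.true_asfr,
                          truth.true_srb, truth.survivorship, init, cfg)
    return fit.trajectory


def oos_error_study(n_train: int = 8, seed: int = 0,
                    n_draws: int = 1000) -> uncertainty.ErrorModel:
    """Pool hold-one-census-out errors over training replicates."""
    errors = []
    for i in range(n_train):
        truth, censuses = _calibration_replicate(seed * 1000 + i)
        errors += uncertainty.holdout_errors(
            censuses, lambda kept: _refit(truth, kept))
    return uncertainty.fit_oos_error_model(errors, n_draws=n_draws)


def coverage_study(model: uncertainty.ErrorModel, n_rep: int = 50,
                   seed: int = 1) -> float:
    """Fraction of fresh held-out census totals inside the 95% UI."""
    held_idx = 2            # the 1975 census; nearest kept gap is 10 years
    covered = 0
    for i in range(n_rep):
        rep_seed = seed * 100_000 + 500 + i
        truth, censuses = _calibration_replicate(rep_seed)
        held = censuses[held_idx]
        kept = [c for c in censuses if c is not held]
        traj = _refit(truth, kept)
        gaps = np.array([min(abs(int(y) - c.mid_year) for c in kept)
                         for y in truth.years], float)
        draws = uncertainty.population_draws(traj, gaps, set(), model,
                                             seed=rep_seed)
        lo, hi = draws.ui()
        yi = truth.true_pop.year_index(held.mid_year)
        obs = float(held.adjusted.sum())
        covered += bool(lo[yi] <= obs <= hi[yi])
    return covered / n_rep
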