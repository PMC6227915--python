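"""Population uncertainty from out-of-sample predictive validity.

Two sources of uncertainty are combined: error between censuses,
estimated by holding out one census at a time, refitting the balancing
model, and relating the absolute relative error to the number of years
to the nearest remaining census (isotonic, so error never shrinks with
distance); and uncertainty in census completeness, propagated from the
completeness model's coefficient variance-covariance.  Draws of relative
error are fully correlated across ages within a location-year; in years
with population-registry counts only the completeness term applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm
from sklearn.isotonic import IsotonicRegression

from .grids import PopulationGrid

_HALF_NORMAL = np.sqrt(np.pi / 2.0)   # E|N(0,s)| = s * sqrt(2/pi)


@dataclass
class ErrorModel:
    """sd of relative population error vs years-to-nearest-census."""

    gap_grid: np.ndarray
    sigma_gap: np.ndarray
    sigma_pes: float
    n_draws: int = 1000

    def __post_init__(self):
        self.gap_grid = np.asarray(self.gap_grid, float)
        self.sigma_gap = np.asarray(self.sigma_gap, float)
        if np.any(np.diff(self.sigma_gap) < -1e-12):
            raise ValueError("sigma_gap must be nondecreasing in the gap")
        if np.any(self.sigma_gap < 0) or self.sigma_pes < 0:
            raise ValueError("error sds must be nonnegative")

    def sigma_at(self, gaps) -> np.ndarray:
        return np.interp(np.asarray(gaps, float),
                         self.gap_grid, self.sigma_gap)


def holdout_errors(censuses, refit) -> list:
    """Hold-one-census-out protocol.

    ``refit(kept_censuses)`` returns a fitted trajectory (PopulationGrid).
    For each held-out census, records (gap to nearest kept census, signed
    relative error of the fitted total vs the adjusted census total).
    """
    if len(censuses) < 2:
        raise ValueError("need >= 2 censuses to hold one out")
    out = []
    for i, held in enumerate(censuses):
        kept = [c for j, c in enumerate(censuses) if j != i]
        traj = refit(kept)
        counts = held.adjusted if held.adjusted is not None else held.counts
        obs_total = float(counts.sum())
        fit_total = float(traj.at(held.mid_year).sum())
        gap = min(abs(held.mid_year - c.mid_year) for c in kept)
        out.append((gap, fit_total / obs_total - 1.0))
    return out


def fit_oos_error_model(errors, completeness_model=None,
                        typical_sdi: float = 0.6,
                        n_draws: int = 1000) -> ErrorModel:
    """Pool (gap, relative error) pairs into an isotonic error model.

    Absolute errors are scaled to normal sds (E|N| = sd * sqrt(2/pi)) and
    regressed isotonically on the gap.  ``sigma_pes`` comes from the
    completeness model's coefficient covariance by the delta method.
    """
    errors = list(errors)
    if len(errors) < 2:
        raise ValueError("need >= 2 held-out errors")
    gaps = np.array([e[0] for e in errors], float)
    sds = np.abs([e[1] for e in errors]) * _HALF_NORMAL
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    grid = np.unique(gaps)
    fitted = iso.fit(gaps, sds).predict(grid)
    sigma_pes = 0.0
    if completeness_model is not None:
        c = float(completeness_model.predict(typical_sdi))
        sigma_pes = float(completeness_model.predict_sd(typical_sdi)[0] / c)
    return ErrorModel(gap_grid=grid, sigma_gap=np.maximum(fitted, 0.0),
                      sigma_pes=sigma_pes, n_draws=n_draws)


@dataclass
class PopulationDraws:
    """Draws of relative population error, correlated across ages."""

    mean: PopulationGrid
    eps: np.ndarray                 # (n_draws, T)

    def totals(self) -> np.ndarray:
        return self.mean.total()[None, :] * (1.0 + self.eps)

    def ui(self, level: float = 95.0):
        """(lower, upper) percentile bounds on total population per year."""
        lo, hi = np.percentile(self.totals(),
                               [(100 - level) / 2, 100 - (100 - level) / 2],
                               axis=0)
        return lo, hi

    def age_ui(self, level: float = 95.0):
        """(lower, upper) (T, 2, 96) bounds; errors are fully age-correlated,
        so bounds scale the mean age pattern."""
        q_lo, q_hi = np.percentile(self.eps,
                                   [(100 - level) / 2,
                                    100 - (100 - level) / 2], axis=0)
        return (self.mean.data * (1 + q_lo)[:, None, None],
                self.mean.data * (1 + q_hi)[:, None, None])


def population_draws(mean_pop: PopulationGrid, gaps, registry_years,
                     model: ErrorModel, seed: int = 0) -> PopulationDraws:
    """Draw relative errors per year and apply them to the mean.

    eps ~ Normal(0, sigma_gap(gap)^2 + sigma_pes^2), truncated at -0.9 so
    drawn populations stay positive; the between-census term is zeroed in
    registry years.
    """
    n = model.n_draws
    if n < 2:
        raise ValueError("need at least 2 draws")
    if n < 100:
        warnings.warn(f"only {n} draws; percentiles will be noisy")
    gaps = np.asarray(gaps, float)
    if gaps.size != mean_pop.years.size:
        raise ValueError("need one gap per year")
    registry = np.isin(mean_pop.years, list(registry_years))
    var = model.sigma_at(gaps) ** 2 + model.sigma_pes ** 2
    var[registry] = model.sigma_pes ** 2
    sd = np.sqrt(var)
    rng = np.random.default_rng(seed)
    eps = np.zeros((n, gaps.size))
    pos = sd > 0
    if pos.any():
        a = -0.9 / sd[pos]
        eps[:, pos] = truncnorm.rvs(
            a, np.inf, loc=0.0, scale=sd[pos],
            size=(n, int(pos.sum())), random_state=rng)
    return PopulationDraws(mean=mean_pop, eps=eps)
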