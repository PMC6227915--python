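"""Bayesian demographic balancing: baseline population and age-time
correlated net migration consistent with fertility, mortality and
adjusted census counts.

The model treats census counts (aggregated to the census age groups) as
lognormal observations of the projected population, with an age-varying
variance schedule (inflated at the youngest ages, increasing after 45).
The unknowns are the log baseline population (Gaussian prior around the
initial, back-projected baseline, which is assumed to be measured with
substantial error) and per-capita net migration rates on a coarsened
age-time knot grid with a mean-zero AR1(age) x AR1(time) Gaussian prior.
Because the cohort-component projection is exactly linear in baseline
counts and migrant counts once fertility, mortality and the sex ratio at
birth are fixed, the projection is precomputed as a design matrix by
unit projections, and the posterior mode is found by L-BFGS with
analytic gradients.  Migration rates are converted to counts against a
fixed reference population (the zero-migration projection of the initial
baseline).

Model versions differ by the maximum census age admitted to the
likelihood; version selection prefers the highest maximum age among
versions with near-best in-sample fit and small old-age migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import ccmpp
from .grids import N_AGES, PopulationGrid, MigrationSurface
from .census_prep import CensusObservation


@dataclass
class BalanceConfig:
    sigma_base: float = 0.1          # log-baseline prior sd
    sigma_mig: float = 0.05          # marginal sd of migration rates
    rho_age: float = 0.9
    rho_time: float = 0.7
    sigma_census: float = 0.02       # census log-sd, ages 5-44
    young_inflation: float = 3.0     # multiplier for ages 0-4
    old_inflation: float = 4.0       # multiplier reached at the open age
    knot_age_step: int = 2
    knot_time_step: int = 2
    max_census_age_candidates: tuple = (95, 75, 65)
    gtol: float = 1e-6
    maxiter: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.rho_age < 1 and 0 < self.rho_time < 1):
            raise ValueError("AR1 correlations must lie in (0, 1)")
        if min(self.sigma_base, self.sigma_mig, self.sigma_census) <= 0:
            raise ValueError("prior sds must be positive")


def variance_schedule(config: BalanceConfig) -> np.ndarray:
    """Census log-count sd by single age: inflated under 5, flat 5-44,
    log-linearly increasing from 45 to the open interval."""
    ages = np.arange(N_AGES)
    sd = np.full(N_AGES, config.sigma_census)
    sd[ages < 5] *= config.young_inflation
    old = ages >= 45
    slope = np.log(config.old_inflation) / (95.0 - 45.0)
    sd[old] *= np.exp(slope * (ages[old] - 45.0))
    return sd


def _ar1_precision(n: int, rho: float) -> np.ndarray:
    """Precision of a unit-variance AR1 process."""
    Q = np.zeros((n, n))
    if n == 1:
        return np.array([[1.0]])
    idx = np.arange(n)
    Q[idx, idx] = 1.0 + rho ** 2
    Q[0, 0] = Q[-1, -1] = 1.0
    Q[idx[:-1], idx[1:]] = -rho
    Q[idx[1:], idx[:-1]] = -rho
    return Q / (1.0 - rho ** 2)


def _hat_basis(grid: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Linear interpolation (hat function) basis, (len(grid), len(knots))."""
    B = np.zeros((grid.size, knots.size))
    for j in range(knots.size):
        e = np.zeros(knots.size)
        e[j] = 1.0
        B[:, j] = np.interp(grid, knots, e)
    return B


def _census_cells(censuses, years, sd_by_age, max_census_age):
    """Flatten usable census age-sex cells into a cell list."""
    cells = []
    for c in censuses:
        counts = c.adjusted if c.adjusted is not None else c.counts
        try:
            yi = int(np.where(years == c.mid_year)[0][0])
        except IndexError:
            raise ValueError(f"census year {c.year} outside the model years")
        for g in range(c.age_start.size):
            lo = int(c.age_start[g])
            hi = int(c.age_end[g]) if c.age_end[g] > 0 else 96
            hi = min(hi, 96)
            if c.drop_under5 and lo < 5:
                continue
            if lo > max_census_age:
                continue
            if c.age_end[g] == -1 and max_census_age < 95:
                continue
            mid = min(0.5 * (lo + (hi if hi < 96 else 100)), 95)
            sd = float(sd_by_age[int(mid)])
            for s in (0, 1):
                if counts[s, g] <= 0:
                    continue
                cells.append((yi, s, lo, hi, float(np.log(counts[s, g])), sd))
    return cells


@dataclass
class BalanceFit:
    baseline: np.ndarray                   # (2, 96) MAP baseline
    migration: MigrationSurface            # counts per interval
    migration_rates: np.ndarray            # (T, 2, 96) per-capita rates
    trajectory: PopulationGrid
    flows: object
    r2: float
    neg_log_posterior: float
    max_census_age: int
    config: BalanceConfig
    cells: list = field(default_factory=list)
    n_clipped: int = 0


def _build_design(init_baseline, years, asfr, srb, surv, cells,
                  age_knots, time_knots, refpop):
    """Columns of the linear map from (baseline counts, migration-rate
    knots) to model counts at the census cells, by unit projections."""
    T = years.size - 1
    n_cells = len(cells)

    def cells_of(grid_data):
        out = np.empty(n_cells)
        for i, (yi, s, lo, hi, _, _) in enumerate(cells):
            out[i] = grid_data[yi, s, lo:hi].sum()
        return out

    def run(baseline, mig_data):
        mig = MigrationSurface(years=years[:-1], data=mig_data)
        grid, _ = ccmpp.project(baseline, years, asfr, srb, surv, mig,
                                clip_negative=False)
        return cells_of(grid.data)

    zero_mig = np.zeros((T, 2, N_AGES))
    A_b = np.empty((n_cells, 2 * N_AGES))
    for s in (0, 1):
        for a in range(N_AGES):
            e = np.zeros((2, N_AGES))
            e[s, a] = 1.0
            A_b[:, s * N_AGES + a] = run(e, zero_mig)

    B_age = _hat_basis(np.arange(N_AGES, dtype=float),
                       age_knots.astype(float))
    B_time = _hat_basis(np.arange(T, dtype=float), time_knots.astype(float))
    nk = age_knots.size * time_knots.size
    A_g = np.empty((n_cells, 2 * nk))
    zero_base = np.zeros((2, N_AGES))
    col = 0
    for s in (0, 1):
        for jt in range(time_knots.size):
            for ja in range(age_knots.size):
                mig_data = np.zeros((T, 2, N_AGES))
                mig_data[:, s, :] = np.outer(B_time[:, jt], B_age[:, ja])
                mig_data *= refpop
                A_g[:, col] = run(zero_base, mig_data)
                col += 1
    return A_b, A_g, B_age, B_time


def fit_map(censuses, years, asfr, srb, surv,
            init_baseline: np.ndarray,
            config: BalanceConfig | None = None,
            max_census_age: int = 95) -> BalanceFit:
    """MAP fit of baseline population and net migration.

    With no censuses at all the prior mode is returned (zero migration,
    baseline at its initialization); censuses that are supplied but fully
    excluded raise an error.
    """
    config = config or BalanceConfig()
    years = np.asarray(years, dtype=int)
    T = years.size - 1
    asfr = np.asarray(asfr, float)
    if asfr.shape == (T, 9):
        asfr = ccmpp.expand_asfr_to_single(asfr)
    srb = np.broadcast_to(np.asarray(srb, float), (T,))
    init_baseline = np.asarray(init_baseline, float)

    sd_by_age = variance_schedule(config)
    cells = _census_cells(censuses, years, sd_by_age, max_census_age)
    if censuses and not cells:
        raise ValueError("all census cells excluded; nothing to fit")

    # reference population for the rate -> count conversion
    ref_grid, _ = ccmpp.project(init_baseline, years, asfr, srb, surv)
    refpop = np.maximum(ref_grid.data[:-1], 1.0)

    age_knots = np.unique(np.append(
        np.arange(0, N_AGES, config.knot_age_step), N_AGES - 1))
    time_knots = np.unique(np.append(
        np.arange(0, T, config.knot_time_step), T - 1))
    nk = age_knots.size * time_knots.size

    def rates_to_counts_surface(u):
        """u: (2, nt, na) knot rates -> (T, 2, 96) migrant counts."""
        out = np.zeros((T, 2, N_AGES))
        for s in (0, 1):
            surface = B_time @ u[s] @ B_age.T          # (T, 96)
            out[:, s, :] = surface * refpop[:, s, :]
        return out

    if not cells:
        B_age = _hat_basis(np.arange(N_AGES, dtype=float),
                           age_knots.astype(float))
        B_time = _hat_basis(np.arange(T, dtype=float),
                            time_knots.astype(float))
        return _finalize(init_baseline,
                         np.zeros((2, time_knots.size, age_knots.size)),
                         years, asfr, srb, surv, refpop, B_age, B_time,
                         config, max_census_age, cells, neg_log_post=0.0)

    A_b, A_g, B_age, B_time = _build_design(
        init_baseline, years, asfr, srb, surv, cells, age_knots,
        time_knots, refpop)

    log_c = np.array([c[4] for c in cells])
    w = 1.0 / np.array([c[5] for c in cells]) ** 2

    Q1 = _ar1_precision(age_knots.size, config.rho_age)
    Q2 = _ar1_precision(time_knots.size, config.rho_time)
    Q = np.kron(Q2, Q1) / config.sigma_mig ** 2       # order: (time, age)

    b0 = np.log(np.maximum(init_baseline.ravel(), 1e-6))
    n_b = b0.size

    def objective(theta):
        b = theta[:n_b]
        u = theta[n_b:]
        Nb = np.exp(b)
        M = A_b @ Nb + A_g @ u
        M_safe = np.maximum(M, 1e-6)
        r = np.log(M_safe) - log_c
        f_data = 0.5 * float(w @ r ** 2)
        g_cells = w * r / M_safe
        grad_b = (A_b.T @ g_cells) * Nb
        grad_u = A_g.T @ g_cells
        db = b - b0
        f_base = 0.5 * float(db @ db) / config.sigma_base ** 2
        grad_b += db / config.sigma_base ** 2
        f_mig = 0.0
        grad_u = grad_u.copy()
        for s in (0, 1):
            us = u[s * nk:(s + 1) * nk]
            Qu = Q @ us
            f_mig += 0.5 * float(us @ Qu)
            grad_u[s * nk:(s + 1) * nk] += Qu
        return (f_data + f_base + f_mig,
                np.concatenate([grad_b, grad_u]))

    theta0 = np.concatenate([b0, np.zeros(2 * nk)])
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.maxiter,
                            "gtol": config.gtol, "ftol": 1e-12})
    if not (res.success or res.status == 1):
        raise RuntimeError(f"balance optimizer did not converge: "
                           f"{res.message} (nit={res.nit})")
    b = res.x[:n_b]
    u = res.x[n_b:].reshape(2, time_knots.size, age_knots.size)
    return _finalize(np.exp(b).reshape(2, N_AGES), u, years, asfr, srb,
                     surv, refpop, B_age, B_time, config, max_census_age,
                     cells, neg_log_post=float(res.fun))


def _finalize(baseline, u, years, asfr, srb, surv, refpop, B_age, B_time,
              config, max_census_age, cells, neg_log_post):
    T = years.size - 1
    rates = np.zeros((T, 2, N_AGES))
    counts = np.zeros((T, 2, N_AGES))
    for s in (0, 1):
        surface = B_time @ u[s] @ B_age.T
        rates[:, s, :] = surface
        counts[:, s, :] = surface * refpop[:, s, :]
    mig = MigrationSurface(
        years=years[:-1], data=counts,
        hyperparams={"sigma_mig": config.sigma_mig,
                     "rho_age": config.rho_age,
                     "rho_time": config.rho_time})
    grid, flows = ccmpp.project(baseline, years, asfr, srb, surv, mig)
    fit = BalanceFit(
        baseline=baseline, migration=mig, migration_rates=rates,
        trajectory=grid, flows=flows, r2=np.nan,
        neg_log_posterior=neg_log_post, max_census_age=max_census_age,
        config=config, cells=cells, n_clipped=getattr(grid, "n_clipped", 0))
    if len(cells) >= 2:
        fit.r2 = _r2_from_cells(grid, cells)
    return fit


def _r2_from_cells(grid, cells):
    logm, logc = [], []
    for yi, s, lo, hi, lc, _ in cells:
        m = grid.data[yi, s, lo:hi].sum()
        if m > 0:
            logm.append(np.log(m))
            logc.append(lc)
    logm = np.array(logm)
    logc = np.array(logc)
    ss_res = float(np.sum((logc - logm) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def insample_fit(fit: BalanceFit, censuses=None) -> float:
    """R-squared of log fitted counts vs log adjusted census counts."""
    cells = fit.cells
    if censuses is not None:
        cells = _census_cells(censuses, fit.trajectory.years,
                              variance_schedule(fit.config),
                              fit.max_census_age)
    if len(cells) < 2:
        raise ValueError("need at least 2 census cells for R^2")
    return _r2_from_cells(fit.trajectory, cells)


def select_version(fits, r2_margin: float = 0.005,
                   old_age_cap: float = 0.01) -> BalanceFit:
    """Choose among model versions fitted with different maximum census
    ages: prefer the highest maximum age among versions whose R^2 is
    within ``r2_margin`` of the best and whose mean absolute migration
    rate over ages 55+ is below ``old_age_cap``; fall back to best R^2."""
    if not fits:
        raise ValueError("no fits supplied")
    best_r2 = max(f.r2 for f in fits)
    eligible = [
        f for f in fits
        if f.r2 >= best_r2 - r2_margin
        and float(np.mean(np.abs(f.migration_rates[:, :, 55:]))) < old_age_cap
    ]
    if eligible:
        return max(eligible, key=lambda f: f.max_census_age)
    return max(fits, key=lambda f: f.r2)
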