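"""Single-year cohort-component projection, forward and backward.

Within each one-year interval the conventions are: half of net migrants
arrive at the interval start, cohorts are survived one age step (the open
interval 95+ pools with age 94 and is survived with a T-ratio), the other
half of migrants arrive at the interval end, and births are computed from
age-specific fertility applied to the mean of start- and end-of-interval
female population.  Vital flows are recorded so that the balancing
identity N(t+1) = N(t) + B - D + G holds to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import N_AGES, OPEN_AGE, PopulationGrid, VitalFlows, MigrationSurface
from .lifetables import CompleteLifeTable, survivorship_ratios

logger = logging.getLogger(__name__)

FERTILE_AGES = np.arange(10, 55)      # single ages with nonzero fertility
ASFR_GROUP_STARTS = np.arange(10, 55, 5)   # 10-14 .. 50-54


def expand_asfr_to_single(group_asfr: np.ndarray) -> np.ndarray:
    """5-year-group ASFR (.., 9) to single ages 10..54, constant in group."""
    group_asfr = np.asarray(group_asfr, dtype=float)
    if group_asfr.shape[-1] != 9:
        raise ValueError("expected 9 five-year groups 10-14 .. 50-54")
    return np.repeat(group_asfr, 5, axis=-1)


@dataclass
class ProjectionSurvivorship:
    """Per-interval, per-sex survivorship ratios for projection."""

    years: np.ndarray            # (T,) interval start years
    s_birth: np.ndarray          # (T, 2)
    s_closed: np.ndarray         # (T, 2, 94) for ages 0..93
    s_open: np.ndarray           # (T, 2) pooled 94 & 95+ ratio

    @classmethod
    def from_lifetables(cls, years, tables) -> "ProjectionSurvivorship":
        """``tables``: sequence of (female, male) CompleteLifeTable per year."""
        years = np.asarray(years, dtype=int)
        T = years.size
        sb = np.empty((T, 2))
        sc = np.empty((T, 2, 94))
        so = np.empty((T, 2))
        for t, pair in enumerate(tables):
            for s, lt in enumerate(pair):
                r = survivorship_ratios(lt)
                sb[t, s] = r.s_birth
                sc[t, s] = r.s_closed
                so[t, s] = r.s_open
        return cls(years=years, s_birth=sb, s_closed=sc, s_open=so)

    @classmethod
    def constant(cls, years, s_birth=1.0, s_closed=1.0, s_open=1.0):
        years = np.asarray(years, dtype=int)
        T = years.size
        return cls(
            years=years,
            s_birth=np.full((T, 2), s_birth, dtype=float),
            s_closed=np.full((T, 2, 94), s_closed, dtype=float),
            s_open=np.full((T, 2), s_open, dtype=float),
        )


def _step(N, G, asfr_single, srb, sb, sc, so, clip_negative=True):
    """One projection year.  Returns (N_next, births(2,), deaths(2,96),
    migrants_effective(2,96), n_clipped)."""
    N1 = N + 0.5 * G
    N2 = np.zeros_like(N)
    N2[:, 1:95] = N1[:, 0:94] * sc
    pooled = N1[:, 94] + N1[:, 95]
    N2[:, 95] += pooled * so
    deaths = np.zeros_like(N)
    deaths[:, 0:94] = N1[:, 0:94] * (1.0 - sc)
    # pooled open-interval deaths attributed to the open age
    deaths[:, 95] = pooled * (1.0 - so)
    deaths[:, 94] = 0.0

    N_end = N2 + 0.5 * G
    # births from mean female exposure; end-of-interval fertile-age counts
    # do not depend on this year's births, so no circularity
    exposure = 0.5 * (N[0, FERTILE_AGES] + N_end[0, FERTILE_AGES])
    B = float(asfr_single @ exposure)
    bf = B / (1.0 + srb)
    births = np.array([bf, B - bf])
    N_end[:, 0] += births * sb
    deaths[:, 0] += births * (1.0 - sb)

    mig_eff = G.copy()
    n_clipped = 0
    if clip_negative:
        neg = N_end < 0
        n_clipped = int(neg.sum())
        if n_clipped:
            # fold the correction into net migration to keep the balance exact
            mig_eff = mig_eff - np.where(neg, N_end, 0.0)
            N_end = np.where(neg, 0.0, N_end)
    return N_end, births, deaths, mig_eff, n_clipped


def project(baseline: np.ndarray,
            years,
            asfr: np.ndarray,
            srb: np.ndarray,
            surv: ProjectionSurvivorship,
            mig: MigrationSurface | None = None,
            clip_negative: bool = True):
    """Project a baseline population forward over consecutive years.

    Parameters
    ----------
    baseline : (2, 96) counts at the first year of ``years``.
    years : grid years (length T+1 for T projection intervals).
    asfr : (T, 45) single-age fertility, or (T, 9) five-year groups.
    srb : (T,) male births per female birth.
    surv : per-interval survivorship.
    mig : net migrant counts per interval; zeros when None.

    Returns (PopulationGrid, VitalFlows).
    """
    years = np.asarray(years, dtype=int)
    if years.size < 2:
        raise ValueError("need at least one projection interval")
    T = years.size - 1
    asfr = np.asarray(asfr, dtype=float)
    if asfr.shape == (T, 9):
        asfr = expand_asfr_to_single(asfr)
    if asfr.shape != (T, FERTILE_AGES.size):
        raise ValueError("asfr must be (T, 45) single ages or (T, 9) groups")
    srb = np.broadcast_to(np.asarray(srb, dtype=float), (T,))
    if mig is None:
        mig = MigrationSurface.zeros(years[:-1])
    if mig.is_rate:
        raise ValueError("project needs migrant counts, not rates")
    if mig.data.shape[0] != T:
        raise ValueError("migration surface must cover every interval")

    data = np.empty((T + 1, 2, N_AGES))
    data[0] = np.asarray(baseline, dtype=float)
    if np.any(data[0] < 0):
        raise ValueError("negative baseline counts")
    births = np.empty((T, 2))
    deaths = np.empty((T, 2, N_AGES))
    migrants = np.empty((T, 2, N_AGES))
    n_clipped = 0
    for t in range(T):
        data[t + 1], births[t], deaths[t], migrants[t], nc = _step(
            data[t], mig.data[t], asfr[t], srb[t],
            surv.s_birth[t], surv.s_closed[t], surv.s_open[t],
            clip_negative=clip_negative,
        )
        n_clipped += nc
    if n_clipped:
        logger.info("project: clipped %d negative cells to zero", n_clipped)
    grid = PopulationGrid(years=years, data=data)
    flows = VitalFlows(years=years[:-1], births=births, deaths=deaths,
                       migrants=migrants)
    grid.n_clipped = n_clipped
    return grid, flows


def back_project(anchor: np.ndarray,
                 anchor_year: int,
                 surv: ProjectionSurvivorship,
                 years_back: int) -> PopulationGrid:
    """Reverse cohort-component projection under zero net migration.

    Each step divides next-year counts by the interval survivorship; the
    pooled open interval is disaggregated proportionally to the anchor's
    own split between age 94 and 95+.  Age 0 of year t-1 is recovered from
    the age-1 survivors of year t, so no birth series is required.  The
    result is the low-confidence initial baseline for the balancing model.
    """
    if years_back < 1:
        raise ValueError("years_back must be >= 1")
    anchor = np.asarray(anchor, dtype=float)
    years = np.arange(anchor_year - years_back, anchor_year + 1)
    data = np.empty((years_back + 1, 2, N_AGES))
    data[-1] = anchor
    tot_open = anchor[:, 94] + anchor[:, 95]
    with np.errstate(invalid="ignore", divide="ignore"):
        share94 = np.where(tot_open > 0, anchor[:, 94] / tot_open, 0.5)
    for k in range(years_back):
        t = years_back - 1 - k                 # interval index into data
        yi = int(np.searchsorted(surv.years, years[t]))
        if yi >= surv.years.size or surv.years[yi] != years[t]:
            raise ValueError(f"no survivorship for back year {years[t]}")
        sc, so = surv.s_closed[yi], surv.s_open[yi]
        if np.any(sc == 0) or np.any(so == 0):
            raise ValueError("zero survivorship; cannot invert")
        cur = data[t + 1]
        prev = np.zeros((2, N_AGES))
        prev[:, 0:94] = cur[:, 1:95] / sc
        pooled = cur[:, 95] / so
        prev[:, 94] = pooled * share94
        prev[:, 95] = pooled * (1.0 - share94)
        data[t] = prev
    grid = PopulationGrid(years=years, data=data)
    grid.low_confidence = True
    return grid


def balance_residual(grid: PopulationGrid, flows: VitalFlows) -> np.ndarray:
    """Per-interval residual N(t+1) - (N(t) + B - D + G), totals over age/sex."""
    if flows.years.size != grid.years.size - 1:
        raise ValueError("flows must cover exactly the grid intervals")
    n = grid.data.sum(axis=(1, 2))
    b = flows.births.sum(axis=1)
    d = flows.deaths.sum(axis=(1, 2))
    g = flows.migrants.sum(axis=(1, 2))
    return n[1:] - (n[:-1] + b - d + g)
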