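"""Synthetic countries with known truth and realistically corrupted
observations.

The generator builds a complete demographic truth — single-age fertility
(a Hadwiger-type unimodal curve over maternal ages 10-54), mortality
(Gompertz-Makeham with a childhood component, improving over time), a
smooth age-peaked migration surface with optional refugee-style shocks,
a sex ratio at birth, and a development index path — and projects it
with the cohort-component engine so the balancing identity holds
exactly.  Observation operators then corrupt the truth the way real
data are corrupted: census undercount that varies with development and
age, terminal-digit age heaping, vital-registration source bias,
birth-history recall noise, and summary-birth-history cohort
children-ever-born.  All noise is lognormal on rates (rates stay
positive) and flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import ccmpp
from .grids import N_AGES, PopulationGrid, MigrationSurface
from .lifetables import CompleteLifeTable
from .ccmpp import ProjectionSurvivorship
from .census_prep import CensusObservation, PESRecord
from .fertility import FertilityObservation, cohort_ceb_from_single

FERTILE_AGES = ccmpp.FERTILE_AGES


# ------------------------------------------------------------ truth

def hadwiger_asfr(tfr: float, mode: float = 27.0, width: float = 3.3
                  ) -> np.ndarray:
    """Single-age ASFR (ages 10..54) with a Hadwiger-type unimodal shape,
    scaled so the rates sum to the target TFR."""
    x = np.arange(10, 55) - 9.5
    c = mode - 9.5
    h = (width / c) * (c / x) ** 1.5 * np.exp(
        -width ** 2 * (c / x + x / c - 2.0))
    return tfr * h / h.sum()


def gompertz_makeham_mx(ages, child=0.08, child_decay=1.1,
                        background=5e-4, gomp=3e-5, gomp_slope=0.095,
                        scale=1.0) -> np.ndarray:
    """Death rate by single age: childhood + background + senescent."""
    a = np.asarray(ages, float)
    return scale * (child * np.exp(-child_decay * a) + background
                    + gomp * np.exp(gomp_slope * a))


def table_from_mx(mx: np.ndarray, a0: float = 0.3) -> CompleteLifeTable:
    """Complete life table from a single-age hazard (ages 0..110)."""
    mx = np.asarray(mx, float)
    ax = np.full(111, 0.5)
    ax[0] = a0
    q = mx / (1.0 + (1.0 - ax) * mx)
    q = np.clip(q, 0.0, 1.0)
    q[110] = 1.0
    ax[110] = min(1.0 / max(mx[110], 1e-6), 10.0)
    return CompleteLifeTable(qx=q, ax=ax)


@dataclass
class CountryScenario:
    """Parametric demographic scenario for a synthetic country."""

    year_start: int = 1950
    year_end: int = 2000
    baseline_total: float = 1_000_000.0
    stable_growth: float = 0.02          # shapes the baseline age pyramid
    tfr_start: float = 6.0
    tfr_end: float = 3.0
    asfr_mode: float = 27.0
    asfr_width: float = 3.3
    mort_scale: float = 1.0
    mort_trend: float = 0.01             # annual proportional decline in mx
    male_excess: float = 1.25
    srb: float = 1.05
    srb_end: float | None = None
    mig_rate: float = 0.0                # baseline net migration rate level
    mig_age_mode: float = 25.0
    mig_age_sd: float = 8.0
    mig_shocks: dict = field(default_factory=dict)   # year -> extra rate
    mig_random_sd: float = 0.0           # sd of a seeded AR1 amplitude path
    mig_random_rho: float = 0.85
    sdi_start: float = 0.35
    sdi_end: float = 0.7
    perturb_sd: float = 0.0              # seed-driven lognormal scenario jitter


@dataclass
class SyntheticTruth:
    """Known truth for one synthetic country."""

    true_pop: PopulationGrid
    true_asfr: np.ndarray                # (T, 45) single ages 10..54
    true_mx: np.ndarray                  # (T, 2, 111)
    true_mig: MigrationSurface           # counts per interval
    true_srb: np.ndarray                 # (T,)
    sdi: np.ndarray                      # (T+1,) per grid year
    survivorship: ProjectionSurvivorship
    lifetables: list                     # [(female, male) CompleteLifeTable]
    flows: object
    scenario: CountryScenario
    seed: int

    @property
    def years(self) -> np.ndarray:
        return self.true_pop.years


def make_true_country(scenario: CountryScenario | None = None,
                      seed: int = 0) -> SyntheticTruth:
    """Build a deterministic truth for the scenario (jitter from seed)."""
    sc = scenario or CountryScenario()
    if sc.year_end - sc.year_start < 3:
        raise ValueError("year range must span at least 3 years")
    if sc.baseline_total < 0:
        raise ValueError("negative baseline population")
    rng = np.random.default_rng(seed)
    jit = (np.exp(rng.normal(0.0, sc.perturb_sd, size=3))
           if sc.perturb_sd > 0 else np.ones(3))

    years = np.arange(sc.year_start, sc.year_end + 1)
    T = years.size - 1
    frac = np.linspace(0.0, 1.0, T)

    # fertility truth
    tfr_path = (sc.tfr_start + (sc.tfr_end - sc.tfr_start) * frac) * jit[0]
    asfr = np.stack([hadwiger_asfr(t, sc.asfr_mode, sc.asfr_width)
                     for t in tfr_path])

    # mortality truth, improving over time
    ages111 = np.arange(111)
    mx = np.empty((T, 2, 111))
    tables = []
    for t in range(T):
        level = sc.mort_scale * jit[1] * np.exp(-sc.mort_trend * t)
        mx_f = gompertz_makeham_mx(ages111, scale=level)
        mx_m = gompertz_makeham_mx(ages111, scale=level * sc.male_excess)
        mx[t, 0], mx[t, 1] = mx_f, mx_m
        tables.append((table_from_mx(mx_f), table_from_mx(mx_m)))
    surv = ProjectionSurvivorship.from_lifetables(years[:-1], tables)

    srb_end = sc.srb if sc.srb_end is None else sc.srb_end
    srb = sc.srb + (srb_end - sc.srb) * frac

    # baseline: stable-population shape from year-0 mortality
    baseline = np.empty((2, N_AGES))
    for s in (0, 1):
        lt = tables[0][s]
        L = np.append(lt.Lx[:95], lt.Tx[95])
        shape = L * np.exp(-sc.stable_growth * np.arange(96))
        birth_share = (1.0 / (1 + sc.srb)) if s == 0 else sc.srb / (1 + sc.srb)
        baseline[s] = shape * birth_share
    baseline *= sc.baseline_total / baseline.sum()

    # migration rate surface -> counts, applied to the evolving population
    age_kernel = np.exp(-0.5 * ((np.arange(96) - sc.mig_age_mode)
                                / sc.mig_age_sd) ** 2)
    amp = np.full(T, sc.mig_rate * jit[2])
    for yr, extra in sc.mig_shocks.items():
        t = int(yr - years[0])
        if 0 <= t < T:
            amp[t] += extra
    if sc.mig_random_sd > 0:
        # smooth seeded AR1 amplitude path: migration waves the observer
        # does not know about (drives out-of-sample error)
        innov_sd = sc.mig_random_sd * np.sqrt(1 - sc.mig_random_rho ** 2)
        z = np.empty(T)
        z[0] = rng.normal(0.0, sc.mig_random_sd)
        for t in range(1, T):
            z[t] = sc.mig_random_rho * z[t - 1] + rng.normal(0.0, innov_sd)
        amp = amp + z
    mig_counts = np.zeros((T, 2, N_AGES))
    data = np.empty((T + 1, 2, N_AGES))
    data[0] = baseline
    for t in range(T):
        G = amp[t] * age_kernel[None, :] * data[t]
        mig_counts[t] = G
        data[t + 1], *_ = ccmpp._step(
            data[t], G, asfr[t], srb[t],
            surv.s_birth[t], surv.s_closed[t], surv.s_open[t])
    mig = MigrationSurface(years=years[:-1], data=mig_counts)

    # regenerate through the public API so flows are recorded
    grid, flows = ccmpp.project(baseline, years, asfr, srb, surv, mig)
    sdi = np.clip(sc.sdi_start + (sc.sdi_end - sc.sdi_start)
                  * np.linspace(0, 1, T + 1), 0.0, 1.0)
    return SyntheticTruth(
        true_pop=grid, true_asfr=asfr, true_mx=mx, true_mig=mig,
        true_srb=srb, sdi=sdi, survivorship=surv, lifetables=tables,
        flows=flows, scenario=sc, seed=seed)


# ------------------------------------------------------------ observation

def default_completeness(ages: np.ndarray, sdi: float) -> np.ndarray:
    """Completeness by age: logistic in SDI, floored at 0.85, with a
    U-shaped age deficit (under-5 and over-65 undercount)."""
    base = 0.85 + 0.17 * expit(6.0 * (sdi - 0.4))
    mult = (1.0 - 0.06 * (ages < 5)
            - 0.05 * expit((ages - 65.0) / 4.0))
    return np.minimum(base * mult, 1.05)


@dataclass
class ObservationConfig:
    """How the truth is observed (and corrupted)."""

    census_years: tuple = ()
    completeness_curve: object = None           # callable (ages, sdi) -> (96,)
    heaping_strength: float = 0.0
    heaping_decade_bias: float = 0.0            # extra pull of 0s over 5s
    age_grouping: str = "five"                  # single | five | ten
    sbh_cohorts: tuple = tuple(range(15, 50, 5))
    vr_bias: dict = field(default_factory=lambda: {"vr": 1.0})
    vr_years: tuple | None = None
    vr_noise_sd: float = 0.0
    cbh_surveys: tuple = ()
    cbh_recall_years: int = 15
    cbh_noise_sd: float = 0.0
    sbh_surveys: tuple = ()
    sbh_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.heaping_strength < 1.0):
            raise ValueError("heaping_strength must be in [0, 1)")
        if self.age_grouping not in {"single", "five", "ten"}:
            raise ValueError("age_grouping must be single, five or ten")


def apply_heaping(counts: np.ndarray, strength: float,
                  decade_bias: float = 0.0) -> np.ndarray:
    """Transfer counts onto terminal-digit-0/5 ages (total preserving).

    Ages one year from a multiple of five lose the fraction ``strength``
    of their count to it; ages two years away lose ``strength / 2``.
    ``decade_bias`` multiplies the pull of multiples of ten by
    (1 + decade_bias), the 0-over-5 preference seen in heavily heaped
    censuses (it is what distorts 5-year group totals).  The open
    interval is untouched.
    """
    x = np.asarray(counts, float).copy()
    if strength == 0:
        return x
    moved = np.zeros_like(x)
    for a in range(1, 95):
        if a % 5 == 0:
            continue
        r = a % 5
        dist = min(r, 5 - r)
        target = a - r if r <= 2 else a + (5 - r)
        if target < 1 or target > 94:
            continue
        frac = strength if dist == 1 else strength / 2.0
        if target % 10 == 0:
            frac = min(frac * (1.0 + decade_bias), 0.95)
        amt = frac * x[a]
        moved[a] -= amt
        moved[target] += amt
    return x + moved


def _group_counts(counts: np.ndarray, grouping: str):
    """Aggregate single-age counts (2, 96) per the grouping scheme."""
    if grouping == "single":
        starts = np.arange(96)
        ends = np.append(np.arange(1, 96), -1)
        return starts, ends, counts.copy()
    if grouping == "five":
        starts = np.arange(0, 96, 5)
        ends = np.append(np.arange(5, 96, 5), -1)
        g = counts[:, :95].reshape(2, 19, 5).sum(axis=2)
        return starts, ends, np.concatenate([g, counts[:, 95:]], axis=1)
    starts = np.arange(0, 91, 10)
    ends = np.append(np.arange(10, 91, 10), -1)
    g = counts[:, :90].reshape(2, 9, 10).sum(axis=2)
    open_grp = counts[:, 90:].sum(axis=1, keepdims=True)
    return starts, ends, np.concatenate([g, open_grp], axis=1)


def observe_census(truth: SyntheticTruth, year: int,
                   obs: ObservationConfig) -> CensusObservation:
    """One corrupted enumeration: undercount, heaping, age grouping."""
    true_counts = truth.true_pop.at(year)
    sdi = float(truth.sdi[truth.true_pop.year_index(year)])
    curve = obs.completeness_curve or default_completeness
    comp = curve(np.arange(N_AGES), sdi)
    counted = true_counts * comp[None, :]
    heaped = np.stack([apply_heaping(counted[s], obs.heaping_strength,
                                     obs.heaping_decade_bias)
                       for s in (0, 1)])
    starts, ends, grouped = _group_counts(heaped, obs.age_grouping)
    return CensusObservation(
        location="synthetic", year=float(year), age_start=starts,
        age_end=ends, counts=grouped, de_facto=True)


def observe_pes(truth: SyntheticTruth, census_years,
                obs: ObservationConfig, noise_sd: float = 0.01
                ) -> list[PESRecord]:
    """Post-enumeration-survey records measuring census completeness."""
    rng = np.random.default_rng(obs.seed + 101)
    curve = obs.completeness_curve or default_completeness
    out = []
    for year in census_years:
        sdi = float(truth.sdi[truth.true_pop.year_index(int(year))])
        comp = curve(np.arange(N_AGES), sdi)
        pop = truth.true_pop.at(int(year)).sum(axis=0)
        overall = float((comp * pop).sum() / pop.sum())
        noisy = overall * float(np.exp(rng.normal(0.0, noise_sd)))
        noisy = float(np.clip(noisy, 0.51, 1.19))
        age_c = {}
        for a in range(0, 95, 5):
            seg = slice(a, min(a + 5, 96))
            age_c[a] = float((comp[seg] * pop[seg]).sum() / pop[seg].sum())
        out.append(PESRecord(location="synthetic", year=int(year),
                             completeness=noisy, sdi=sdi,
                             age_completeness=age_c))
    return out


def observe_fertility_sources(truth: SyntheticTruth,
                              obs: ObservationConfig
                              ) -> list[FertilityObservation]:
    """VR, CBH and SBH observations of the true fertility surface."""
    rng = np.random.default_rng(obs.seed + 202)
    years = truth.years[:-1]
    group_asfr = truth.true_asfr.reshape(-1, 9, 5).mean(axis=2)  # (T, 9)
    out = []

    vr_years = obs.vr_years if obs.vr_years is not None else tuple(years)
    for src, bias in obs.vr_bias.items():
        for yr in vr_years:
            t = int(yr - years[0])
            if not (0 <= t < years.size):
                continue
            for gi, g in enumerate(range(10, 55, 5)):
                val = group_asfr[t, gi] * bias
                noisy = val * float(np.exp(rng.normal(0.0, obs.vr_noise_sd)))
                out.append(FertilityObservation(
                    location="synthetic", year=int(yr), source_type="vr",
                    source_id=src, age_start=g, measure="asfr",
                    value=noisy,
                    variance=(obs.vr_noise_sd * max(noisy, 1e-12)) ** 2))

    for sv in obs.cbh_surveys:
        src = f"cbh_dhs_{sv}"
        for yr in range(sv - obs.cbh_recall_years, sv):
            t = int(yr - years[0])
            if not (0 <= t < years.size):
                continue
            for gi, g in enumerate(range(15, 50, 5)):
                val = group_asfr[t, gi + 1]
                noisy = val * float(np.exp(rng.normal(0.0, obs.cbh_noise_sd)))
                out.append(FertilityObservation(
                    location="synthetic", year=int(yr), source_type="cbh",
                    source_id=src, age_start=g, measure="asfr",
                    value=noisy,
                    variance=(obs.cbh_noise_sd * max(noisy, 1e-12)) ** 2))

    for sv in obs.sbh_surveys:
        src = f"sbh_census_{sv}"
        for cohort in obs.sbh_cohorts:
            ceb = cohort_ceb_from_single(truth.true_asfr, years, cohort,
                                         int(sv))
            noisy = ceb * float(np.exp(rng.normal(0.0, obs.sbh_noise_sd)))
            out.append(FertilityObservation(
                location="synthetic", year=int(sv), source_type="sbh",
                source_id=src, age_start=cohort, measure="ceb",
                value=noisy,
                variance=(obs.sbh_noise_sd * max(noisy, 1e-12)) ** 2))
    return out


# ------------------------------------------------------------ life-table library

def make_lifetable_library(n: int, seed: int = 0):
    """Synthetic library of internally consistent complete/abridged pairs,
    generated from varied Gompertz-Makeham-plus-childhood hazards."""
    if n < 2:
        raise ValueError("library needs n >= 2")
    rng = np.random.default_rng(seed)
    ages = np.arange(111)
    pairs = []
    for _ in range(n):
        # ranges bracket observed human schedules: q(0) ~ 0.01-0.15,
        # m(80) ~ 0.04-0.15
        mx = gompertz_makeham_mx(
            ages,
            child=float(np.exp(rng.normal(np.log(0.05), 0.6))),
            child_decay=float(rng.uniform(0.9, 1.4)),
            background=float(np.exp(rng.normal(np.log(6e-4), 0.5))),
            gomp=float(np.exp(rng.normal(np.log(2e-5), 0.3))),
            gomp_slope=float(rng.uniform(0.085, 0.105)),
        )
        comp = table_from_mx(mx)
        pairs.append((comp, comp.to_abridged()))
    return pairs
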