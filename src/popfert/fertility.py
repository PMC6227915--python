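"""Age-specific fertility estimation.

A two-stage model estimates ASFR for the seven main maternal age groups
15-19 .. 45-49 from heterogeneous sources (vital registration, complete
birth histories).  Stage 1 is a spatiotemporal-GPR-style smoother: a
covariate prior (log ASFR on schooling for 20-24; a natural cubic spline
on the estimated 20-24 ASFR, plus schooling, for the other groups),
source random effects that shift every source to a reference level,
time smoothing of residuals, and a Matern-5/2 Gaussian process.  Stage 2
splits aggregate data — children-ever-born from summary birth histories
and total birth counts — into pseudo-ASFR points using the stage-1
surface, and the model is refitted with the augmented data.

The very low rates at 10-14 and 50-54 use a separate model: a log-ratio
regression on the 15-19 rate, and a constant ratio to the 45-49 rate.
The sex ratio at birth is a GP over time around a time-invariant prior
of 0.512 live-born males per birth.

All rates are per woman-year internally; multiply by 1000 only at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._gp import gp_posterior, gp_draws, tricube_smooth
from .ccmpp import expand_asfr_to_single

ASFR_GROUP_STARTS = np.arange(10, 55, 5)
MAIN_GROUPS = np.arange(15, 50, 5)        # the seven directly modelled groups
PSEUDO_SOURCES = ("sbh_split", "births_split")


@dataclass
class FertilityObservation:
    """One fertility data point: period ASFR, cohort CEB, or total births."""

    location: str
    year: int                        # period year, or survey year for SBH
    source_type: str                 # vr | cbh | sbh | total_births | *_split
    source_id: str
    age_start: int                   # maternal age group start
    measure: str                     # asfr | ceb | births
    value: float
    variance: float = 0.0
    reference: bool = False

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("fertility observation value must be >= 0")


@dataclass
class ASFREstimate:
    """ASFR per woman-year on 5-year maternal age groups by year."""

    years: np.ndarray                # (T,)
    asfr: np.ndarray                 # (9, T) groups 10-14 .. 50-54
    draws: np.ndarray | None = None  # (n, 9, T)
    stage: str = "stage1"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.asfr = np.asarray(self.asfr, dtype=float)
        if self.asfr.shape != (9, self.years.size):
            raise ValueError("asfr must be (9, T)")
        if np.any(self.asfr < 0):
            raise ValueError("negative ASFR")

    def group_row(self, age_start: int) -> np.ndarray:
        return self.asfr[int((age_start - 10) // 5)]

    def at_year(self, year: int) -> np.ndarray:
        idx = int(np.where(self.years == year)[0][0])
        return self.asfr[:, idx]

    def single_age(self) -> np.ndarray:
        """(T, 45) single-age rates (constant within group), ages 10..54."""
        return expand_asfr_to_single(self.asfr.T)


@dataclass
class ExtremeAgeModel:
    """Models for the extreme maternal ages.

    10-14:  ASFR(10-14) = ASFR(15-19) * exp(b0 + b1 * ASFR(15-19))
    50-54:  ASFR(50-54) = r5054 * ASFR(45-49)
    """

    intercept: float
    slope: float
    r5054: float

    def __post_init__(self):
        if self.r5054 <= 0 or not np.isfinite([self.intercept, self.slope,
                                               self.r5054]).all():
            raise ValueError("invalid extreme-age model parameters")


@dataclass
class SRBSeries:
    """Sex ratio at birth (male per female livebirth) by year."""

    years: np.ndarray
    srb: np.ndarray
    draws: np.ndarray | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.srb = np.asarray(self.srb, dtype=float)
        if np.any(self.srb <= 0.8) or np.any(self.srb >= 1.4):
            raise ValueError("SRB outside (0.8, 1.4)")

    def at(self, years) -> np.ndarray:
        idx = np.searchsorted(self.years, np.asarray(years, int))
        return self.srb[np.clip(idx, 0, self.srb.size - 1)]


@dataclass
class StGPRConfig:
    """Smoothing hyperparameters, set by a three-tier data-density rule."""

    dense_threshold: int = 40
    moderate_threshold: int = 15
    bandwidths: tuple = (5.0, 10.0, 20.0)       # dense, moderate, sparse
    lengths: tuple = (5.0, 10.0, 15.0)
    spline_knot: float = 0.1        # ASFR(20-24) where the 30+ upturn kicks in
    amplitude_floor: float = 1e-3
    logvar_floor: float = 1e-8
    n_draws: int = 100
    seed: int = 0

    def tier(self, n_years: int):
        if n_years >= self.dense_threshold:
            return self.bandwidths[0], self.lengths[0]
        if n_years >= self.moderate_threshold:
            return self.bandwidths[1], self.lengths[1]
        return self.bandwidths[2], self.lengths[2]


def resolve_reference(data) -> str:
    """Reference-source cascade: flagged source, else VR, else DHS CBH,
    else any CBH; otherwise an error listing the candidates."""
    flagged = {o.source_id for o in data if o.reference}
    if len(flagged) > 1:
        raise ValueError(f"multiple reference sources flagged: {sorted(flagged)}")
    if flagged:
        return flagged.pop()
    by_type: dict = {}
    for o in data:
        if o.measure == "asfr":
            by_type.setdefault(o.source_type, set()).add(o.source_id)
    if "vr" in by_type:
        return sorted(by_type["vr"])[0]
    cbh = sorted(by_type.get("cbh", set()))
    dhs = [s for s in cbh if "dhs" in s.lower()]
    if dhs:
        return dhs[0]
    if cbh:
        return cbh[0]
    raise ValueError(
        "no reference source resolvable; candidates by type: "
        f"{ {k: sorted(v) for k, v in by_type.items()} }")


def _education_lookup(education, age_start, years):
    """education: DataFrame(year, age_start, value) or None -> array(T,)."""
    if education is None:
        return None
    sub = education[education["age_start"] == age_start]
    if sub.empty:
        return None
    return np.interp(np.asarray(years, float),
                     sub["year"].to_numpy(float), sub["value"].to_numpy(float))


def _ncs_basis(x, knot, lo, hi):
    """Natural cubic spline basis with one interior knot (3 columns)."""
    x = np.asarray(x, float)
    ks = np.array([lo, knot, hi])

    def d(j, xx):
        return ((np.maximum(xx - ks[j], 0) ** 3
                 - np.maximum(xx - ks[2], 0) ** 3) / (ks[2] - ks[j]))

    return np.column_stack([x, d(0, x) - d(1, x)])


def _fit_group(obs, years, prior_log, cfg, ref_source, rng):
    """Shift sources to the reference level, smooth residuals, GP.

    ``obs``: list of (year, value, variance, source_id, is_pseudo).
    Returns (log posterior mean, log posterior cov) over ``years``.
    """
    t = np.array([o[0] for o in obs], float)
    v = np.array([o[1] for o in obs], float)
    keep = v > 0
    t, v = t[keep], v[keep]
    obs = [o for o, k in zip(obs, keep) if k]
    if t.size == 0:
        return prior_log.copy(), None
    y = np.log(v)
    logvar = np.array(
        [max(o[2] / o[1] ** 2, cfg.logvar_floor) for o in obs])
    prior_at = np.interp(t, years, prior_log)
    resid = y - prior_at

    # source random effects: mean residual offset per source, relative to
    # the reference; pseudo (already-split) sources stay at level zero
    offsets = {}
    srcs = np.array([o[3] for o in obs])
    pseudo = np.array([o[4] for o in obs])
    ref_mask = (srcs == ref_source) | pseudo
    ref_level = float(np.mean(resid[ref_mask])) if ref_mask.any() else 0.0
    for s in np.unique(srcs):
        m = srcs == s
        if s == ref_source or pseudo[m].all():
            offsets[s] = 0.0
        else:
            offsets[s] = float(np.mean(resid[m])) - ref_level
    resid_adj = resid - np.array([offsets[s] for s in srcs])

    bw, length = cfg.tier(np.unique(t).size)
    smooth = tricube_smooth(t, resid_adj, years, bw,
                            weights=1.0 / (logvar + 1e-6))
    smooth_at = np.interp(t, years, smooth)
    around = resid_adj - smooth_at
    amplitude = max(1.4826 * float(np.median(np.abs(smooth))),
                    cfg.amplitude_floor)
    nsv = (1.4826 * float(np.median(np.abs(around)))) ** 2
    mean, cov = gp_posterior(
        t, resid_adj, logvar + nsv, years, length, amplitude,
        mean_obs=smooth_at, mean_pred=smooth)
    return prior_log + mean, cov


def fit_stage1(data, years, education=None, super_region="other",
               config: StGPRConfig | None = None, stage: str = "stage1"
               ) -> ASFREstimate:
    """Stage-1 ASFR estimation for the seven main maternal age groups.

    The prior for 20-24 is a log-linear model on mean schooling (a linear
    time trend in the high-income super-region, where schooling is not
    used); other groups use a natural cubic spline on the estimated 20-24
    ASFR plus schooling.  Source random effects shift data to the
    reference source's level before residual smoothing and GP regression.
    """
    cfg = config or StGPRConfig()
    years = np.asarray(years, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    usable = [o for o in data if o.measure == "asfr"
              and o.source_type in ("vr", "cbh") + PSEUDO_SOURCES]
    if not any(o.source_type in ("vr", "cbh") for o in usable):
        raise ValueError("stage 1 needs VR or CBH ASFR data")
    ref = resolve_reference([o for o in usable
                             if o.source_type in ("vr", "cbh")])
    use_edu = education is not None and super_region != "high-income"

    def group_obs(g):
        return [(o.year, o.value, o.variance, o.source_id,
                 o.source_type in PSEUDO_SOURCES)
                for o in usable if o.age_start == g
                and years[0] <= o.year <= years[-1]]

    asfr = np.zeros((9, years.size))
    covs: dict = {}

    # --- 20-24 first: its estimate drives the other groups' priors
    obs20 = [o for o in group_obs(20) if o[1] > 0]
    if not obs20:
        raise ValueError("no usable data for the 20-24 group")
    t20 = np.array([o[0] for o in obs20], float)
    y20 = np.log(np.array([o[1] for o in obs20]))
    edu20 = _education_lookup(education, 20, years) if use_edu else None
    if edu20 is not None:
        x_obs = np.interp(t20, years, edu20)
        x_all = edu20
    else:
        x_obs = (t20 - years.mean()) / max(np.ptp(years), 1.0)
        x_all = (years - years.mean()) / max(np.ptp(years), 1.0)
    srcs20 = [o[3] for o in obs20]
    X = _with_source_dummies(np.column_stack([np.ones_like(x_obs), x_obs]),
                             srcs20, ref)
    beta, *_ = np.linalg.lstsq(X, y20, rcond=None)
    prior20 = np.column_stack([np.ones_like(x_all), x_all]) @ beta[:2]
    mean20, cov20 = _fit_group(obs20, years, prior20, cfg, ref, rng)
    asfr[2] = np.exp(mean20)
    covs[20] = (mean20, cov20)

    # --- other main groups: spline on est 20-24 (+ schooling)
    est20 = asfr[2]
    lo, hi = min(est20.min(), cfg.spline_knot * 0.5), max(est20.max(), 0.4)
    B_all = _ncs_basis(est20, cfg.spline_knot, lo, hi)
    for g in MAIN_GROUPS:
        if g == 20:
            continue
        gi = int((g - 10) // 5)
        obs_g = group_obs(g)
        if not obs_g:
            asfr[gi] = 0.0
            continue
        pos = [o for o in obs_g if o[1] > 0]
        if not pos:
            continue
        y_g = np.log(np.array([o[1] for o in pos]))
        t_g = np.array([o[0] for o in pos], float)
        cols = [np.ones_like(t_g)]
        cols_all = [np.ones(years.size)]
        B_obs = _ncs_basis(np.interp(t_g, years, est20), cfg.spline_knot,
                           lo, hi)
        cols.append(B_obs)
        cols_all.append(B_all)
        edu_g = _education_lookup(education, g, years) if use_edu else None
        if edu_g is not None:
            cols.append(np.interp(t_g, years, edu_g)[:, None])
            cols_all.append(edu_g[:, None])
        Xg = np.column_stack([np.column_stack(cols)])
        n_fixed = Xg.shape[1]
        Xg = _with_source_dummies(Xg, [o[3] for o in pos], ref)
        beta, *_ = np.linalg.lstsq(Xg, y_g, rcond=None)
        prior_g = np.column_stack(cols_all) @ beta[:n_fixed]
        mean_g, cov_g = _fit_group(obs_g, years, prior_g, cfg, ref, rng)
        asfr[gi] = np.exp(mean_g)
        covs[g] = (mean_g, cov_g)

    est = ASFREstimate(years=years, asfr=asfr, stage=stage)
    est.draws = _make_draws(asfr, covs, years, cfg, rng)
    return est


def _with_source_dummies(X, sources, ref):
    srcs = np.asarray(sources)
    extra = [np.where(srcs == s, 1.0, 0.0)
             for s in np.unique(srcs) if s != ref
             and not any(s.startswith(p) for p in PSEUDO_SOURCES)]
    if extra:
        return np.column_stack([X] + extra)
    return X


def _make_draws(asfr, covs, years, cfg, rng):
    n = cfg.n_draws
    draws = np.repeat(asfr[None, :, :], n, axis=0)
    for g, (mean, cov) in covs.items():
        if cov is None:
            continue
        gi = int((g - 10) // 5)
        d = np.exp(gp_draws(mean, cov, n, rng))
        m = d.mean(axis=0)
        scale = np.where(m > 0, asfr[gi] / np.maximum(m, 1e-300), 1.0)
        draws[:, gi, :] = d * scale[None, :]
    return draws


# ---------------------------------------------------------------- stage 2

def cohort_ceb_from_single(asfr_single: np.ndarray, years: np.ndarray,
                           cohort_start: int, survey_year: int) -> float:
    """Children ever born for the 5-year maternal cohort aged
    [cohort_start, cohort_start+5) at the survey date.

    Averages, over the five single-year cohorts, the sum of single-age
    ASFR along each cohort's age-time diagonal up to the survey year,
    truncated to the years covered by the surface.
    """
    years = np.asarray(years, dtype=int)
    total = 0.0
    for a in range(cohort_start, cohort_start + 5):
        for alpha in range(10, min(a, 55)):
            yr = survey_year - (a - alpha)
            if years[0] <= yr <= years[-1]:
                ti = int(yr - years[0])
                total += asfr_single[ti, alpha - 10]
    return total / 5.0


def split_aggregates(data, stage1: ASFREstimate, exposure=None):
    """Split aggregate fertility records into pseudo-ASFR points.

    SBH children-ever-born: the ratio of observed CEB to the stage-1
    implied cohort cumulative fertility scales the stage-1 cohort ASFR at
    every 5-year lag where the cohort occupies a single age group.
    Total-births records are split by the stage-1 age pattern of births
    (needs female ``exposure``: dict age_start -> women, per year).
    """
    single = stage1.single_age()
    out = []
    for o in data:
        if o.source_type == "sbh" and o.measure == "ceb":
            implied = cohort_ceb_from_single(single, stage1.years,
                                             o.age_start, o.year)
            if implied <= 0:
                if o.value > 0:
                    raise ValueError(
                        f"cohort {o.age_start} at {o.year}: observed CEB "
                        f"{o.value} but implied cumulative fertility is 0")
                continue
            ratio = o.value / implied
            rel_var = o.variance / o.value ** 2 if o.value > 0 else 0.0
            for lag in range(0, o.age_start - 10, 5):
                g = o.age_start - lag
                yr = o.year - lag
                if g < 15 or g > 45:
                    continue
                if not (stage1.years[0] <= yr <= stage1.years[-1]):
                    continue
                base = stage1.group_row(g)[int(yr - stage1.years[0])]
                val = ratio * base
                out.append(FertilityObservation(
                    location=o.location, year=yr, source_type="sbh_split",
                    source_id=f"sbh_split:{o.source_id}", age_start=g,
                    measure="asfr", value=val,
                    variance=rel_var * val ** 2))
        elif o.source_type == "total_births" and o.measure == "births":
            if exposure is None:
                raise ValueError("total-births splitting needs exposure")
            yi = int(o.year - stage1.years[0])
            shares_b = np.array([stage1.group_row(g)[yi] * exposure[g]
                                 for g in MAIN_GROUPS])
            implied = shares_b.sum()
            if implied <= 0:
                raise ValueError("implied births are zero")
            ratio = o.value / implied
            rel_var = o.variance / o.value ** 2 if o.value > 0 else 0.0
            for g in MAIN_GROUPS:
                val = ratio * stage1.group_row(g)[yi]
                out.append(FertilityObservation(
                    location=o.location, year=o.year,
                    source_type="births_split",
                    source_id=f"births_split:{o.source_id}", age_start=g,
                    measure="asfr", value=val,
                    variance=rel_var * val ** 2))
    return out


def fit_final(data, years, education=None, super_region="other",
              config: StGPRConfig | None = None, exposure=None
              ) -> ASFREstimate:
    """Stage 2: split aggregates against stage 1, refit with everything."""
    stage1 = fit_stage1(data, years, education=education,
                        super_region=super_region, config=config)
    pseudo = split_aggregates(
        [o for o in data if o.source_type in ("sbh", "total_births")],
        stage1, exposure=exposure)
    if not pseudo:
        return replace(stage1, stage="final")
    est = fit_stage1(list(data) + pseudo, years, education=education,
                     super_region=super_region, config=config, stage="final")
    return est


# ------------------------------------------------------- extreme ages, SRB

def fit_extreme_age_model(data) -> ExtremeAgeModel:
    """Fit the 10-14 log-ratio regression and the 50-54 constant ratio
    from VR observations that cover the extreme age groups."""
    by_year: dict = {}
    for o in data:
        if o.source_type == "vr" and o.measure == "asfr":
            by_year.setdefault(o.year, {})[o.age_start] = o.value
    lo_x, lo_y, hi_r = [], [], []
    for vals in by_year.values():
        if 10 in vals and 15 in vals and vals[10] > 0 and vals[15] > 0:
            lo_x.append(vals[15])
            lo_y.append(np.log(vals[10] / vals[15]))
        if 50 in vals and 45 in vals and vals[45] > 0:
            hi_r.append(vals[50] / vals[45])
    if len(lo_x) < 2 or not hi_r:
        raise ValueError("insufficient VR data for the extreme-age model")
    X = np.column_stack([np.ones(len(lo_x)), lo_x])
    beta, *_ = np.linalg.lstsq(X, np.array(lo_y), rcond=None)
    return ExtremeAgeModel(intercept=float(beta[0]), slope=float(beta[1]),
                           r5054=float(np.mean(hi_r)))


def apply_extreme_ages(est: ASFREstimate, model: ExtremeAgeModel
                       ) -> ASFREstimate:
    """Fill the 10-14 and 50-54 rows from the 15-19 and 45-49 rows."""
    a1519 = est.group_row(15)
    a4549 = est.group_row(45)
    asfr = est.asfr.copy()
    asfr[0] = a1519 * np.exp(model.intercept + model.slope * a1519)
    asfr[8] = model.r5054 * a4549
    draws = None
    if est.draws is not None:
        draws = est.draws.copy()
        d1519 = draws[:, 1, :]
        draws[:, 0, :] = d1519 * np.exp(model.intercept + model.slope * d1519)
        draws[:, 8, :] = model.r5054 * draws[:, 7, :]
    return ASFREstimate(years=est.years, asfr=asfr, draws=draws,
                        stage=est.stage)


def estimate_srb(obs_years, obs_p, obs_var, years,
                 prior_mean: float = 0.512, length: float = 15.0,
                 n_draws: int = 100, seed: int = 0) -> SRBSeries:
    """Sex ratio at birth via a GP on the proportion of live-born males,
    around a time-invariant prior mean of 0.512 (SRB 1.05)."""
    years = np.asarray(years, dtype=int)
    obs_years = np.asarray(obs_years, float)
    obs_p = np.asarray(obs_p, float)
    if obs_p.size and (np.any(obs_p <= 0) or np.any(obs_p >= 1)):
        raise ValueError("proportions male must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if obs_p.size == 0:
        p = np.full(years.size, prior_mean)
        srb = p / (1 - p)
        return SRBSeries(years=years, srb=srb,
                         draws=np.repeat(srb[None, :], n_draws, axis=0))
    resid = obs_p - prior_mean
    amplitude = max(1.4826 * float(np.median(np.abs(resid))), 0.002)
    nv = np.maximum(np.broadcast_to(np.asarray(obs_var, float),
                                    obs_p.shape), 1e-8)
    mean, cov = gp_posterior(obs_years, resid, nv, years, length, amplitude)
    p = np.clip(prior_mean + mean, 0.45, 0.58)
    srb = p / (1 - p)
    d = gp_draws(mean, cov, n_draws, rng)
    p_d = np.clip(prior_mean + d, 0.45, 0.58)
    return SRBSeries(years=years, srb=srb, draws=p_d / (1 - p_d))
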