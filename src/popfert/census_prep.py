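"""Census preparation: completeness adjustment, age-sex quality scores,
and age-heaping corrections.

Census counts are typically undercounts, with the deficit concentrated
in young children and the very old, and ages are preferentially reported
on terminal digits 0 and 5.  This module turns raw counts into adjusted
inputs for the demographic balancing model: a completeness model fitted
to post-enumeration surveys (logit completeness vs SDI, plus a smooth
global age pattern of enumeration), the UN-style age-sex accuracy index
used to decide whether smoothing is needed, and the Feeney (single-year)
and Arriaga / Arriaga-strong (grouped) heaping corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

# completeness is modelled on a scaled-logit link so that modest
# overcounts (up to 1.25 representable, predictions capped at 1.02) fit
_CAP = 1.25
_PRED_CAP = 1.02


@dataclass
class PESRecord:
    """One post-enumeration survey result."""

    location: str
    year: int
    completeness: float                      # net coverage proportion
    sdi: float
    age_completeness: dict | None = None     # age_start -> completeness

    def __post_init__(self):
        if not (0.5 < self.completeness < 1.2):
            raise ValueError("PES completeness outside (0.5, 1.2)")


@dataclass
class CensusObservation:
    """One census enumeration with raw and (optionally) adjusted counts."""

    location: str
    year: float                               # decimal census date allowed
    age_start: np.ndarray                     # (G,) group starts
    age_end: np.ndarray                       # (G,) half-open ends; -1 = open
    counts: np.ndarray                        # (2, G), female then male
    de_facto: bool = True
    outlier: bool = False
    adjusted: np.ndarray | None = None
    completeness: float | None = None
    age_multipliers: np.ndarray | None = None
    correction: str = "none"
    joint_score: float | None = None
    drop_under5: bool = False

    def __post_init__(self):
        self.age_start = np.asarray(self.age_start, dtype=int)
        self.age_end = np.asarray(self.age_end, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, self.age_start.size):
            raise ValueError("counts must be (2, n_groups)")
        if np.any(self.counts < 0):
            raise ValueError("negative census counts")

    @property
    def mid_year(self) -> int:
        """Nearest mid-year for the single-year time grid."""
        return int(np.floor(self.year + 0.5))


@dataclass
class CompletenessModel:
    """Census completeness as a function of SDI, with a global age pattern.

    ``coef`` are the intercept/slope of the scaled-logit regression,
    ``vcov`` their sampling variance-covariance, and ``age_multipliers``
    a positive, mean-1 multiplier per 5-year age-group start.
    """

    coef: np.ndarray                          # (2,)
    vcov: np.ndarray                          # (2, 2)
    age_starts: np.ndarray = field(
        default_factory=lambda: np.arange(0, 96, 5))
    age_multipliers: np.ndarray | None = None

    def __post_init__(self):
        if self.age_multipliers is None:
            self.age_multipliers = np.ones(self.age_starts.size)

    def predict(self, sdi) -> np.ndarray:
        eta = self.coef[0] + self.coef[1] * np.asarray(sdi, dtype=float)
        return np.minimum(_CAP * expit(eta), _PRED_CAP)

    def predict_sd(self, sdi) -> np.ndarray:
        """Delta-method sd of predicted completeness at given SDI."""
        sdi = np.atleast_1d(np.asarray(sdi, dtype=float))
        X = np.column_stack([np.ones_like(sdi), sdi])
        var_eta = np.einsum("ij,jk,ik->i", X, self.vcov, X)
        eta = X @ self.coef
        grad = _CAP * expit(eta) * (1 - expit(eta))
        return grad * np.sqrt(np.maximum(var_eta, 0.0))

    def multiplier_at(self, age_start: int) -> float:
        i = int(np.searchsorted(self.age_starts, age_start, side="right") - 1)
        i = max(0, min(i, self.age_starts.size - 1))
        return float(self.age_multipliers[i])


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated power construction)."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = k.size

    def d(j, xx):
        num = (np.maximum(xx - k[j], 0) ** 3
               - np.maximum(xx - k[-1], 0) ** 3)
        return num / (k[-1] - k[j])

    cols = [np.ones_like(x), x]
    for j in range(K - 2):
        cols.append(d(j, x) - d(K - 2, x))
    return np.column_stack(cols)


def penalized_spline_fit(x, y, weights=None, knots=None, lam=1.0):
    """Inverse-variance-weighted ridge fit on a natural cubic basis.

    Penalty is on the curvature coefficients only; returns a callable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if knots is None:
        knots = np.linspace(x.min(), x.max(), min(6, max(3, x.size // 2)))
    B = _natural_cubic_basis(x, knots)
    P = np.eye(B.shape[1])
    P[0, 0] = P[1, 1] = 0.0           # do not shrink the linear part
    A = B.T @ (w[:, None] * B) + lam * P
    b = B.T @ (w * y)
    beta = np.linalg.solve(A, b)

    def predict(xx):
        return _natural_cubic_basis(np.asarray(xx, float), knots) @ beta

    return predict


def fit_completeness_model(pes: list[PESRecord], spline_lam: float = 1.0
                           ) -> CompletenessModel:
    """Fit logit-scale completeness vs SDI and the global age pattern.

    The age pattern is a penalized-spline meta-regression of age-specific
    completeness ratios (age completeness / overall completeness) across
    all PES that report them, normalized to mean 1.
    """
    if len(pes) < 3:
        raise ValueError("need at least 3 PES records")
    sdi = np.array([p.sdi for p in pes])
    comp = np.array([p.completeness for p in pes])
    if np.ptp(sdi) < 1e-12:
        raise ValueError("all PES records share one SDI; slope unidentifiable")
    y = logit(np.clip(comp / _CAP, 1e-6, 1 - 1e-6))
    X = np.column_stack([np.ones_like(sdi), sdi])
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    dof = max(y.size - 2, 1)
    vcov = XtX_inv * float(resid @ resid / dof)

    age_starts = np.arange(0, 96, 5)
    mult = np.ones(age_starts.size)
    ages_obs, ratio_obs = [], []
    for p in pes:
        if p.age_completeness:
            for a, c in p.age_completeness.items():
                ages_obs.append(a + 2.5)
                ratio_obs.append(c / p.completeness)
    if len(ages_obs) >= 4:
        fitter = penalized_spline_fit(np.array(ages_obs), np.array(ratio_obs),
                                      lam=spline_lam)
        mult = np.maximum(fitter(age_starts + 2.5), 0.05)
    mult = mult / mult.mean()
    return CompletenessModel(coef=coef, vcov=vcov, age_starts=age_starts,
                             age_multipliers=mult)


def adjust_census(census: CensusObservation,
                  model: CompletenessModel,
                  sdi: float,
                  sdi_group: str,
                  own_pes: PESRecord | None = None) -> CensusObservation:
    """Divide raw counts by completeness and the age-pattern multiplier.

    High-SDI locations with their own PES use its nationally reported
    completeness; everyone else uses the model prediction at the census
    SDI.  Low and middle SDI censuses additionally flag under-5 counts
    for exclusion from the balancing likelihood.
    """
    if census.outlier:
        raise ValueError(
            f"census {census.location} {census.year} is flagged as an "
            "outlier and must not be adjusted or used")
    if sdi_group not in {"low", "middle", "high-middle", "high"}:
        raise ValueError(f"unknown sdi_group {sdi_group!r}")
    if sdi_group == "high" and own_pes is not None:
        completeness = own_pes.completeness
    else:
        completeness = float(model.predict(sdi))
    mults = np.array([model.multiplier_at(a) for a in census.age_start])
    adjusted = census.counts / (completeness * mults[None, :])
    return replace(
        census,
        adjusted=adjusted,
        completeness=completeness,
        age_multipliers=mults,
        drop_under5=sdi_group in {"low", "middle"},
    )


def age_sex_joint_score(census: CensusObservation):
    """UN age-sex accuracy index from 5-year-group counts.

    Age ratio AR(g) = 100 * 2 P(g) / (P(g-1) + P(g+1)); the age-ratio
    score is the mean |AR - 100| per sex.  Sex ratio SR(g) = 100 M/F; the
    sex-ratio score is the mean absolute change between adjacent groups.
    Joint score = 3 * sex-ratio score + male + female age-ratio scores.
    """
    counts = census.adjusted if census.adjusted is not None else census.counts
    widths = np.where(census.age_end > 0,
                      census.age_end - census.age_start, -1)
    if census.age_start.size < 5 or not np.all(widths[:-1] == 5):
        raise ValueError("joint score needs >= 5 five-year groups")
    f, m = counts[0], counts[1]
    if np.any(f == 0) or np.any(m == 0):
        raise ValueError("zero count; ratios undefined")
    age_scores = []
    for P in (m, f):                      # male first per convention
        ar = 100.0 * 2.0 * P[1:-1] / (P[:-2] + P[2:])
        age_scores.append(float(np.mean(np.abs(ar - 100.0))))
    sr = 100.0 * m / f
    sex_score = float(np.mean(np.abs(np.diff(sr))))
    joint = 3.0 * sex_score + age_scores[0] + age_scores[1]
    return {
        "age_ratio_score_male": age_scores[0],
        "age_ratio_score_female": age_scores[1],
        "sex_ratio_score": sex_score,
        "joint_score": joint,
    }


def whipple_index(counts: np.ndarray, ages: np.ndarray | None = None) -> float:
    """Whipple index of digit preference on ages 23-62 (100 = no heaping)."""
    counts = np.asarray(counts, dtype=float)
    if ages is None:
        ages = np.arange(counts.size)
    mask = (ages >= 23) & (ages <= 62)
    heap = (ages % 5 == 0) & mask
    denom = counts[mask].sum()
    if denom == 0:
        raise ValueError("empty age range for Whipple index")
    return float(100.0 * 5.0 * counts[heap].sum() / denom)


def _feeney(counts: np.ndarray, tol: float = 1e-8, max_iter: int = 2000,
            damping: float = 0.5) -> np.ndarray:
    """Iterative redistribution of terminal-digit excess (single-year ages).

    Each multiple of 5 is compared with the cubic (4-point Lagrange)
    interpolant of its four surrounding ages; the excess is moved back
    onto those ages with double weight on the immediate neighbours (the
    inverse of the classic transfer pattern), damped for stability, until
    the maximum relative change per sweep falls below ``tol``.  The total
    within each 5-age block — and hence overall — is conserved exactly,
    which pins the equilibrium at the undisturbed level; smooth schedules
    are fixed points to interpolation accuracy.
    """
    x = np.asarray(counts, dtype=float).copy()
    n = x.size
    w = np.array([0.5, 1.0, 1.0, 0.5])     # offsets -2,-1,+1,+2
    w = w / w.sum()
    lagrange = np.array([-1.0, 4.0, 4.0, -1.0]) / 6.0
    offs = np.array([-2, -1, 1, 2])
    for _ in range(max_iter):
        max_rel = 0.0
        for d in range(5, n - 2, 5):
            idx = d + offs
            if idx[0] < 0 or idx[-1] >= n:
                continue
            target = float(lagrange @ x[idx])
            excess = x[d] - target
            move = damping * excess
            before = x[d]
            x[d] -= move
            x[idx] += move * w
            max_rel = max(max_rel, abs(move) / max(before, 1e-300))
        if max_rel < tol:
            break
    return x


def _arriaga_split(g10: np.ndarray) -> np.ndarray:
    """Split 10-year totals into 5-year groups with the Arriaga weights.

    Interior first half: (-G(older) + 11 G(this) + 2 G(younger)) / 24.
    Endpoints use a linearly extrapolated phantom neighbour group.
    """
    n = g10.size
    padded = np.empty(n + 2)
    padded[1:-1] = g10
    padded[0] = 2 * g10[0] - g10[1]        # phantom younger group
    padded[-1] = 2 * g10[-1] - g10[-2]     # phantom older group
    out = np.empty(2 * n)
    for i in range(n):
        younger, this, older = padded[i], padded[i + 1], padded[i + 2]
        first = (-older + 11.0 * this + 2.0 * younger) / 24.0
        out[2 * i] = first
        out[2 * i + 1] = this - first
    return out


def correct_heaping(counts: np.ndarray, method: str,
                    age_start: np.ndarray | None = None) -> np.ndarray:
    """Heaping correction for one sex's counts.

    ``feeney`` needs single-year ages; ``arriaga``/``arriaga_strong`` need
    5-year groups spanning at least 30 years of age.  Arriaga preserves
    10-year totals; arriaga_strong first smooths the 10-year totals with
    a (1,2,1)/4 moving average (overall total preserved).
    """
    counts = np.asarray(counts, dtype=float)
    if method == "feeney":
        if age_start is not None and np.any(np.diff(age_start) != 1):
            raise ValueError("feeney requires single-year ages")
        out = _feeney(counts)
        return np.maximum(out, 0.0)
    if method not in {"arriaga", "arriaga_strong"}:
        raise ValueError(f"unknown method {method!r}")
    if age_start is None:
        age_start = np.arange(counts.size) * 5
    age_start = np.asarray(age_start, dtype=int)
    if np.any(np.diff(age_start) != 5):
        raise ValueError(f"{method} requires 5-year groups")
    if age_start[-1] + 5 - age_start[0] < 30:
        raise ValueError(f"{method} requires >= 30 years of age span")
    n5 = counts.size
    n_pairs = n5 // 2
    head = counts[: 2 * n_pairs]
    tail = counts[2 * n_pairs:]            # odd leftover group untouched
    g10 = head.reshape(n_pairs, 2).sum(axis=1)
    if method == "arriaga_strong":
        sm = g10.copy()
        if n_pairs >= 3:
            sm[1:-1] = (g10[:-2] + 2 * g10[1:-1] + g10[2:]) / 4.0
            sm *= g10.sum() / sm.sum()     # preserve the overall total
        g10 = sm
    split = _arriaga_split(g10)
    out = np.concatenate([split, tail])
    if np.any(out < 0):
        # floor at zero, redistributing the deficit proportionally
        total = out.sum()
        out = np.maximum(out, 0.0)
        out *= total / out.sum()
    return out


def select_correction(census: CensusObservation,
                      whipple_threshold: float = 105.0,
                      joint_arriaga: float = 20.0,
                      joint_strong: float = 40.0) -> str:
    """Pick a heaping correction from data quality scores.

    Single-year counts get Feeney when the Whipple index exceeds the
    threshold; grouped counts get Arriaga (joint score in [20, 40)) or
    Arriaga strong (>= 40), else no correction.
    """
    widths = census.age_end - census.age_start
    single = bool(np.all(widths[:-1] == 1))
    if single:
        w = whipple_index(census.counts.sum(axis=0),
                          ages=census.age_start)
        return "feeney" if w > whipple_threshold else "none"
    score = age_sex_joint_score(census)["joint_score"]
    if score >= joint_strong:
        return "arriaga_strong"
    if score >= joint_arriaga:
        return "arriaga"
    return "none"
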