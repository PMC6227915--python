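"""Life-table graduation: abridged tables to single-year ages 0-110.

An abridged period life table uses the standard grouped ages <1, 1-4,
then 5-year groups to 110+.  Projection needs single-year survivorship,
so abridged tables are expanded: ages 15-99 by monotone piecewise-cubic
interpolation of group-boundary ``lx`` values, ages 0-14 and 100+ from a
log-log regression of single-year on parent-group death probabilities
fitted on a library of complete/abridged table pairs, with the predicted
values rescaled so that within every abridged group

    1 - prod(1 - 1qx)  ==  5qx        (exactly)

``1ax`` is 0.5 at every single age except <1 and the terminal group,
which copy the abridged values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

# Abridged group start ages: <1, 1-4, 5-year groups to 110+
ABRIDGED_STARTS = np.array([0, 1] + list(range(5, 111, 5)))
N_ABRIDGED = ABRIDGED_STARTS.size          # 24
COMPLETE_AGES = np.arange(111)             # single ages 0..110
TERMINAL_AGE = 110


def abridged_group_of_age(age: int) -> int:
    """Index of the abridged group containing a single age."""
    return int(np.searchsorted(ABRIDGED_STARTS, age, side="right") - 1)


def _group_widths() -> np.ndarray:
    w = np.diff(np.append(ABRIDGED_STARTS, TERMINAL_AGE + 1)).astype(float)
    return w


@dataclass
class AbridgedLifeTable:
    """Grouped period life table on the standard abridged ages.

    qx is the probability of dying within the group given survival to its
    start; the terminal group has qx = 1.  lx (survivors, l0 = 1), nmx and
    nLx are derived.  ``nax`` is person-years lived by in-group decedents.
    """

    qx: np.ndarray                       # (24,)
    nax: np.ndarray | None = None        # (24,); default n/2 (0.3 for <1)
    shock_mx: np.ndarray | None = None   # optional fatal-discontinuity rate

    def __post_init__(self):
        self.qx = np.asarray(self.qx, dtype=float)
        if self.qx.shape != (N_ABRIDGED,):
            raise ValueError(f"qx must have {N_ABRIDGED} groups")
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            raise ValueError("qx outside [0, 1]")
        if self.qx[-1] != 1.0:
            raise ValueError("terminal group qx must equal 1")
        w = _group_widths()
        if self.nax is None:
            nax = w / 2.0
            nax[0] = 0.3
            nax[-1] = 5.0          # e(110), overridden when known
            self.nax = nax
        else:
            self.nax = np.asarray(self.nax, dtype=float)
        self.lx = np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])[:-1]
        if np.any(np.diff(self.lx) > 0):
            raise ValueError("lx must be nonincreasing")
        dx = self.lx * self.qx
        nLx = np.empty(N_ABRIDGED)
        nLx[:-1] = w[:-1] * self.lx[1:] + self.nax[:-1] * dx[:-1]
        nLx[-1] = self.nax[-1] * self.lx[-1]
        self.nLx = nLx
        with np.errstate(divide="ignore", invalid="ignore"):
            self.nmx = np.where(nLx > 0, dx / nLx, 0.0)


@dataclass
class CompleteLifeTable:
    """Single-year period life table on ages 0..110."""

    qx: np.ndarray                       # (111,)
    ax: np.ndarray                       # (111,)

    def __post_init__(self):
        self.qx = np.asarray(self.qx, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        if self.qx.shape != (111,) or self.ax.shape != (111,):
            raise ValueError("complete table needs 111 single ages")
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            raise ValueError("qx outside [0, 1]")
        if self.qx[-1] != 1.0:
            raise ValueError("terminal qx must equal 1")
        self.lx = np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])[:-1]
        dx = self.lx * self.qx
        Lx = np.empty(111)
        Lx[:-1] = self.lx[1:] + self.ax[:-1] * dx[:-1]
        Lx[-1] = self.ax[-1] * self.lx[-1]
        self.Lx = Lx
        self.Tx = np.cumsum(Lx[::-1])[::-1]

    @classmethod
    def from_qx(cls, qx, a0: float = 0.3, a_term: float = 5.0) -> "CompleteLifeTable":
        ax = np.full(111, 0.5)
        ax[0] = a0
        ax[-1] = a_term
        return cls(qx=np.asarray(qx, dtype=float), ax=ax)

    def to_abridged(self) -> AbridgedLifeTable:
        """Exact grouping: 5qx from the ratio of boundary survivorship."""
        lx_b = np.append(self.lx, self.lx[-1] * (1 - self.qx[-1]))  # l(111)=0
        starts = np.append(ABRIDGED_STARTS, TERMINAL_AGE + 1)
        l_at = self.lx[ABRIDGED_STARTS]
        q = np.empty(N_ABRIDGED)
        nax = np.empty(N_ABRIDGED)
        w = _group_widths()
        for g in range(N_ABRIDGED):
            lo, hi = starts[g], starts[g + 1]
            l_next = lx_b[hi] if hi <= 110 else 0.0
            q[g] = 1.0 - (l_next / l_at[g] if l_at[g] > 0 else 0.0)
            dx_g = l_at[g] - l_next
            if dx_g > 0:
                # person-years of decedents within the group, from single ages
                Ls = self.Lx[lo:hi].sum()
                nax[g] = (Ls - w[g] * l_next) / dx_g
            else:
                nax[g] = w[g] / 2.0
        q[-1] = 1.0
        nax[-1] = (self.Tx[TERMINAL_AGE] / self.lx[TERMINAL_AGE]
                   if self.lx[TERMINAL_AGE] > 0 else w[-1] / 2.0)
        return AbridgedLifeTable(qx=q, nax=nax)


@dataclass
class QxRegressionCoeffs:
    """Per-age OLS fits of log(1qx) on log(parent-group 5qx).

    Fitted at single ages 0..14 and 100..109; the terminal age 110 always
    has qx = 1 and carries no coefficients.
    """

    ages: np.ndarray
    beta0: np.ndarray
    beta1: np.ndarray
    resid_sd: np.ndarray

    def predict(self, age: int, group_qx: float) -> float:
        i = int(np.where(self.ages == age)[0][0])
        return float(np.exp(self.beta0[i] + self.beta1[i] * np.log(group_qx)))


REGRESSION_AGES = np.concatenate([np.arange(0, 15), np.arange(100, 110)])


def fit_qx_regression(library) -> QxRegressionCoeffs:
    """OLS of log single-year qx on log parent-group qx, one fit per age.

    ``library`` is a list of (CompleteLifeTable, AbridgedLifeTable) pairs.
    """
    if len(library) < 2:
        raise ValueError("need at least 2 library pairs")
    b0 = np.empty(REGRESSION_AGES.size)
    b1 = np.empty(REGRESSION_AGES.size)
    sd = np.empty(REGRESSION_AGES.size)
    for i, age in enumerate(REGRESSION_AGES):
        g = abridged_group_of_age(int(age))
        y, x = [], []
        for comp, abr in library:
            if comp.qx[age] > 0 and abr.qx[g] > 0:
                y.append(np.log(comp.qx[age]))
                x.append(np.log(abr.qx[g]))
        y = np.asarray(y)
        x = np.asarray(x)
        if y.size < 2 or np.ptp(x) < 1e-12:
            raise ValueError(f"degenerate regressor at single age {age}")
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        b0[i], b1[i] = coef
        dof = max(y.size - 2, 1)
        sd[i] = float(np.sqrt(resid @ resid / dof))
    return QxRegressionCoeffs(ages=REGRESSION_AGES.copy(), beta0=b0, beta1=b1,
                              resid_sd=sd)


def _scale_group_qx(qx_pred: np.ndarray, target_q: float) -> np.ndarray:
    """Scale predicted single-year qx so 1 - prod(1-q) equals target exactly."""
    if target_q <= 0:
        return np.zeros_like(qx_pred)
    if target_q >= 1.0 - 1e-12:
        # extinct group: keep the predicted age pattern, close it with q=1
        top = np.max(qx_pred)
        q = np.minimum(qx_pred / top, 1.0) if top > 0 else np.ones_like(qx_pred)
        q[-1] = 1.0
        return q
    if np.all(qx_pred <= 0):
        # no age pattern available: constant hazard split
        n = qx_pred.size
        return np.full(n, 1.0 - (1.0 - target_q) ** (1.0 / n))

    def f(k):
        return np.prod(1.0 - k * qx_pred) - (1.0 - target_q)

    hi = (1.0 - 1e-12) / np.max(qx_pred)
    if f(hi) > 0:         # even maximal scaling can't reach target
        raise ValueError("qx out of [0, 1] after scaling")
    k = brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-15)
    return k * qx_pred


def expand_lifetable(abridged: AbridgedLifeTable,
                     coeffs: QxRegressionCoeffs) -> CompleteLifeTable:
    """Expand an abridged table to single ages 0..110.

    Ages 15-99 come from monotone cubic interpolation of the abridged lx
    at group boundaries (no rescaling needed: boundary values are
    interpolated exactly, so group consistency is automatic).  Ages 0-14
    and 100-109 come from the regression coefficients, rescaled within
    each abridged group to match its 5qx exactly.  Age 110 has qx = 1.
    """
    if np.any(np.diff(abridged.lx) > 0):
        raise ValueError("abridged lx must be nonincreasing")
    qx = np.zeros(111)

    # interpolation span: knots at all group boundaries with lx > 0
    knots = ABRIDGED_STARTS.astype(float)
    lvals = abridged.lx.copy()
    pos = lvals > 0
    # keep the contiguous positive prefix; pad one zero knot to anchor decline
    last = int(np.max(np.nonzero(pos))) if pos.any() else 0
    kn, lv = knots[: last + 1], lvals[: last + 1]
    # interpolate on the log-survivorship (cumulative-hazard) scale:
    # monotonicity is preserved and the relative accuracy of the implied
    # qx is far better where lx spans orders of magnitude
    interp = PchipInterpolator(kn, np.log(lv), extrapolate=False)

    def l_of(age: float) -> float:
        if age >= kn[-1]:
            return 0.0
        return float(np.exp(interp(age)))

    l_single = np.array([l_of(a) for a in range(15, 101)])  # ages 15..100
    for a in range(15, 100):
        la, lb = l_single[a - 15], l_single[a - 14]
        qx[a] = 1.0 - (lb / la) if la > 0 else 1.0

    # regression ages, rescaled group by group
    for lo, hi in [(0, 0), (1, 4), (5, 9), (10, 14), (100, 104), (105, 109)]:
        g = abridged_group_of_age(lo)
        tq = abridged.qx[g]
        ages = np.arange(lo, hi + 1)
        pred = np.array([
            coeffs.predict(int(a), tq) if tq > 0 else 0.0 for a in ages
        ])
        qx[lo:hi + 1] = _scale_group_qx(pred, tq)
    qx[110] = 1.0

    ax = np.full(111, 0.5)
    ax[0] = abridged.nax[0]
    ax[110] = abridged.nax[-1]
    table = CompleteLifeTable(qx=qx, ax=ax)
    if np.any(np.diff(table.lx) > 1e-12):
        raise ValueError("expanded lx not nonincreasing")
    return table


def add_shock_rates(complete: CompleteLifeTable, shock_mx) -> CompleteLifeTable:
    """Add group-constant fatal-discontinuity death rates to a complete table.

    qx is converted to mx with the table's ax, the abridged-group shock rate
    is added to every member single age, and the result converted back.
    Probabilities exceeding 1 are capped with a warning.
    """
    shock_mx = np.asarray(shock_mx, dtype=float)
    if shock_mx.shape != (N_ABRIDGED,):
        raise ValueError("shock_mx must be per abridged group")
    if np.any(shock_mx < 0):
        raise ValueError("shock_mx must be nonnegative")
    if np.all(shock_mx == 0):
        return CompleteLifeTable(qx=complete.qx.copy(), ax=complete.ax.copy())
    q, a = complete.qx, complete.ax
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(q < 1, q / (1.0 - (1.0 - a) * q), np.inf)
    groups = np.array([abridged_group_of_age(x) for x in COMPLETE_AGES])
    m_new = m + shock_mx[groups]
    with np.errstate(invalid="ignore"):
        q_new = np.where(np.isinf(m_new), 1.0,
                         m_new / (1.0 + (1.0 - a) * m_new))
    if np.any(q_new > 1.0):
        warnings.warn("shocked qx capped at 1")
        q_new = np.minimum(q_new, 1.0)
    q_new[110] = 1.0
    return CompleteLifeTable(qx=q_new, ax=a.copy())


@dataclass
class SurvivorshipRatios:
    """Single-year projection survivorship derived from Lx ratios.

    s_birth  : L0 / l0, survival of a birth cohort to the first mid-year
    s_closed : S(a) = L(a+1)/L(a) for ages a = 0..93
    s_open   : T(95)/T(94), applied to the pooled ages 94 and 95+
    """

    s_birth: float
    s_closed: np.ndarray      # (94,)
    s_open: float


def survivorship_ratios(complete: CompleteLifeTable) -> SurvivorshipRatios:
    L, T = complete.Lx, complete.Tx
    if np.any(L[:96] <= 0):
        raise ValueError("zero Lx below the open interval")
    s_closed = L[1:95] / L[0:94]
    s_birth = float(L[0] / complete.lx[0])
    if np.all(complete.qx[95:110] == 0):
        # deathless open interval: the forced q(110)=1 is a table-closure
        # artifact, not mortality; survivorship is exactly 1
        s_open = 1.0
    else:
        s_open = float(T[95] / T[94])
    for name, val in [("s_birth", s_birth), ("s_open", s_open)]:
        if not (0 < val <= 1):
            raise ValueError(f"{name} outside (0, 1]")
    return SurvivorshipRatios(s_birth=s_birth, s_closed=s_closed, s_open=s_open)
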