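"""Summary demographic indicators: TFR, TFU25, TFO30, NRR, livebirths,
growth rates, age-structure measures, and the Socio-demographic Index.

Fertility summaries operate on per-woman ASFR for the nine 5-year
maternal age groups 10-14 .. 50-54 (published tables print rates per
1000; divide by 1000 before use).  TFR = 5 * sum of group rates;
TFU25 covers ages 10-24, TFO30 covers ages 30-54, and the decomposition
TFU25 + (25-29 term) + TFO30 = TFR is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import PopulationGrid
from .lifetables import CompleteLifeTable

GROUP_STARTS = np.arange(10, 55, 5)


@dataclass
class FertilitySummary:
    tfr: float
    tfu25: float
    tfo30: float
    livebirths: float | None = None


def fertility_summaries(asfr: np.ndarray, women=None) -> FertilitySummary:
    """Summary fertility from per-woman group ASFRs (9 groups).

    ``women`` (optional, per group) enables the livebirth count
    Sum(ASFR * women).
    """
    asfr = np.asarray(asfr, float)
    if asfr.shape != (9,):
        raise ValueError("expected 9 age-group ASFRs (10-14 .. 50-54)")
    if np.any(np.isnan(asfr)):
        missing = GROUP_STARTS[np.isnan(asfr)]
        raise ValueError(f"missing ASFR for group(s) starting {missing}")
    tfr = 5.0 * float(asfr.sum())
    tfu25 = 5.0 * float(asfr[:3].sum())
    tfo30 = 5.0 * float(asfr[4:].sum())
    births = None
    if women is not None:
        women = np.asarray(women, float)
        births = float(asfr @ women)
    return FertilitySummary(tfr=tfr, tfu25=tfu25, tfo30=tfo30,
                            livebirths=births)


def aggregate_asfr(asfr: np.ndarray, span: tuple, women=None) -> float:
    """ASFR over an arbitrary age span: births over woman-years.

    Equal group weights when no population is given (so e.g. the 10-19
    rate is the mean of the 10-14 and 15-19 rates).
    """
    asfr = np.asarray(asfr, float)
    lo, hi = span
    sel = (GROUP_STARTS >= lo) & (GROUP_STARTS < hi)
    if not sel.any():
        raise ValueError(f"span {span} covers no age group")
    if women is None:
        return float(asfr[sel].mean())
    women = np.asarray(women, float)
    return float((asfr[sel] @ women[sel]) / women[sel].sum())


def nrr(asfr: np.ndarray, srb: float, female_lt: CompleteLifeTable) -> float:
    """Net reproductive rate: expected female livebirths per woman under
    period fertility, mortality and sex ratio at birth.

    NRR = Sum_g 5 * ASFR(g) * (1 / (1 + SRB)) * (5Lx_female(g) / (5 l0)).
    """
    asfr = np.asarray(asfr, float)
    out = 0.0
    for g, a in zip(GROUP_STARTS, asfr):
        L5 = float(female_lt.Lx[g:g + 5].sum())
        out += 5.0 * a * (1.0 / (1.0 + srb)) * (L5 / (5.0 * female_lt.lx[0]))
    return out


def nrr_single_age(asfr_single: np.ndarray, srb: float,
                   female_lt: CompleteLifeTable) -> float:
    """Single-age NRR (ages 10..54), for cross-checking the grouped form."""
    asfr_single = np.asarray(asfr_single, float)
    ages = np.arange(10, 55)
    surv = female_lt.Lx[ages] / female_lt.lx[0]
    return float((asfr_single * surv).sum() / (1.0 + srb))


@dataclass
class PopulationSummary:
    growth_rate: float               # per year, logarithmic
    percent_change: float
    working_age_share: float         # ages 15-64, at the end year
    mean_age: float
    proportion_female: float


def growth_rate(n1: float, n2: float, dt: float) -> float:
    """Annualized logarithmic growth rate between two totals."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    return float(np.log(n2 / n1) / dt)


def percent_change(n1: float, n2: float) -> float:
    if n1 <= 0:
        raise ValueError("initial total must be positive")
    return float(100.0 * (n2 / n1 - 1.0))


def population_summaries(pop: PopulationGrid, t1: int, t2: int,
                         life_table: CompleteLifeTable | None = None
                         ) -> PopulationSummary:
    """Growth between t1 and t2; structure measures at t2.

    The open interval contributes at age 95 + e(95) to the mean age when
    a life table is supplied, else at age 100.
    """
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    n1, n2 = pop.total(t1), pop.total(t2)
    end = pop.at(t2)
    total = end.sum()
    if total <= 0:
        raise ValueError("zero population")
    by_age = end.sum(axis=0)
    working = float(by_age[15:65].sum() / total)
    midpoints = np.arange(96) + 0.5
    if life_table is not None:
        e95 = float(life_table.Tx[95] / life_table.lx[95])
        midpoints = midpoints.copy()
        midpoints[95] = 95 + e95
    else:
        midpoints = midpoints.copy()
        midpoints[95] = 100.0
    mean_age = float((by_age @ midpoints) / total)
    return PopulationSummary(
        growth_rate=growth_rate(n1, n2, t2 - t1),
        percent_change=percent_change(n1, n2),
        working_age_share=working,
        mean_age=mean_age,
        proportion_female=float(end[0].sum() / total),
    )


@dataclass
class SDIAnchors:
    """Component min/max used to rescale to [0, 1].

    TFU25 is inverted (high fertility -> low development).  LDI is used
    on the log scale.
    """

    tfu25: tuple = (0.0, 3.0)
    log_ldi: tuple = (5.5, 11.5)
    education: tuple = (0.0, 17.0)


@dataclass
class SDIValue:
    sdi: float
    fertility_component: float
    income_component: float
    education_component: float


def sdi(tfu25: float, ldi: float, education: float,
        anchors: SDIAnchors | None = None) -> SDIValue:
    """Socio-demographic Index: geometric mean of the rescaled TFU25
    (inverted), log lag-distributed income, and mean education 15+."""
    anchors = anchors or SDIAnchors()

    def rescale(x, lo, hi, invert=False):
        if hi <= lo:
            raise ValueError("anchor min must be below max")
        v = (x - lo) / (hi - lo)
        v = float(np.clip(v, 0.0, 1.0))
        return 1.0 - v if invert else v

    f = rescale(tfu25, *anchors.tfu25, invert=True)
    i = rescale(np.log(ldi), *anchors.log_ldi)
    e = rescale(education, *anchors.education)
    return SDIValue(sdi=float((f * i * e) ** (1.0 / 3.0)),
                    fertility_component=f, income_component=i,
                    education_component=e)
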