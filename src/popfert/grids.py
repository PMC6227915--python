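"""Core demographic containers: population grids, vital flows, migration surfaces.

Populations live on single-year ages 0..94 plus an open interval 95+,
two sexes (female first), and mid-year time points.  Flows (births,
deaths, net migrants) are attached to the year-long intervals between
adjacent time points, so that the demographic balancing identity

    N(t+1) = N(t) + B - D + G

can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("female", "male")
N_AGES = 96          # single ages 0..94 plus open interval 95+
OPEN_AGE = 95        # start of the open age interval
AGES = np.arange(N_AGES)


def _as_year_array(years) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    if years.ndim != 1 or years.size < 1:
        raise ValueError("years must be a non-empty 1-D array")
    if years.size > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("years must be consecutive calendar years")
    return years


@dataclass
class PopulationGrid:
    """Persons N(a, s, t) at single ages 0..95+ by sex and mid-year."""

    years: np.ndarray                 # (T,)
    data: np.ndarray                  # (T, 2, 96): year x sex x age

    def __post_init__(self):
        self.years = _as_year_array(self.years)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.years.size, 2, N_AGES):
            raise ValueError(
                f"data shape {self.data.shape} != ({self.years.size}, 2, {N_AGES})"
            )

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(f"year {year} not in grid ({self.years[0]}..{self.years[-1]})")
        return idx

    def at(self, year: int) -> np.ndarray:
        """Counts at one year, shape (2, 96)."""
        return self.data[self.year_index(year)]

    def total(self, year=None) -> np.ndarray | float:
        if year is None:
            return self.data.sum(axis=(1, 2))
        return float(self.at(year).sum())

    def to_frame(self, location: str = "synthetic") -> pd.DataFrame:
        t, s, a = np.meshgrid(self.years, np.arange(2), AGES, indexing="ij")
        return pd.DataFrame(
            {
                "location": location,
                "year": t.ravel(),
                "sex": np.asarray(SEXES)[s.ravel()],
                "age": a.ravel(),
                "value": self.data.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationGrid":
        years = np.sort(df["year"].unique())
        data = np.zeros((years.size, 2, N_AGES))
        sex_idx = {s: i for i, s in enumerate(SEXES)}
        yr_idx = {int(y): i for i, y in enumerate(years)}
        for row in df.itertuples(index=False):
            data[yr_idx[int(row.year)], sex_idx[row.sex], int(row.age)] = row.value
        return cls(years=years, data=data)


@dataclass
class VitalFlows:
    """Births, deaths and net migrants per interval [t, t+1)."""

    years: np.ndarray                 # (T-1,) interval start years
    births: np.ndarray                # (T-1, 2) by sex of child
    deaths: np.ndarray                # (T-1, 2, 96)
    migrants: np.ndarray              # (T-1, 2, 96), signed

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.births = np.asarray(self.births, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.migrants = np.asarray(self.migrants, dtype=float)
        n = self.years.size
        if self.births.shape != (n, 2):
            raise ValueError("births shape mismatch")
        if self.deaths.shape != (n, 2, N_AGES) or self.migrants.shape != (n, 2, N_AGES):
            raise ValueError("deaths/migrants shape mismatch")


@dataclass
class MigrationSurface:
    """Net migration G(a, s, t) per interval, as counts or per-capita rates.

    ``hyperparams`` records the AR1(age) x AR1(time) prior that produced a
    fitted surface (sigma_mig, rho_age, rho_time); empty for truth surfaces.
    """

    years: np.ndarray                 # (T,) interval start years
    data: np.ndarray                  # (T, 2, 96)
    is_rate: bool = False
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.years.size, 2, N_AGES):
            raise ValueError("migration data shape mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("migration surface contains non-finite values")
        if self.is_rate and np.any(np.abs(self.data) >= 0.5):
            raise ValueError("per-capita migration rates must lie in (-0.5, 0.5)")

    @classmethod
    def zeros(cls, years) -> "MigrationSurface":
        years = np.asarray(years, dtype=int)
        return cls(years=years, data=np.zeros((years.size, 2, N_AGES)))
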