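"""Tidy CSV schemas.

Ages are integers; age intervals are half-open [age_start, age_end);
an open-ended interval is coded age_end = -1.  Rates are written per
woman (multiply by 1000 for the conventional per-1000 presentation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import SEXES, PopulationGrid, MigrationSurface
from .census_prep import CensusObservation
from .fertility import FertilityObservation
from .lifetables import AbridgedLifeTable, ABRIDGED_STARTS, TERMINAL_AGE


def write_population(grid: PopulationGrid, path, location="synthetic"):
    grid.to_frame(location).to_csv(path, index=False)


def read_population(path) -> PopulationGrid:
    return PopulationGrid.from_frame(pd.read_csv(path))


def write_census(censuses: list[CensusObservation], path):
    rows = []
    for c in censuses:
        for s, sex in enumerate(SEXES):
            for g in range(c.age_start.size):
                rows.append({
                    "location": c.location, "year": c.year, "sex": sex,
                    "age_start": int(c.age_start[g]),
                    "age_end": int(c.age_end[g]),
                    "value": c.counts[s, g],
                    "defacto": int(c.de_facto), "outlier": int(c.outlier),
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_census(path) -> list[CensusObservation]:
    df = pd.read_csv(path)
    out = []
    for (loc, year), grp in df.groupby(["location", "year"], sort=True):
        piv = grp.pivot_table(index=["age_start", "age_end"], columns="sex",
                              values="value").reset_index()
        piv = piv.sort_values("age_start")
        out.append(CensusObservation(
            location=str(loc), year=float(year),
            age_start=piv["age_start"].to_numpy(int),
            age_end=piv["age_end"].to_numpy(int),
            counts=np.stack([piv["female"].to_numpy(float),
                             piv["male"].to_numpy(float)]),
            de_facto=bool(grp["defacto"].iloc[0]),
            outlier=bool(grp["outlier"].iloc[0]),
        ))
    return out


def write_fertility(obs: list[FertilityObservation], path):
    pd.DataFrame([{
        "location": o.location, "year": o.year,
        "source_type": o.source_type, "source_id": o.source_id,
        "age_start": o.age_start, "age_end": o.age_start + 5,
        "measure": o.measure, "value": o.value, "variance": o.variance,
        "reference": int(o.reference),
    } for o in obs]).to_csv(path, index=False)


def read_fertility(path) -> list[FertilityObservation]:
    df = pd.read_csv(path)
    return [FertilityObservation(
        location=r.location, year=int(r.year), source_type=r.source_type,
        source_id=r.source_id, age_start=int(r.age_start),
        measure=r.measure, value=float(r.value),
        variance=float(r.variance), reference=bool(r.reference),
    ) for r in df.itertuples(index=False)]


def write_lifetable(tables: dict, path, location="synthetic"):
    """``tables``: {(year, sex): AbridgedLifeTable}."""
    rows = []
    ends = np.append(ABRIDGED_STARTS[1:], -1)
    for (year, sex), lt in tables.items():
        for g in range(ABRIDGED_STARTS.size):
            rows.append({
                "location": location, "year": year, "sex": sex,
                "age_start": int(ABRIDGED_STARTS[g]), "age_end": int(ends[g]),
                "qx": lt.qx[g], "lx": lt.lx[g], "ax": lt.nax[g],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lifetable(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for (year, sex), grp in df.groupby(["year", "sex"], sort=True):
        grp = grp.sort_values("age_start")
        out[(int(year), str(sex))] = AbridgedLifeTable(
            qx=grp["qx"].to_numpy(float), nax=grp["ax"].to_numpy(float))
    return out


def write_migration(mig: MigrationSurface, path, location="synthetic"):
    t, s, a = np.meshgrid(mig.years, np.arange(2), np.arange(96),
                          indexing="ij")
    pd.DataFrame({
        "location": location, "year": t.ravel(),
        "sex": np.asarray(SEXES)[s.ravel()], "age": a.ravel(),
        "net_migrants": mig.data.ravel(),
    }).to_csv(path, index=False)
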