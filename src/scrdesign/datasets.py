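"""Published reference tables for the seven Alberta boreal caribou ranges.

These are the printed survey tallies and SCR density estimates from the
winter fecal-DNA aerial surveys of seven boreal caribou (Rangifer
tarandus caribou) population ranges in Alberta, Canada.  They serve two
roles: worked-example inputs for the tally arithmetic, and reference
(D, g0, sigma) truths for simulation studies at realistic parameter
values.  The raw capture data behind them is archived separately and is
not required by this package.
"""

from __future__ import annotations

import pandas as pd

from .tallies import GenotypingTally

__all__ = ["survey_tallies", "density_estimates", "reference_truth"]

_TALLY_ROWS = [
    # population, year, area_km2, distance_flown_km, collected, scored,
    # unique genotypes, spatial recaptures
    ("Cold Lake",    "2014",      7277, 7497,   844,  781, 261, 148),
    ("ESAR",         "2013",     13160, 13121, 1382, 1254, 401, 188),
    ("Little Smoky", "2014-2015", 3084, 3048,   855,  835, 108,  36),
    ("Nipisi",       "2018",      2104, 2119,   417,  415,  67,  72),
    ("Red Earth",    "2017",     24737, 25377, 1819, 1777, 386, 530),
    ("Slave Lake",   "2018",      1516, 1501,   206,  190,  42,  38),
    ("WSAR",         "2015",     15726, 16407, 1687, 1613, 490, 314),
]

_DENSITY_ROWS = [
    # population, D (per 1,000 km^2), D CI, SE(D), CV(D), g0, sigma_m, N, N CI
    ("Cold Lake",    61.9, (46.3, 82.9), 6.69, 0.15, 0.015, 3363.2, 353, (276, 452)),
    ("ESAR",         50.6, (42.9, 59.6), 4.24, 0.08, 0.024, 1778.8, 647, (549, 763)),
    ("Little Smoky", 31.1, (22.8, 42.5), 4.99, 0.16, 0.028, 1603.0,  94, (69, 129)),
    ("Nipisi",       30.7, (22.8, 41.4), 4.70, 0.15, 0.053, 1941.6,  63, (47, 85)),
    ("Red Earth",    16.1, (14.4, 17.9), 0.87, 0.05, 0.022, 3124.8, 387, (347, 430)),
    ("Slave Lake",   25.9, (17.2, 39.1), 5.51, 0.21, 0.247, 1226.0,  38, (25, 58)),
    ("WSAR",         43.0, (38.5, 48.1), 2.43, 0.06, 0.013, 2868.9, 659, (590, 737)),
]


def survey_tallies() -> list[GenotypingTally]:
    """Per-population genotyping tallies from the seven range surveys."""
    return [GenotypingTally(r[0], r[4], r[5], r[6], r[7]) for r in _TALLY_ROWS]


def survey_table() -> pd.DataFrame:
    """The full sampling table including range areas and distance flown."""
    return pd.DataFrame(_TALLY_ROWS, columns=[
        "population", "survey_year", "area_km2", "distance_flown_km",
        "samples_collected", "samples_scored", "unique_genotypes",
        "spatial_recaptures"])


def density_estimates() -> pd.DataFrame:
    """Published per-range SCR density estimates (D per 1,000 km^2)."""
    rows = [{
        "population": p, "D": d, "D_lo": ci[0], "D_hi": ci[1], "SE_D": se,
        "CV_D": cv, "g0": g0, "sigma_m": sg, "N": n, "N_lo": nci[0],
        "N_hi": nci[1],
    } for p, d, ci, se, cv, g0, sg, n, nci in _DENSITY_ROWS]
    return pd.DataFrame(rows)


def reference_truth(population: str) -> dict:
    """(D, g0, sigma, area) for one range, for use as simulation truth."""
    dens = density_estimates().set_index("population")
    surv = survey_table().set_index("population")
    if population not in dens.index:
        raise KeyError(f"unknown population {population!r}; "
                       f"choose from {list(dens.index)}")
    r = dens.loc[population]
    return {"D": float(r.D), "g0": float(r.g0), "sigma": float(r.sigma_m),
            "area_km2": float(surv.loc[population, "area_km2"])}
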