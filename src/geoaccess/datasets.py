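"""Published summary tables from the Ibadan NHIS accessibility survey.

These are the printed aggregate tables of a field study of National
Health Insurance Scheme (NHIS) enrollees and health facilities across the
11 local government areas (LGAs) of Ibadan, Nigeria: the administrative
breakdown of populations, facilities and enrollees; the per-facility
bypassing counts of the 431 interviewed patrons; and the per-facility
shortest/longest distances travelled.  They serve as worked-example inputs
for the reporting operations — the raw point coordinates of the study were
never deposited, so point-level analyses run on synthetic data instead
(:mod:`geoaccess.synthetic`).

Known quirks of the printed tables, reproduced as-is: the bypass table
totals 431 patrons against a designed sample of 420, and the published
nearest-neighbour summary prints an Rn and z-score that are not mutually
consistent with its own Do and De under the standard formulas.  This
module reports the tables' own arithmetic and does not reconcile them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STUDY_AREA_M2",
    "N_FACILITIES",
    "OBSERVED_MEAN_NN_M",
    "lga_table",
    "bypass_counts",
    "distance_rows",
]

#: Declared study area of the 11-LGA Ibadan metropolis (m²).
STUDY_AREA_M2 = 3_198_130_000.0

#: Health facilities mapped in the point-pattern analysis.
N_FACILITIES = 531

#: Printed observed mean nearest-neighbour distance (m) of those facilities.
OBSERVED_MEAN_NN_M = 670.6474

_LGA_ROWS = [
    # name, stratum, population, primary, secondary, tertiary, nhis, enrollees
    ("Ibadan North", "urban", 856_988, 24, 63, 1, 38, 42_429),
    ("Ibadan Northeast", "urban", 330_399, 13, 36, 0, 31, 12_792),
    ("Ibadan Northwest", "urban", 152_834, 9, 27, 0, 22, 23_593),
    ("Ibadan Southeast", "urban", 266_457, 15, 14, 0, 7, 769),
    ("Ibadan Southwest", "urban", 283_098, 23, 79, 0, 65, 23_730),
    ("Akinyele", "semiurban", 211_359, 36, 10, 0, 3, 204),
    ("Egbeda", "semiurban", 319_388, 34, 42, 0, 9, 6_857),
    ("Ido", "semiurban", 117_129, 18, 27, 0, 11, 1_188),
    ("Lagelu", "semiurban", 147_957, 19, 10, 0, 6, 559),
    ("Oluyole", "semiurban", 734_377, 26, 12, 0, 0, 0),
    ("Ona-Ara", "semiurban", 118_465, 29, 24, 0, 0, 0),
]

_BYPASS_ROWS = [
    # facility, bypassed, non-bypassing
    ("Teju", 59, 1),
    ("St. Mary", 59, 0),
    ("St. Marello", 29, 0),
    ("St. Dominic", 30, 7),
    ("Cottage Police Clinic", 39, 2),
    ("Lafia", 63, 0),
    ("LAD", 39, 9),
    ("Jericho", 14, 0),
    ("Immaculate", 50, 0),
    ("Doctor's Polyclinic", 10, 5),
    ("Chrisbo", 13, 2),
]

_DISTANCE_ROWS = [
    # facility, shortest km, longest km
    ("Chrisbo", 1.095, 2.732),
    ("Doctors Polyclinic", 1.021, 3.731),
    ("Immaculate", 1.141, 7.617),
    ("Jericho", 0.763, 3.805),
    ("Lad", 0.513, 6.062),
    ("Lafia", 1.157, 7.329),
    ("Police Cottage", 0.833, 5.709),
    ("St. Marello Catholic", 1.932, 8.595),
    ("St. Mary Catholic", 1.752, 7.234),
    ("St. Dominic", 0.978, 6.156),
    ("Teju", 0.866, 6.089),
]


def lga_table() -> pd.DataFrame:
    """Per-LGA populations, facility counts by care level, NHIS accreditation
    and enrollee counts for the 5 urban and 6 semiurban LGAs."""
    return pd.DataFrame(
        _LGA_ROWS,
        columns=[
            "name",
            "stratum",
            "population",
            "facilities_primary",
            "facilities_secondary",
            "facilities_tertiary",
            "nhis_facilities",
            "enrollees",
        ],
    )


def bypass_counts() -> pd.DataFrame:
    """Bypassed / non-bypassing patron counts at each surveyed facility."""
    return pd.DataFrame(_BYPASS_ROWS, columns=["facility_id", "n_bypassed", "n_non_bypassed"])


def distance_rows() -> pd.DataFrame:
    """Shortest and longest distance travelled (km) per surveyed facility."""
    return pd.DataFrame(_DISTANCE_ROWS, columns=["facility_id", "shortest_km", "longest_km"])
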