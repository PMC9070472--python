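"""Coverage statistics across administrative strata and the Kish sample size.

Coverage works on a per-LGA summary table (one row per local government
area with its stratum, projected population, facility counts by care
level, NHIS-accredited facility count and enrollee count) and derives the
percentages an access report prints: each stratum's share of the gross
population, insurance coverage (enrollees / population) within stratum,
each stratum's share of all enrollees, and the accredited share of each
LGA's facilities.  All percentages are recomputed from the raw sums at
report time and printed at 1 dp, half-up.
"""

from __future__ import annotations

import math

import pandas as pd

from .types import (
    CoverageReport,
    KishInput,
    StratumTotals,
    ValidationError,
    round_half_up,
)

__all__ = ["coverage_stats", "kish_sample_size"]


def _stratum_totals(df: pd.DataFrame) -> StratumTotals:
    fac = (
        df["facilities_primary"] + df["facilities_secondary"] + df["facilities_tertiary"]
    ).sum()
    return StratumTotals(
        population=int(df["population"].sum()),
        facilities=int(fac),
        nhis_facilities=int(df["nhis_facilities"].sum()),
        enrollees=int(df["enrollees"].sum()),
    )


def coverage_stats(lga_table: pd.DataFrame) -> CoverageReport:
    """Derive stratum totals and coverage percentages from a per-LGA table.

    Requires at least one urban and one semiurban record.  The per-LGA
    accreditation share is the accredited fraction of ALL facilities in the
    LGA (primary facilities, which cannot be accredited, stay in the
    denominator — the convention of the published summary tables).
    """
    strata = lga_table["stratum"].astype(str).str.lower()
    urban_df = lga_table[strata == "urban"]
    semi_df = lga_table[strata == "semiurban"]
    if len(urban_df) == 0 or len(semi_df) == 0:
        raise ValidationError("coverage_stats needs at least one urban and one semiurban LGA")
    urban = _stratum_totals(urban_df)
    semi = _stratum_totals(semi_df)
    gross_pop = urban.population + semi.population
    if gross_pop <= 0:
        raise ValidationError("gross population is zero; shares are undefined")
    total_enr = urban.enrollees + semi.enrollees
    shares = {}
    for _, r in lga_table.iterrows():
        fac = int(
            r["facilities_primary"] + r["facilities_secondary"] + r["facilities_tertiary"]
        )
        shares[str(r["name"])] = (
            round_half_up(100.0 * int(r["nhis_facilities"]) / fac, 1) if fac else 0.0
        )
    pct = lambda num, den: round_half_up(100.0 * num / den, 1) if den else 0.0
    return CoverageReport(
        urban=urban,
        semiurban=semi,
        urban_pop_share=pct(urban.population, gross_pop),
        semiurban_pop_share=pct(semi.population, gross_pop),
        urban_nhis_coverage=pct(urban.enrollees, urban.population),
        semiurban_nhis_coverage=pct(semi.enrollees, semi.population),
        urban_enrollee_share=pct(urban.enrollees, total_enr),
        semiurban_enrollee_share=pct(semi.enrollees, total_enr),
        lga_accreditation_share=shares,
    )


def kish_sample_size(inp: KishInput | None = None, **kwargs) -> int:
    """Kish minimum sample size n = ceil(z² · p · (1−p) / d²).

    ``p`` is the anticipated proportion, ``d`` the absolute precision and
    ``z`` the standard-normal quantile (1.96 for 95% confidence).  The
    ceiling is the conservative convention: a fractional respondent always
    rounds up.

    >>> kish_sample_size(p=0.5, d=0.05)
    385
    """
    if inp is None:
        inp = KishInput(**kwargs)
    raw = inp.z * inp.z * inp.p * (1.0 - inp.p) / (inp.d * inp.d)
    return int(math.ceil(raw))
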