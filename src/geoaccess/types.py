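"""Domain types and coordinate conventions shared by every analysis stage.

All coordinates are planar metres in a projected coordinate system (the
analyses are meaningless on raw longitude/latitude); every distance the
package computes is Euclidean in that plane.  Report-facing distances are
kilometres rounded to three decimals; percentages are printed at one
decimal, half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely import intersects_xy

__all__ = [
    "SchemaError",
    "ValidationError",
    "CARE_LEVELS",
    "FACILITY_COLUMNS",
    "ENROLLEE_COLUMNS",
    "LGA_COLUMNS",
    "StudyArea",
    "NNAResult",
    "GiParams",
    "KishInput",
    "StratumTotals",
    "CoverageReport",
    "round_half_up",
]


class SchemaError(ValueError):
    """A table is missing a required column or property."""


class ValidationError(ValueError):
    """A record violates a stated invariant (duplicate id, bad coordinate...)."""


CARE_LEVELS = ("primary", "secondary", "tertiary")

FACILITY_COLUMNS = ["id", "name", "level", "nhis_accredited", "lga", "x", "y"]
ENROLLEE_COLUMNS = ["id", "x", "y", "used_facility_id"]
LGA_COLUMNS = [
    "name",
    "stratum",
    "population",
    "facilities_primary",
    "facilities_secondary",
    "facilities_tertiary",
    "nhis_facilities",
    "enrollees",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed report tables).

    Python's built-in round() is banker's rounding; report tables here use
    the half-up convention (98.35 -> 98.4 at 1 dp).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StudyArea:
    """The region the point pattern lives in.

    The area in m² is always required: the Clark–Evans expectation
    0.5*sqrt(A/n) is undefined without a declared A, and silently inferring
    an enclosing rectangle would make results irreproducible.  A polygon is
    optional but needed for grid aggregation and for simulation; when both
    are given their areas must agree to 0.1%.
    """

    area: float
    polygon: Optional[Polygon] = None

    def __post_init__(self) -> None:
        if not (self.area > 0 and math.isfinite(self.area)):
            raise ValidationError(f"study area must be a positive finite m² value, got {self.area}")
        if self.polygon is not None:
            pa = abs(self.polygon.area)
            if abs(pa - self.area) > 1e-3 * self.area:
                raise ValidationError(
                    f"polygon area {pa:.6g} m² disagrees with declared area "
                    f"{self.area:.6g} m² by more than 0.1%"
                )

    @classmethod
    def from_polygon(cls, polygon: Polygon | Sequence) -> "StudyArea":
        if not isinstance(polygon, Polygon):
            polygon = Polygon(polygon)
        return cls(area=abs(polygon.area), polygon=polygon)

    @classmethod
    def square(cls, area: float, origin: tuple[float, float] = (0.0, 0.0)) -> "StudyArea":
        """A square region of the given area anchored at ``origin``."""
        s = math.sqrt(area)
        x0, y0 = origin
        ring = [(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s)]
        return cls(area=area, polygon=Polygon(ring))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        if self.polygon is None:
            raise ValidationError("study area has no polygon; bounds are undefined")
        return self.polygon.bounds

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-region test (boundary counts as inside)."""
        if self.polygon is None:
            return np.ones(np.shape(x), dtype=bool)
        return intersects_xy(self.polygon, np.asarray(x), np.asarray(y))


@dataclass(frozen=True)
class NNAResult:
    """Every quantity of a Clark–Evans average nearest-neighbour analysis.

    Attributes
    ----------
    n : number of points
    area : declared study area A in m²
    observed_mean_distance : Do, mean distance to the nearest other point (m)
    expected_mean_distance : De = 0.5*sqrt(A/n), the CSR expectation (m)
    standard_error : SE = 0.26136 / sqrt(n²/A) (m)
    rn : Clark–Evans ratio Do/De; <1 clustered, ≈1 random, >1 dispersed
    z_score : (Do − De)/SE; negative under clustering
    p_value : two-sided standard-normal tail probability of z
    pattern : "clustered", "random" or "dispersed" at the chosen alpha
    """

    n: int
    area: float
    observed_mean_distance: float
    expected_mean_distance: float
    standard_error: float
    rn: float
    z_score: float
    p_value: float
    pattern: str
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "area_m2": self.area,
            "observed_mean_distance_m": self.observed_mean_distance,
            "expected_mean_distance_m": self.expected_mean_distance,
            "standard_error_m": self.standard_error,
            "rn": self.rn,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "pattern": self.pattern,
            "alpha": self.alpha,
        }


@dataclass(frozen=True)
class GiParams:
    """Grid and neighbourhood scale of a Gi* hotspot analysis.

    cell_size is the square fishnet cell edge in metres; band is the
    fixed-distance neighbourhood radius applied to cell centers (a cell is
    always its own neighbour — the star form).  Confidence bins use the
    0.10/0.05/0.01 thresholds on FDR-adjusted p-values.
    """

    cell_size: float
    band: float
    alpha_bins: tuple[float, float, float] = (0.10, 0.05, 0.01)

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.band < self.cell_size:
            raise ValidationError(
                f"band ({self.band}) must be at least the cell size ({self.cell_size})"
            )


@dataclass(frozen=True)
class KishInput:
    """Inputs of the Kish minimum-sample-size formula n = z²·p·(1−p)/d²."""

    p: float
    d: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValidationError(f"anticipated proportion p must be in (0, 1), got {self.p}")
        if not self.d > 0:
            raise ValidationError(f"absolute precision d must be > 0, got {self.d}")
        if not self.z > 0:
            raise ValidationError(f"normal quantile z must be > 0, got {self.z}")


@dataclass(frozen=True)
class StratumTotals:
    population: int
    facilities: int
    nhis_facilities: int
    enrollees: int


@dataclass(frozen=True)
class CoverageReport:
    """Stratum totals and the derived coverage percentages (1 dp, half-up).

    Shares within a partition (urban+semiurban population shares, enrollee
    shares) sum to 100 up to rounding; coverage is enrollees/population
    within the stratum; the per-LGA accreditation share is the accredited
    fraction of all facilities in that LGA.
    """

    urban: StratumTotals
    semiurban: StratumTotals
    urban_pop_share: float
    semiurban_pop_share: float
    urban_nhis_coverage: float
    semiurban_nhis_coverage: float
    urban_enrollee_share: float
    semiurban_enrollee_share: float
    lga_accreditation_share: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "urban": vars(self.urban).copy(),
            "semiurban": vars(self.semiurban).copy(),
            "urban_pop_share_pct": self.urban_pop_share,
            "semiurban_pop_share_pct": self.semiurban_pop_share,
            "urban_nhis_coverage_pct": self.urban_nhis_coverage,
            "semiurban_nhis_coverage_pct": self.semiurban_nhis_coverage,
            "urban_enrollee_share_pct": self.urban_enrollee_share,
            "semiurban_enrollee_share_pct": self.semiurban_enrollee_share,
            "lga_accreditation_share_pct": dict(self.lga_accreditation_share),
        }
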