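"""Synthetic facility networks and enrollee populations.

Generates data with the statistical structure the downstream analyses
assume: facility point patterns that are clustered (Thomas process),
random (CSR) or regular (square lattice) over a large planar study region;
enrollee residences uniform in the region; a distance-decay facility
choice; and a landmark-proxy measurement error that displaces each
recorded residence 300–500 m from the true one.

Defaults mirror the study conditions the package is designed around: a
~3.2×10⁹ m² metropolitan region, 531 facilities, 431 interviewed
enrollees.  The choice model favours nearby facilities (probability
∝ attractiveness·exp(−d/λ)) but, with hundreds of candidates and a
kilometre-scale λ, rarely picks the single nearest one — which is exactly
the mechanism that produces high apparent bypass rates.

Randomness: a single seed spawns independent child streams for facilities
and enrollees (in that fixed order), so changing the number of enrollees
never perturbs facility coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import StudyArea, ValidationError

__all__ = ["SyntheticConfig", "gen_facilities", "gen_enrollees", "simulate"]

#: Default study region: a square with the area of the 11-LGA Ibadan
#: metropolis used throughout the worked examples (m²).
DEFAULT_AREA_M2 = 3.19813e9

# care-level mix and accreditation odds loosely matching an urban Nigerian
# facility census: mostly primary/secondary, a rare tertiary; only
# secondary/tertiary facilities can be NHIS-accredited.
_LEVEL_PROBS = {"primary": 0.42, "secondary": 0.575, "tertiary": 0.005}
_ACCREDIT_PROB = 0.56


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    decay_lambda is the e-folding scale (metres) of the facility-choice
    distance decay; jitter_min/jitter_max bound the landmark-proxy
    displacement radius (metres).
    """

    seed: int = 0
    area: StudyArea = field(default_factory=lambda: StudyArea.square(DEFAULT_AREA_M2))
    n_facilities: int = 531
    pattern: str = "thomas"
    thomas_parents: int = 25
    thomas_sd: float = 2000.0
    n_enrollees: int = 431
    decay_lambda: float = 5000.0
    attractiveness: Optional[Sequence[float]] = None
    jitter_min: float = 300.0
    jitter_max: float = 500.0
    n_lga: int = 11

    def __post_init__(self) -> None:
        if self.pattern not in ("csr", "thomas", "grid"):
            raise ValidationError(f"pattern must be csr|thomas|grid, got {self.pattern!r}")
        if self.n_facilities < 1 or self.n_enrollees < 1 or self.thomas_parents < 1:
            raise ValidationError("all counts must be positive")
        if not self.decay_lambda > 0:
            raise ValidationError(f"decay_lambda must be > 0, got {self.decay_lambda}")
        if self.jitter_min < 0 or self.jitter_min > self.jitter_max:
            raise ValidationError(
                f"need 0 <= jitter_min <= jitter_max, got [{self.jitter_min}, {self.jitter_max}]"
            )
        if self.attractiveness is not None and len(self.attractiveness) != self.n_facilities:
            raise ValidationError(
                "attractiveness must have one positive weight per facility"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        area = d.pop("area", None)
        cfg = cls(**d) if area is None else cls(area=StudyArea.square(float(area)), **d)
        return cfg


def _child_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    fac_ss, enr_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(fac_ss), np.random.default_rng(enr_ss)


def _uniform_in_area(rng: np.random.Generator, area: StudyArea, n: int) -> np.ndarray:
    """Exact uniform sampling inside the study polygon by rejection from its bbox."""
    x0, y0, x1, y1 = area.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 64)
        cand = np.column_stack(
            [rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)]
        )
        keep = area.contains(cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _thomas_points(
    rng: np.random.Generator, area: StudyArea, n: int, n_parents: int, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Thomas cluster process conditioned on exactly n offspring in the area.

    Parents are uniform in the region; offspring pick a parent uniformly at
    random and scatter with an isotropic Gaussian of the given sd, with
    rejection (not reflection) at the region boundary so within-cluster
    uniformity of direction is preserved.
    """
    parents = _uniform_in_area(rng, area, n_parents)
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(2 * (n - len(pts)), 64)
        pidx = rng.integers(0, n_parents, m)
        cand = parents[pidx] + rng.normal(0.0, sd, size=(m, 2))
        keep = area.contains(cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n], parents


def _grid_points(area: StudyArea, n: int) -> np.ndarray:
    """Square lattice with spacing s = sqrt(area/n), centred in the bounding
    box and including boundary sites, row-major truncated to exactly n."""
    s = math.sqrt(area.area / n)
    x0, y0, x1, y1 = area.bounds
    kx = int(math.floor((x1 - x0) / s + 1e-9)) + 1
    ky = int(math.floor((y1 - y0) / s + 1e-9)) + 1
    mx = ((x1 - x0) - s * (kx - 1)) / 2.0
    my = ((y1 - y0) - s * (ky - 1)) / 2.0
    xs = x0 + mx + s * np.arange(kx)
    ys = y0 + my + s * np.arange(ky)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    keep = area.contains(pts[:, 0], pts[:, 1])
    pts = pts[keep]
    if len(pts) < n:
        raise ValidationError(
            f"grid pattern cannot place {n} points at spacing {s:.3g} inside the area "
            f"(only {len(pts)} lattice sites fall inside)"
        )
    return pts[:n]


def _lga_labels(area: StudyArea, pts: np.ndarray, n_lga: int) -> list[str]:
    # vertical strips of equal width stand in for administrative areas
    x0, _, x1, _ = area.bounds
    strip = np.clip(((pts[:, 0] - x0) / (x1 - x0) * n_lga).astype(int), 0, n_lga - 1)
    return [f"LGA{i + 1:02d}" for i in strip]


def gen_facilities(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a facility table with the configured spatial pattern.

    Deterministic given the seed.  For the thomas pattern the parent
    coordinates are attached as ``df.attrs["thomas_parents"]`` so tests can
    locate planted clusters.
    """
    rng, _ = _child_rngs(config.seed)
    parents = None
    if config.pattern == "csr":
        pts = _uniform_in_area(rng, config.area, config.n_facilities)
    elif config.pattern == "thomas":
        pts, parents = _thomas_points(
            rng, config.area, config.n_facilities, config.thomas_parents, config.thomas_sd
        )
    else:
        pts = _grid_points(config.area, config.n_facilities)
    n = config.n_facilities
    levels = rng.choice(
        list(_LEVEL_PROBS), size=n, p=list(_LEVEL_PROBS.values())
    )
    accredited = np.where(
        levels == "primary", False, rng.random(n) < _ACCREDIT_PROB
    )
    # a facility set with zero accredited members is useless downstream;
    # force at least one (the first non-primary, else relabel the first).
    if not accredited.any():
        idx = int(np.argmax(levels != "primary")) if (levels != "primary").any() else 0
        levels[idx] = "secondary"
        accredited[idx] = True
    df = pd.DataFrame(
        {
            "id": [f"F{i + 1:04d}" for i in range(n)],
            "name": [f"Facility {i + 1}" for i in range(n)],
            "level": levels,
            "nhis_accredited": accredited.astype(bool),
            "lga": _lga_labels(config.area, pts, config.n_lga),
            "x": pts[:, 0],
            "y": pts[:, 1],
        }
    )
    if parents is not None:
        df.attrs["thomas_parents"] = parents
    return df


def gen_enrollees(config: SyntheticConfig, facilities: pd.DataFrame) -> pd.DataFrame:
    """Generate enrollees with distance-decay facility choice and proxy jitter.

    True residences are uniform in the region.  Each enrollee uses facility
    j with probability ∝ attractiveness_j · exp(−d_j / decay_lambda), where
    d_j is the Euclidean distance from the TRUE residence.  The recorded
    (x, y) is the true residence displaced by a uniform angle and a radius
    uniform on [jitter_min, jitter_max] — the landmark-proxy error.  The
    true coordinates are kept in diagnostic columns ``true_x``/``true_y``
    (writers emit only the standard schema).
    """
    if facilities is None or len(facilities) == 0:
        raise ValidationError("gen_enrollees needs a non-empty facility table")
    _, rng = _child_rngs(config.seed)
    n = config.n_enrollees
    w = (
        np.ones(len(facilities))
        if config.attractiveness is None
        else np.asarray(config.attractiveness, dtype=float)
    )
    if (w <= 0).any():
        raise ValidationError("attractiveness weights must all be positive")
    # insured enrollees can only use accredited providers, so the choice
    # set is the accredited subset (all facilities if none are flagged)
    if "nhis_accredited" in facilities.columns:
        mask = facilities["nhis_accredited"].astype(bool).to_numpy()
        if mask.any():
            facilities = facilities[mask]
            w = w[mask]
    fxy = facilities[["x", "y"]].to_numpy(dtype=float)
    true = _uniform_in_area(rng, config.area, n)
    # log-space scores keep exp(-d/λ) stable for tiny λ
    d = np.sqrt(((true[:, None, :] - fxy[None, :, :]) ** 2).sum(axis=2))
    logp = np.log(w)[None, :] - d / config.decay_lambda
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    choice = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    choice = np.minimum(choice, len(facilities) - 1)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    radius = rng.uniform(config.jitter_min, config.jitter_max, n)
    rec = true + np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    fac_ids = facilities["id"].astype(str).to_numpy()
    return pd.DataFrame(
        {
            "id": [f"E{i + 1:04d}" for i in range(n)],
            "x": rec[:, 0],
            "y": rec[:, 1],
            "used_facility_id": fac_ids[choice],
            "true_x": true[:, 0],
            "true_y": true[:, 1],
        }
    )


def simulate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a matched (facilities, enrollees) pair from one config."""
    facilities = gen_facilities(config)
    enrollees = gen_enrollees(config, facilities)
    return facilities, enrollees
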