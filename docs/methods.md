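# Methods

This note documents the statistical procedures geoaccess implements, the
modelling choices behind the synthetic-data generator, and the numerical
conventions that make runs reproducible. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All analyses operate on planar coordinates in metres (a projected system
such as a UTM zone); nothing in the package computes on raw
longitude/latitude, and no projection helper is provided — projecting is
the user's responsibility upstream. Internal distances are metres;
report-facing distances are kilometres at 3 decimals and percentages are
printed at 1 decimal, both rounded half-up (ties away from zero), the
convention of the printed tables the reporting operations emulate.

## Clark–Evans nearest-neighbour analysis

For n points on a region of declared area A, with D̄o the mean distance
from each point to its nearest other point:

    D̄e = 0.5 * sqrt(A / n)
    SE  = 0.26136 / sqrt(n² / A)
    Rn  = D̄o / D̄e
    z   = (D̄o − D̄e) / SE,   p = two-sided standard-normal tail

Pattern labels at level α (default 0.05): clustered iff Rn < 1 and
p < α; dispersed iff Rn > 1 and p < α; otherwise random. The z sign
convention makes clustering negative (D̄o < D̄e). The 0.26136 constant is
the Clark & Evans (1954) standard-error coefficient.

Choices worth knowing:

- **The area is always an explicit input.** Rn is meaningless without a
  declared A, and silently substituting an enclosing rectangle (as some
  GIS defaults do) makes results irreproducible. Pass a scalar area or a
  polygon.
- **No edge correction.** The plain statistic is used, matching the form
  implemented in common desktop GIS tools; a Donnelly-corrected variant
  is deliberately out of scope. On a bounded window the plain estimator
  of D̄o carries a positive bias of order 0.41/√n in Rn (boundary points
  have artificially distant neighbours). Consequence: on CSR data in a
  square at n ≈ 500 the expected Rn is ≈ 1.02, not 1.00.
- **Calibration harness on a torus.** `csr_calibration` simulates the
  null with a periodic (toroidal) metric, which realises the edge-free
  setting the Clark–Evans expectation assumes. This isolates what the
  harness is meant to check — the adequacy of the normal approximation
  and the test's nominal size — from the window-edge bias above, which
  is a property of bounded observation windows, not of the
  approximation. The toroidal metric is exposed as the `box` argument
  and is never applied to observed field data.
- The theoretical maximum of Rn is ≈ 2.149 (triangular lattice); a
  square lattice attains exactly 2 when the declared area is n·s².

## Gi* hotspot mapping

Points are counted into a square fishnet anchored at the bounding box's
minimum corner, with half-open cells [x0+i·s, x0+(i+1)·s) so a point on
a shared edge belongs to the higher-index cell. Cells whose centers fall
outside the study polygon are dropped; interior zero-count cells are
kept — cold spots are made of them. Note the centre-in-polygon drop rule
means a boundary sliver cell (possible when the cell size does not tile
the window) can be dropped together with any points it contains; choose
a cell size that tiles the window when exact count conservation matters.

For cell i with counts x and binary weights w_ij = 1[d(i,j) ≤ band]
(including w_ii — the star form):

    Gi* = [Σ_j w_ij x_j − X̄ W_i] / (S · sqrt[(n·W2_i − W_i²)/(n−1)])

with X̄ = Σx/n, S = sqrt(Σx²/n − X̄²), W_i = Σ_j w_ij, W2_i = Σ_j w_ij².
p-values are two-sided normal tails, adjusted with the
Benjamini–Hochberg step-up (the standard procedure with the FDR control
guarantee; proprietary GIS FDR variants are not publicly specified at
formula level). Confidence bins: ±3 if p_adj < 0.01, ±2 if < 0.05,
±1 if < 0.10, else 0, signed by Gi*.

Degenerate inputs: a constant count surface (S = 0) is an error. A cell
whose neighbourhood covers every cell has numerator and denominator both
exactly zero and is reported as Gi* = 0, p = 1; if the band makes every
neighbourhood global, the call errors instead of returning a table of
zeros.

Scale defaults, always logged: when only a band is given, cell_size =
band/2; when neither is given, the band is the maximum nearest-neighbour
distance over the input points (the smallest radius at which every
point — and a fortiori every occupied cell — has a neighbour) and
cell_size = band/2. There is no "optimal scale" search; the choice is
explicit and reproducible.

Edge behaviour worth knowing: cells at the fishnet boundary have smaller
W_i, which inflates |Gi*| for cells adjacent to mass concentrations near
the boundary. The planted-hotspot test therefore centres its analysis
window on the planted cluster so the cluster is interior to the fishnet;
analysts gridding real data should likewise extend the window beyond the
pattern of interest.

## Nearest-facility assignment and bypassing

Distances are Euclidean straight lines — the standard travel-cost proxy
where road-network and travel-time data are unavailable; topographic and
infrastructural barriers are acknowledged and ignored. Each enrollee's
candidate set is the accredited facilities (all facilities with
`accredited_only=False`). Ties within 1e-6 m are co-nearest: the
reported nearest id is the lexicographically smallest, and an enrollee
using any co-nearest facility is not a bypasser. Bypassing is therefore
"used facility ∉ co-nearest set", the operationalisation of patronising
a facility other than the one with the lowest travel cost.

Report tables group by the facility USED — the patron population of each
facility, which is how facility-exit surveys sample. The distance table
reports, per facility, the min and max distance travelled among its
patrons (in km, 3 dp) and closes with the unweighted mean of each column
over facilities; this is the one reading of the published table layout
whose total row reproduces its own arithmetic. Percentages in the bypass
table are recomputed from summed counts, never averaged.

## Synthetic-data generator

The generator emulates the structure of a facility-accessibility field
study so the whole chain is testable without deposited coordinates.

Defaults are the study conditions of the motivating survey and are not
tuning knobs: a square region of 3.19813 × 10⁹ m² (the 11-LGA Ibadan
metropolis), 531 facilities, 431 enrollees, landmark-proxy jitter radius
uniform on [300, 500] m. Where the study fixes no value, a single
realistic choice was made and kept: 25 Thomas parents with 2000 m
offspring sd (kilometre-scale urban clusters), exponential distance
decay with λ = 5000 m for facility choice (patients discount facilities
on the scale of a few km), care-level mix ≈ 42/57.5/0.5%
primary/secondary/tertiary with only non-primary facilities accreditable
at 56% odds — ratios matching the published facility census of the
region.

Mechanics:

- **Patterns.** csr: uniform by rejection sampling from the polygon's
  bounding box (rejection, not reflection, keeps uniformity exact).
  thomas: parents uniform; offspring pick a parent uniformly and scatter
  isotropically (sd = thomas_sd), rejected at the boundary, conditioned
  on exactly n points. grid: square lattice at spacing √(area/n),
  centred in the bounding box including boundary sites, truncated
  row-major to n; shapes that lose too many lattice sites to their
  boundary (e.g. a disc) raise an error.
- **Choice model.** Facility j is used with probability ∝
  attractiveness_j · exp(−d_j/λ) computed from the TRUE residence over
  the accredited subset; the recorded residence is then displaced by a
  uniform angle and a uniform [jitter_min, jitter_max] radius. Choosing
  before jittering reproduces the measurement structure of
  landmark-proxy geocoding and creates apparent bypassing even for
  near-rational choosers (λ → 0): with zero jitter the bypass rate is 0,
  with 300–500 m jitter it stays positive. Scores are computed in log
  space so tiny λ cannot underflow.
- **Randomness.** One seed spawns independent child streams for
  facilities and enrollees in a fixed order, so enlarging the enrollee
  sample never perturbs facility coordinates; identical seeds give
  byte-identical tables.

What the generator does **not** emulate: road networks and travel time,
non-uniform residential density (true residences are uniform in the
region — a declared modelling choice, not an inference about any city),
facility capacity, referral, or any behavioural reason for bypassing.
Tests passing on synthetic data therefore demonstrate the correctness
and statistical behaviour of the methods, not the empirical bypass
mechanism of a real population.

## Reporting

Coverage statistics recompute every percentage from the raw per-LGA sums
at call time. The per-LGA accreditation share uses all facilities in the
LGA as denominator (primary facilities, though never accreditable,
remain in it — the convention of the published summary table it
mirrors). The Kish sample size uses a ceiling, the conservative
convention. The published bypass table it reproduces totals 431 patrons
against the survey's designed 420, and the published nearest-neighbour
summary prints an Rn and z that are not mutually consistent with its own
D̄o and D̄e under the standard formulas; the package reproduces each
table's own arithmetic and documents, rather than reconciles, these
discrepancies. (For the same reason, only D̄e — fully determined by n and
A — is treated as a reproducible reference value.)

## Problem sizes in the test suite

The statistical property tests run at the scales their claims need and
no larger: CSR calibration uses 1000 simulations at n = 531; the lattice
limit uses 10,000 points; planted-hotspot recovery uses 500-point
single-parent Thomas patterns on three seeds plus 20 CSR seeds for the
null; oracle-equivalence checks use 20 random instances each of a few
hundred points. The full suite completes in well under a minute.
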