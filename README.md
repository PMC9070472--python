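# geoaccess

Spatial accessibility analysis for health-facility networks, built for
health-systems researchers studying how the geography of a provider
network shapes access to care — and in particular for the common
situation of an insurance scheme (such as Nigeria's NHIS) whose
accredited facilities cluster in an urban core while enrollees live
everywhere.

The package answers four questions about a facility network on a planar
(projected, metre-based) map:

1. **Is the network clustered?** The Clark–Evans average
   nearest-neighbour test compares the observed mean distance to the
   nearest other facility, *D̄o*, with its expectation under complete
   spatial randomness over a declared study area *A*:

   *D̄e* = ½√(*A*/*n*),  SE = 0.26136/√(*n*²/*A*),
   *Rn* = *D̄o*/*D̄e*,  *z* = (*D̄o* − *D̄e*)/SE.

   *Rn* < 1 with small *p* ⇒ clustered; ≈ 1 ⇒ random; > 1 ⇒ dispersed.

2. **Where are the hotspots?** Facilities are counted into a square
   fishnet; each cell gets a Getis–Ord Gi\* z-score with binary
   fixed-distance weights (the star form includes the cell itself),
   p-values are Benjamini–Hochberg FDR-adjusted and binned into signed
   confidence classes (±1/±2/±3 at 90/95/99%, 0 = not significant).

3. **Who bypasses?** Each enrollee is assigned their Euclidean-nearest
   accredited facility; an enrollee whose actually-used facility is not
   among the co-nearest set is a *bypasser*. Per-facility bypass-rate
   and shortest/longest-distance tables summarise the patron population
   of every facility, and hub-line GeoJSONs ("spider-web diagrams")
   visualise the flows.

4. **How equitable is coverage?** Stratum (urban/semiurban) population
   shares, scheme coverage and enrollee shares are derived from a
   per-LGA summary table, alongside the Kish minimum sample size
   n = ⌈z²p(1−p)/d²⌉ for survey planning.

Because the field study's point coordinates were never deposited, the
package ships a synthetic-data generator that reproduces the study's
structure — clustered/random/regular facility patterns over a
~3.2 × 10⁹ m² region, uniform residences, exponential distance-decay
facility choice, and the 300–500 m landmark-proxy jitter of the recorded
residences — so every stage is testable end to end. Published summary
tables of the Ibadan NHIS survey are included in `geoaccess.datasets`
as worked-example inputs for the reporting operations.

## Worked example

```python
from geoaccess import SyntheticConfig, simulate, clark_evans, assign_nearest, bypass_table

cfg = SyntheticConfig(seed=3)          # 531 facilities, 431 enrollees
facilities, enrollees = simulate(cfg)

nna = clark_evans(facilities, area=cfg.area.area)
assignments = assign_nearest(enrollees, facilities)
total = bypass_table(assignments).iloc[-1]
print(nna.pattern, round(nna.rn, 3))
print(f"{total['pct_bypassed']}% of {int(total['n_patrons'])} enrollees bypassed")
```

Running the bundled examples prints, among others:

```
expected under CSR (De)   : 1227.0741 m     # ½√(A/n) at n=531, A=3.19813e9 m²
Clark-Evans ratio Rn      : 0.6402          # < 1: facilities are clustered
pattern                   : clustered
bypassed nearest          : 392 (91.0%)     # synthetic study, seed 3
overall bypass rate       : 94.0% (405/431) # published Ibadan counts
urban NHIS coverage       : 5.5%            # vs 0.5% semiurban
```

The `De` value is the closed-form CSR expectation for 531 facilities on
the declared 3.19813 × 10⁹ m² study area; the 94.0% is the overall
bypass rate recomputed from the published per-facility counts; the
coverage percentages quantify the urban/semiurban equity gap.

Each script in `examples/` demonstrates one capability
(`point_pattern_test.py`, `hotspot_mapping.py`, `bypass_analysis.py`,
`coverage_and_sample_size.py`, `full_pipeline.py`). A thin CLI mirrors
the library:

```bash
geoaccess simulate --seed 1 --out-dir study
geoaccess nna study/facilities.csv --area 3.19813e9
geoaccess assign study/enrollees.csv study/facilities.csv
geoaccess report assignments.csv
geoaccess run --config pipeline.yaml
```

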