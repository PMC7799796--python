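# Methods

## Problem and model

`caregap` quantifies gaps in the spatial accessibility of two classes of
formally established care services for people aged 65+ with lowered
self-sufficiency: **residential** services (homes for the elderly,
special-regime homes; capacity in beds) and **outpatient-clinic**
services (day care centres, day services centres; capacity in daily
spots). The unit of analysis is the district, nested in regions and
composed of municipalities. Demand is proxied by X1, the count of
recipients of the state care allowance aged 65+ living in each
municipality; supply by X2 (residential capacity) and X3 (clinic
capacity) summed per district.

The analysis has three phases.

**Phase 1 — reachability and coverage.** For every municipality the
minimal travel time to the nearest municipality hosting a facility of
each class is computed twice: by *individual transport* (IT), as
shortest paths on a road network with per-edge travel minutes, and by
*public transport* (PT), from a timetable of station-to-station
connections. PT records pass hard feasibility filters before use:
duration strictly below 90 minutes, at most 5 transfers, direct distance
strictly below 150 km, and arrival at one of the target times of the
reference weekday (Tuesday; 14:00 for residential visits, 07:00 and
08:00 for clinics). Among feasible records of one origin–destination
pair the best connection is chosen by a weighing function (below).
Municipal travel times are banded into cumulative 30- and 60-minute
budgets, and the district coverage indicators are recipient-weighted
shares:

    X_k = 100 · Σ X1(municipalities within the band) / Σ X1(district)

giving X4a/X4b (residential, IT), X5 (residential, PT), X6 (clinic, IT)
and X7 (clinic, PT), where `a` is the 30-minute and `b` the 60-minute
part.

**Phase 2 — gap classification and TOPSIS ranking.** Each district ×
service × mode combination is graded on a three-tier scale: **I** (good,
no gap) when a provider is seated in the district and 30-minute coverage
reaches at least 80%; **III** (poor, significant gap) when no provider
is seated in the district and 60-minute coverage is at most 40%; **II**
(lowered, a gap) otherwise. Classes aggregate per region into counts
plus an overall "Total in %" row (half-up rounding; one decimal for
residential tables, integers for clinic tables). Districts are also
ranked by TOPSIS run separately per coverage group on the two-criterion
matrix (a-part, b-part) with weights 0.60/0.40 for residential groups
and 0.70/0.30 for clinic groups: vector column normalisation,
weighting, ideal/base alternatives as column max/min, Euclidean
distances, closeness c = d⁻/(d⁻+d⁺) ∈ [0,1]. The four group scores
average into the mean-total score MTc per district.

**Phase 3 — association.** Pearson correlations over districts between
X1–X3 and the four group closeness scores (entered as X4–X7), with
two-sided significance flags at α = 0.05 and 0.01 and a 95% percentile
bootstrap confidence interval per pair.

## Design choices where the design was open

* **Classification rule totality.** The verbal scale has holes (e.g.
  30-minute coverage of 70–80% falls between the stated ranges of
  classes I and II). II is defined as the residual class, which makes
  the rule total and mutually exclusive; the monotonicity property
  (more coverage never yields a worse class) is property-tested.
* **Coverage basis.** The scale is applied to recipient-weighted
  coverage, the only formalised coverage quantity, even though the
  verbal scale speaks of area shares; a municipality-count "area" proxy
  is available as a `ScaleRule(basis="area")` sensitivity option.
* **Weighing function.** The PT connection choice compares travel time,
  arrival slack, departure earliness, transfer count and price. Its
  exact form is a package choice: a weighted sum of min-max-normalised
  attributes (weights 0.5/0.1/0.1/0.2/0.1, travel time dominant;
  configurable and recorded in the run log), with a deterministic
  tie-break (travel time, transfers, price, input order). Constant
  attributes contribute zero after normalisation.
* **Arrival matching.** "Arrival at 07:00/08:00/14:00" is matched to the
  exact minute by default, with a configurable ± tolerance
  (`arrival_tolerance_min`), since no tolerance window is defined by the
  analysis design. PT travel time counts departure→arrival (transfer
  waits included); initial waiting before departure is not counted.
* **Common endpoint.** Both modes measure access to the *municipality*
  hosting the nearest facility, not the facility door — regional
  timetables describe main-station links, and using the same endpoint
  for IT keeps the modes comparable. A municipality hosting a facility
  of the class is at 0 minutes in both modes (timetables contain no
  self-connections). `AccessConfig.it_target` reserves a door-level IT
  switch for real-data runs.
* **TOPSIS degeneracies.** An all-zero criterion column normalises to
  zeros with a warning; indistinguishable alternatives (d⁺ = d⁻ = 0, as
  when a group's coverage is 100% everywhere) get closeness 0.5 with a
  warning instead of an exception, so batch runs survive pathological
  inputs. All eight criteria are benefit criteria. Ties in rankings
  break by district id.
* **Zero-recipient districts.** Coverage would divide by zero; it is
  defined as 0 with a warning, and such districts are excluded from the
  TOPSIS group rankings (logged) and dropped from the correlation input.
* **Significance test.** Only the α levels are part of the analysis
  design; the test implemented is the two-sided t-test with
  t = r·√((N−2)/(1−r²)) and N−2 degrees of freedom. |r| = 1 is flagged
  significant by convention with a warning.
* **Bootstrap.** District rows are resampled jointly (pairs), 2000
  resamples, percentile bounds at 2.5/97.5 (no BCa). Zero-variance
  resamples are redrawn by default (`degenerate_policy="drop"`
  discards them instead). Rows are sorted by district id before
  resampling so the interval does not depend on input row order.
* **Strength labels.** Only "moderate" (0.30–0.49) and "substantial"
  (0.50–0.69) come from the six-interval interpretation scale the
  analysis cites; the outer intervals (negligible < 0.10, low 0.10–0.29,
  very high 0.70–0.89, near-perfect ≥ 0.90) are a documented extension
  in the same spirit, matched on |r|.
* **Descriptive statistics.** sd uses the N−1 denominator; skewness is
  sample (Fisher) skewness and kurtosis is sample *excess* kurtosis,
  labelled as such in `topsis_summary.csv`.

## Synthetic study areas

The generator (`caregap.synthetic`) emulates the structural features the
analysis assumes rather than any real geography:

* 13 regions with 3–12 districts each and 6–12 municipalities per
  district (planar x,y coordinates in km; no geodetic math — nothing in
  the analysis needs a projected CRS at this scale, and no capital-like
  outlier unit is generated);
* per-municipality recipient counts from a negative-binomial spec
  (mean 220, shape 1.8), giving the strongly overdispersed district
  totals observed in administrative registers;
* facility counts per district Poisson with expected rates 10
  (residential) and 1.75 (clinic) — matching roughly 760 residential and
  133 clinic facilities over 76 districts — scaled by the district's
  relative demand so that capacity tracks demand positively, as real
  provider networks do; districts without any clinic are therefore a
  normal outcome. Residential capacities are lognormal around 53 beds;
  clinic capacities uniform on 5–15 daily spots;
* a road network that is connected within every district (hub spokes
  plus a chain), with chained district hubs per region and region
  gateways, edge minutes drawn from a configurable spec (default
  uniform 8–26 minutes; doubled for inter-district and tripled for
  inter-region links);
* a timetable of within-region connections (own hub always; other
  same-district municipalities and region hubs with probability
  `transit_coverage` = 0.35), each arriving exactly at 07:00, 08:00 and
  14:00 with duration scaled to straight-line distance plus noise,
  Poisson transfer counts and distance-proportional prices; a fraction
  of records deliberately violates the feasibility filters so the
  filtering path is exercised.

All randomness flows from one `numpy` Generator seeded by
`RegionConfig.seed`; equal configurations produce bit-identical datasets
(hash-tested).

**Planted scenarios.** `plant_gap_scenario` edits a copy of a dataset so
one district lands in a chosen class for a chosen service and mode, for
classifier-recovery testing: the district is isolated for the planted
mode (road links neutralised to a 10 000-minute sentinel, or origin
connections removed), per-municipality recipients are equalised so a
planted share of connected municipalities is exactly the planted
coverage share, and a facility host is wired to all municipalities
(class I, coverage 100%), to ~60% of them (class II, coverage in the
50–70% band; same-class facilities are consolidated onto the single host
so stray hosts cannot inflate coverage), or removed entirely with
nothing reachable (class III). Every edit is appended to the mandatory
`edit_log`. Class II is infeasible in a one-municipality district (only
0% or 100% coverage is constructible) and raises an explicit error.

**What the generator does not emulate.** Real road topology and
congestion, door-level facility access, city public transport,
capacity-constrained admission, demographic dynamics, and the full
spatial autocorrelation of real demand. Passing tests on synthetic areas
therefore validate the *computational pipeline* — filters, formulas,
classification, ranking, inference — not any empirical claim about a
particular country's service network.

## Numerical conventions

* Unreachable = `math.inf` internally; empty field in CSV exports.
* Bands are inclusive (`minutes ≤ b`) and cumulative by default;
  `cumulative=False` switches the second band to ring (30–60) semantics
  for sensitivity analysis.
* "Total in %" rows round half-up (not banker's rounding).
* Exports: coverage percentages with one decimal, closeness scores with
  three decimals, times as HH:MM; full precision is kept internally.
* Parallel road edges collapse to the fastest; roads are undirected.

## Problem sizes in the test and acceptance suites

Shortest-path results are checked against exhaustive simple-path
enumeration on 100 random graphs of at most 8 nodes; TOPSIS invariants
(dominance monotonicity, scale invariance, [0,1] range) over 1000 random
matrices; planted-class recovery over 20 seeded datasets × 3 classes ×
2 services × 2 modes (240 recoveries, 1 region × 2 districts × 5
municipalities each); bootstrap calibration over 500 bivariate-normal
replicates at n = 76, true ρ = 0.4, 2000 resamples each (coverage must
fall in 90–98%). The acceptance script's pipeline run uses the full
13-region default configuration.
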