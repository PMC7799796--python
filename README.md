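# caregap

Spatial-accessibility gap analysis for care services for people aged 65+
with lowered self-sufficiency.

Planners of social-care networks need to know not only *how much*
capacity exists but *where it can actually be reached*. `caregap`
implements a three-phase district-level analysis of residential care
(homes for the elderly, special-regime homes) and outpatient-clinic care
(day care and day services centres):

1. **Reachability and coverage** — minimal travel times from every
   municipality to the nearest facility-hosting municipality, by
   individual transport (shortest paths on a road network) and by public
   transport (timetable connections filtered to < 90 min, ≤ 5 transfers,
   < 150 km, arriving at 07:00/08:00/14:00 on a common workday, the best
   connection per pair chosen by a weighing function). Coverage
   indicators are recipient-weighted shares per district d:

   `X_k = 100 · Σ X1(d, within 30/60 min) / Σ X1(d)`

   where X1 counts care-allowance recipients aged 65+, giving
   X4a/b … X7b for residential/clinic × individual/public transport.

2. **Gap classification and TOPSIS ranking** — each district × service ×
   mode is graded I (good: provider seated in the district and ≥ 80%
   coverage within 30 min), III (poor: no provider and ≤ 40% coverage
   within 60 min) or II (lowered: everything else), aggregated into
   per-region scale tables with "Total in %" rows. Districts are ranked
   by TOPSIS closeness c_i = d⁻/(d⁻+d⁺) per coverage group (criterion
   weights 0.60/0.40 residential, 0.70/0.30 clinic) and by the mean
   total MTc_i.

3. **Association** — Pearson correlations between demand (X1), capacity
   (X2, X3) and the accessibility scores, with t-test significance flags
   at α = 0.05/0.01 and 95% percentile-bootstrap confidence intervals.

Real runs consume CSV inputs (`districts.csv`, `municipalities.csv`,
`facilities.csv`, `road_edges.csv`, `transit_connections.csv`); a
first-class synthetic generator produces seeded study areas with the
structural properties the analysis assumes, including planted scenarios
with known gap classes for validation. See `docs/methods.md` for the
model, conventions and design choices.

## Worked example

```python
from caregap.reporting import RunConfig, run_full_analysis
from caregap.synthetic import RegionConfig

cfg = RunConfig(
    generator=RegionConfig(
        n_regions=3, districts_per_region=(4, 6),
        municipalities_per_district=(5, 9), seed=42,
    ),
    seed=42,
)
report = run_full_analysis(cfg, "out/")
```

This writes seven result tables. The `scale_table.csv` Total rows for
this 14-district area:

```
service_class mode     region     I   II  III
       clinic   IT Total in %  64.0 29.0  7.0
       clinic   PT Total in %  36.0 43.0 21.0
  residential   IT Total in % 100.0  0.0  0.0
  residential   PT Total in %  78.6 21.4  0.0
```

i.e. every district has good residential accessibility by car
(a seated provider and ≥ 80% of recipients within 30 minutes), while by
public transport 21% of districts drop to class II, and clinic care by
public transport shows a significant gap (class III) in 21% of
districts. The best-ranked districts in `topsis_scores.csv`:

```
             X4ci  X5ci   X6ci   X7ci   MTci  rank_MT
district_id
R01-D02       0.5   1.0  1.000  1.000  0.875        1
R03-D03       0.5   1.0  1.000  1.000  0.875        2
R01-D04       0.5   1.0  1.000  0.927  0.857        3
```

(X4 coverage is 100% everywhere here, so that group cannot discriminate
and every district receives the neutral closeness 0.5 with a logged
warning.) And from `correlations.csv`, demand vs capacity:

```
var_a var_b  n        r  sig05  sig01  ci_lower  ci_upper       label
   X1    X2 14 0.558509   True  False  0.094597  0.863667 substantial
```

— districts with more allowance recipients tend to hold more residential
beds (r = 0.56, significant at 0.05, bootstrap 95% CI 0.09–0.86).

The same pipeline is scriptable from the shell:

```sh
caregap run --config cfg.yaml --out results/ --seed 42
caregap simulate --out data/ --seed 7        # dataset CSVs only
caregap access --data data/ --out results/   # single stages
```

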