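# camtrap-niche

Spatiotemporal niche-partitioning analysis for camera-trap surveys.

Sympatric carnivores can coexist by separating along the time axis (being
active at different hours of the diel cycle), the space axis (using
different sites and habitats), or both. This package implements the
standard camera-trap workflow used to quantify that separation for a
predator guild and its prey:

1. **Independence filtering** — raw photo-captures are reduced to
   independent events: within each (species, station) stream a capture
   counts only when it falls strictly more than 30 minutes (configurable)
   after the most recently retained event.
2. **Circular (diel) statistics** — event clock times are mapped to angles
   θ = 2π·h/24 on the 24-h circle; per species we report the mean
   activity time, mean resultant length R̄, circular variance V = 1 − R̄,
   the large-sample standard error and 95% CI of the mean direction, and
   Rayleigh's uniformity test Z = nR̄².
3. **Diel overlap** — activity densities are estimated with von Mises
   kernel density estimates (plug-in concentration
   κ_k = adjust·[3nκ̂²I₂(2κ̂)/(4√π I₀(κ̂)²)]^{2/5}); the coefficient of
   overlap Δ = ∫ min(f, g) is estimated with Δ̂₁ (grid integral of
   min(f̂, ĝ), adjust 0.8) when the smaller sample is below 75 and Δ̂₄
   (mean clipped density ratios at the observed points, adjust 1.0)
   otherwise, with smoothed-bootstrap 95% CIs (default 10 000 iterations).
4. **Association and habitat axis** — Spearman rank correlation of percent
   hourly activity (temporal association) and of per-station relative
   abundance indices RAI = events/trap-nights (spatial association);
   habitat-use percentages; Jacobs selectivity
   D = (r − p)/(r + p − 2rp) against effort-weighted availability;
   Pianka's niche overlap O = Σp₁p₂/√(Σp₁²Σp₂²) over stations; and
   UPGMA clustering of species habitat profiles under the
   correspondence-analysis chi-square distance.
5. **Synthetic surveys** — a generator with known ground truth (true
   overlap by quadrature, true Jacobs signs, true hourly laws) emulating a
   50-station, 4-habitat survey design, so every stage of the analysis has
   a recoverable target.

## Worked example

Simulate a survey of two crepuscular/nocturnal predators whose true diel
overlap is 0.80 and whose habitat preferences are opposed, then analyze it:

```bash
camtrap-niche simulate --scenario two-predator --seed 3 --out sim/
camtrap-niche run --detections sim/detections.csv --stations sim/stations.csv \
    --out out/ --seed 3 --n-boot 1000
```

or in Python:

```python
from camtrap_niche import (
    SurveySpec, two_predator_scenario, generate_survey,
    AnalysisConfig, analyze,
)

dets, stations, truth = generate_survey(two_predator_scenario(0.80),
                                        SurveySpec(), seed=3)
bundle = analyze(dets, stations, AnalysisConfig(n_boot=1000, seed=3))
row = bundle["pairwise"][0]
print(row["estimator"], round(row["temporal_overlap"], 2),
      (round(row["temporal_ci_lo"], 2), round(row["temporal_ci_hi"], 2)))
print("Pianka site overlap:", round(row["pianka_overlap"], 2))
```

printing

```
Dhat4 0.75 (0.66, 0.83)
Pianka site overlap: 0.34
```

— the estimator chosen by the n = 75 rule, the estimated temporal overlap
with its bootstrap CI (the true value 0.80 lies inside), and a much lower
spatial overlap: high temporal but low spatial overlap is the classic
signature of site-level partitioning between predators that share the same
activity rhythm.

The report bundle also contains the circular-summary table, habitat-use
percentages, Jacobs and Pianka tables, hourly/site Spearman associations
with significance stars, a Newick dendrogram, per-pair density plots, and a
machine-readable `report.json` validated against a shipped schema.

## A note on printed reference statistics

Published circular-statistics tables in this literature are sometimes
internally inconsistent (e.g. a printed Rayleigh Z that does not equal
nR̄² for the printed n and variance, or truncated CI bounds). The test
suite therefore validates this package against closed-form values,
exhaustive small-n enumeration, quadrature oracles, and Monte-Carlo
calibration on synthetic data with known ground truth rather than against
any printed table.
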