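# ursadiet

Tools for quantifying brown-bear (*Ursus arctos*) diet from scats, scoring
body condition from lateral photographs, and modelling the seasonal course of
condition against diet and reproductive status — the analysis chain used in
longitudinal, non-invasive monitoring of the philopatric female bears of the
Shiretoko Peninsula, which feed on subalpine stone-pine (*Pinus pumila*) nuts
in August and spawning salmon (*Oncorhynchus* spp.) in September.

It is written for wildlife nutritional ecologists who have tabular field
records (scat compositions, photo landmark coordinates, reproductive
statuses) and want a tested, reproducible path from those records to
corrected diet compositions, a body-condition index, and ranked seasonal
models. A synthetic-study generator with known ground truth stands in for
field data, so the whole pipeline is testable on any machine.

## What it computes

**Diet from scats.** Washed scat material is scored with the point-frame
method: the share of grid intersections covered by food item *i* is its
occupancy,

    Occupancy_i [%] = 100 · n_i / Σ_j n_j ,

used as the item's volumetric proportion. Because items differ in
digestibility, volumes are corrected before interpretation: with dry-matter
correction factors CF_D and digestible-energy factors CF_E,

    EDC_i  = 100 · V_i·CF_D,i / Σ_food V_j·CF_D,j
    EDEC_i = 100 · V_i·CF_D,i·CF_E,i / Σ_food V_j·CF_D,j·CF_E,j ,

the estimated dietary content (ingested dry mass) and estimated
digestible-energy content, over food items only. Acceptance rules (≥ 200
points per scat, with a ≥ 50 g wet-weight exception for highly digestible
salmon scats), nonfood exclusion (incidental material; bear hair at ≤ 0.5%
treated as grooming residue), nine-category aggregation, period summaries
with frequency of occurrence, through-origin calibration of visually
estimated volumes (vFV) against EDC, and high/low consumption-year
classification are all implemented as specified rules with audit logging.

**Body condition from photographs.** On a quality-graded, angle-rectified
lateral photograph, torso height TH (vertical abdomen-to-waist distance) and
horizontal torso length HTL (horizontal tail-base-to-shoulder distance) are
each measured three times; TH:HTL, the ratio of the replicate means, is the
condition index. Sessions (June = 1 … November = 6, half-month steps in
August–September) need ≥ 2 photographs; bear-years need ≥ 2 sessions;
sessions after offspring loss are excluded.

**Seasonal condition models.** TH:HTL is modelled with gamma-family,
log-link GAMMs: thin-plate regression splines of session (optionally one
smooth per level of a diet-year or reproductive-status factor), fixed effects
for status and diet-year class, and crossed random intercepts for year and
bear. Smoothing and variance parameters are selected by REML on the working
model; the 13-model candidate set is ranked by AICc and Akaike weights, and
population-level prediction curves carry 95% confidence bands.

## Worked example

```python
from ursadiet import (FoodItemTable, example_taxonomy, compute_occupancy,
                      apply_nonfood_rules, compute_edc, compute_edec,
                      aggregate_categories)

taxonomy = FoodItemTable.from_frame(example_taxonomy())
counts = {"pine_nuts": 132, "herbaceous_plants": 88, "salmon": 9, "debris": 11}
flagged = apply_nonfood_rules(compute_occupancy(counts), taxonomy)
edc = aggregate_categories(compute_edc(flagged, taxonomy), taxonomy)
edec = aggregate_categories(compute_edec(flagged, taxonomy), taxonomy)
for k in edc.values:
    print(f"{k:12s} EDC {edc.values[k]:5.1f}   EDEC {edec.values.get(k, 0):5.1f}")
```

```
pine_nuts    EDC  58.2   EDEC  70.8
plants       EDC  25.9   EDEC  12.8
salmon       EDC  15.9   EDEC  16.4
```

Read: although pine nuts covered 55% of the counted points, their higher
dry-matter retention and energy density raise them to 58% of ingested dry
mass and 71% of digestible energy; the `debris` points are excluded as
nonfood before correction. (The shipped example taxonomy carries placeholder
correction factors in literature-plausible ranges — supply your own
`taxonomy.csv` for real analyses.)

The full pipeline runs from the shell. `simulate` writes a complete
synthetic study (scats, taxonomy, photographs, reproductive records, ground
truth); `report` runs diet quantification, year classification, condition
scoring, and model selection end to end:

```sh
ursadiet simulate --seed 7 --out demo/
ursadiet report --dir demo/ --out demo/out/ --seed 7
```

On the default synthetic study this prints `top model: S(Session x Diet1) +
RST x Diet1` — the selection table in `demo/out/selection.csv` gives that
model (separate session smooths for high- and low-consumption years, plus
reproductive status) an Akaike weight of 1.000, and `estimates.csv` shows
the with-young condition deficit (β = −0.019, SE 0.005, log scale) and the
two smooth terms (edf 3.0 for high-consumption years vs 3.7 for
low-consumption years, whose minimum falls later in the season) — matching
how the study was generated. Other outputs: `diet_summary.csv`,
`annual_edc.csv`, `year_classes.csv`, `observations.csv`, `curves.csv`.

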