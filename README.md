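# nucleoscore

Quantification of nucleolar stress from multichannel fluorescence images.

The nucleolus reorganizes in characteristic ways when ribosome biogenesis
is perturbed: granular-component (GC) proteins such as nucleolin disperse
into the nucleoplasm, while fibrillar-center (FC) proteins such as UBF
condense into peripheral stress caps or decompact into extended strings.
`nucleoscore` implements a per-cell **nucleolar normality score** that
captures both movements in a single dimensionless ratio, and the
surrounding machinery needed to use it at screening scale:

* **Segmentation** — nuclei from a DNA counterstain (rolling-ball
  background subtraction, 10%-of-maximum threshold, border and size
  gates) and nucleoli from the FC marker (0.7-px Gaussian smoothing,
  per-nucleus threshold at 40% of the min–max span, ≥ 4 px objects).
* **Scoring** — per-cell integrated intensities split into nucleolar and
  nucleoplasmic compartments and combined as

      score = (GC nucleolar / GC nucleoplasmic) / (FC nucleolar / FC nucleoplasmic)

  which decreases under stress, plus single-channel nucleolus/nucleoplasm
  ratios (e.g. for RNA Pol I occupancy) and per-field intensity summaries
  (e.g. 5-EU nascent-RNA readouts).
* **Screening** — field→well aggregation, vehicle (DMSO) normalization,
  one-sided 2-SD hit calling across two concentrations, hit categories,
  and hypergeometric target-class enrichment.
* **FRAP** — double normalization with exact acquisition-bleaching
  correction, bounded two-component exponential recovery fits, composite
  T½, and Welch-test group comparisons.
* **Phosphoproteomics filtering** — spectral-count ratio rules
  (0 → 0.1 replacement), abundance classification (|LogFC| > 1.5,
  FDR < 0.05), and site exclusion rules (per-replicate minimum counts,
  significantly decreased proteins).
* **Synthetic data** — ground-truthed generator for the four stress
  phenotypes (normal, canonical stress caps, metabolic shrinkage,
  dissolution strings), simulated screening plates with planted hits, and
  forward-simulated FRAP traces, so the whole pipeline is testable
  without microscope data.

## Worked example

Generate a small synthetic experiment, score it, and call hits:

```python
from nucleoscore import synthetic, scoring, screen

# a normal and a dissolution-phenotype field, with ground truth
params = synthetic.default_analysis_params()
for phenotype in ("normal", "dissolution"):
    sf = synthetic.generate_field(synthetic.PhenotypeParams(phenotype=phenotype, seed=1))
    cells = scoring.score_field(sf.field, params=params)
    print(phenotype, "mean score:", round(cells["normality_score"].mean(), 3),
          "analytic:", round(sf.truth["analytic_score"].mean(), 3))
```

```
normal mean score: 3.866 analytic: 3.8
dissolution mean score: 0.011 analytic: 0.011
```

A healthy cell keeps most nucleolin in nucleoli (GC ratio high) while UBF
also concentrates there, giving a score near 3.8 under the generator's
default intensity pools; in the dissolution phenotype the GC marker is
almost fully nucleoplasmic and the score collapses by two orders of
magnitude. At plate scale:

```python
cells, layout, truth = synthetic.generate_plate(
    n_compounds=200, hit_fraction=0.15, effect_size_sd=6.0,
    cells_per_well=30, n_vehicle_wells=64, seed=2,
)
wells = screen.aggregate_wells(cells, layout)
mean, sd = screen.vehicle_stats(wells)
calls = screen.call_hits(wells, mean, sd, k=2)
print("hits:", sum(c.category != "none" for c in calls), "of", len(calls))
```

```
hits: 34 of 200
```

The same steps are available from the shell via the `nucleoscore` CLI
(`simulate`, `score`, `screen`, `frap`, `phospho`); every run writes its
effective configuration next to its outputs.

As a point of reference for the hit-category arithmetic: in a screen of
1180 compounds where 83 are hits at both 1 and 10 µM and 69 at 10 µM only,
`screen.hit_percentages(83, 69, 1180)` gives 7.0% + 5.8% = 12.9% of the
library.

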