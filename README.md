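# dimerscreen

A hit-discovery pipeline for luminescence receptor-dimerization
high-throughput screens, written for computational chemists and screening
scientists who want the full cascade — plate normalization, substructure
pharmacophore discovery, machine-learning hit expansion, dose-response
pharmacology and image-based phenotyping — as one tested, reproducible
library rather than a chain of one-off scripts.

The pipeline covers five stages:

1. **Plate statistics** (`dimerscreen.plates`). Tukey median polish
   decomposes each plate into `value = grand + row + col + residual`,
   correcting row/column/edge artifacts; B-scores
   `b = residual / (1.4826 · MAD)` put all plates on one robust scale for
   screen-wide top-N triage. Confirmation hits are signals strictly above
   `mean(neg) + 3·SD(neg)`.
2. **MCS enrichment** (`dimerscreen.mcs`). The maximum common substructure
   of every hit pair is mined (element/bond-order matching, ring bonds to
   ring bonds), deduplicated, clustered with k-means on circular
   fingerprints, and scored by compound-level fold-enrichment
   `(h/H)/(r/R)` against a reference library; enriched patterns select
   analogue sub-libraries.
3. **ML expansion** (`dimerscreen.ml`). A 500-tree random forest on
   2048-bit radius-2 Morgan fingerprints ranks unscreened compounds by
   predicted activity, always excluding training compounds.
4. **Dose-response** (`dimerscreen.doseresponse`). Signals are normalized
   to reference-ligand controls (0% = vehicle, 100% = reference) and fit
   with the variable-slope 4PL
   `y = bottom + (top − bottom)/(1 + 10^(hill(log₁₀EC₅₀ − log₁₀x)))`
   for EC50/Emax, descending IC50 fits, and modulator potentiation on
   fitted tops.
5. **CSA segmentation** (`dimerscreen.csa`). A deterministic cardiomyocyte
   cross-sectional-area algorithm on two-channel (nuclei + cell body)
   images: mode/SD-based thresholds, 500-px nucleus filter, Scharr-gradient
   compact watershed (compactness 0.1) seeded by nuclei, border removal and
   morphological cleanup, reporting per-cell pixel areas.

`dimerscreen.synthetic` generates every input the pipeline consumes —
artifact-laden plates, planted-pharmacophore SMILES libraries,
dose-response tables, and cell micrographs — with exact ground truth, so
the whole cascade is testable offline. See `docs/methods.md` for models,
parameter choices and limitations.

## Worked example

Simulate a 10-plate screen with ±30% gradients, 20% edge depression and 2%
spiked actives, normalize it, and triage the top 80 wells:

```python
from dimerscreen import synthetic as syn, plates as pl

spec = syn.PlateEffectSpec(seed=1)          # 1e6 counts, 5% CV, +8-unit spikes
screen, truth = syn.simulate_screen(spec, n_plates=10)
scored = [pl.b_score(p) for p in screen]
top = pl.select_top_hits(scored, 80, plates=screen)

actives = set(truth.wells.loc[truth.wells.is_active, "compound_id"])
hit = len(actives & set(top.compound_id))
print(f"spiked {len(actives)}, recovered {hit} in top 80 "
      f"({100 * hit / len(actives):.1f}%)")
print(top.head(3)[["compound_id", "plate_id", "b_score"]].to_string(index=False))
```

```
spiked 66, recovered 64 in top 80 (97.0%)
compound_id plate_id   b_score
  CMP-01429     P005 12.704227
  CMP-01738     P005 12.700840
  CMP-00791     P003 10.457772
```

66 of 3,200 sample wells carried a planted active effect of 8 robust
units; after median polish removed the spatial artifacts, 64 of them
ranked inside the screen-wide top 80 by B-score (the top scores sit where
they should, around 8–12 robust units). Fitting a simulated agonist curve
on the 2-fold 0.0625–32 µM series recovers the generating pharmacology:

```python
from dimerscreen import doseresponse as drc

true = drc.FourPLFit(bottom=0.0, top=27.9, ec50=1.05e-5, hill=1.0)
table, _ = syn.simulate_drc(true, n_reps=4, noise_cv=0.05, seed=2)
fit = drc.fit_4pl(drc.normalize_to_reference(table))
print(f"EC50 {fit.ec50 * 1e6:.2f} uM, Emax {fit.top:.1f}% of reference")
```

```
EC50 9.94 uM, Emax 26.8% of reference
```

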