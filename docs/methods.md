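# Methods

`dimerscreen` reimplements, as a tested library, the computational cascade
of a small-molecule receptor-dimerization agonist campaign: plate
normalization and hit calling for a luminescence high-throughput screen
(HTS), maximum-common-substructure (MCS) pharmacophore discovery with
fold-enrichment scoring, fingerprint/random-forest hit expansion,
four-parameter-logistic (4PL) pharmacology, and an automated cardiomyocyte
cross-sectional-area (CSA) segmentation algorithm. Every stage is
exercisable on synthetic data with ground truth; this note records the
models, the parameters that matter, and the design choices that were
genuinely open.

## Plate statistics

A raw 384-well plate is modeled as an additive decomposition
`value = grand + row + col + residual`, estimated by Tukey median polish:
alternating subtraction of row then column medians. Decisions: rows are
swept first; at most 10 sweeps; the convergence tolerance is `1e-6 ×` the
plate median; residuals are recomputed at the end as `value − fitted` so
the identity holds to machine precision regardless of convergence. Median
polish converges asymptotically — on noisy plates the sweep cap typically
triggers before the tolerance and the decomposition carries an honest
`converged=False`; all downstream guarantees (spike recovery, invariance
properties) hold at the 10-sweep operating point.

B-scores are `residual / (1.4826 × MAD)` with the MAD taken about the
median of the *sample-well* residuals; control wells are excluded from the
polish and the MAD and never receive a score. Because the scale is
per-plate, the screen-wide top-N triage ranks all plates together; ties at
the boundary break by ascending compound id for reproducibility.
Confirmation hits are called on raw signal strictly above
`mean(neg) + 3 × SD(neg)` with the sample SD (`ddof=1`); the denominator
convention and the strictness of the inequality are package decisions.

## Synthetic screen generator

Sample wells follow
`grand_mean × (1 + g_r·u) × (1 + g_c·v) × (1 − edge) × (1 + N(0, cv))`,
where `u, v ∈ [−1, 1]` span rows/columns, so a gradient of 0.3 means ±30%
across the plate; the outermost well ring loses `edge` (default 20%) of
its signal. Defaults (`grand_mean = 1e6` counts, `cv = 0.05`,
`spike_rate = 0.02`, spikes at 8 robust units, 10 plates of 16×24 with
controls in edge-adjacent columns 1 and 22) are the conditions under which
triage recovery is benchmarked. Active wells get an additive spike of
`spike_effect × cv × grand_mean` — the expected robust residual scale of
the noise model — so "+8 robust units" is independent of the luminescence
scale. The plate layout and control placement are declared defaults, not
measurements; real campaigns differ and the layout is configurable.

## Compound libraries and the planted pharmacophore

Libraries are assembled from a fixed fragment grammar (8 ring systems,
short linkers, terminal decorations, optional second substituent), which
guarantees parseability and controllable substructure-match rates. Actives
graft a pharmacophore core (default anilide, `O=C(Nc1ccccc1)`) and are
verified to match it; inactives are grammar draws verified not to. Truth
is the carrier flag; observed labels flip with probability `label_noise`.
The grammar yields ~4,400 distinct structures per 5,000 draws — diverse
enough that structure duplication does not couple label noise across
records, but far simpler than a real vendor collection: fingerprint
separation of carriers is easier here than for real actives, so classifier
benchmarks bound the pipeline's plumbing, not real-world enrichment.

## MCS mining, clustering and enrichment

Pairwise MCS uses FMCS with atoms compared by element, bonds by order,
ring bonds matching only ring bonds, and a 2 s per-pair timeout
(timed-out pairs are skipped and logged). Patterns below 4 heavy atoms are
discarded; uniqueness is by the canonical fragment string obtained by
mapping the MCS query back into one parent molecule. Unique patterns are
embedded as 1024-bit radius-2 circular fingerprints of the fragment and
clustered by k-means (Euclidean metric, 10 restarts, fixed seed); each
cluster's representative is the medoid. Default `k = 10` mirrors the
campaign's cluster count but is configurable — the feature space and the
choice of k are package decisions, since neither is standard.

Fold-enrichment is compound-level: `(h/H)/(r/R)` for `h` of `H` hit
compounds and `r` of `R` reference compounds containing the pattern.
`r = 0` yields a flagged infinite fold by default; a 0.5 pseudocount is
available behind a flag. Embedding-level counting (multiple matches per
compound) is deliberately not used.

## Random-forest hit expansion

Morgan fingerprints: radius 2, 2048 bits, binary. Forest: 500 trees,
balanced class weights, out-of-bag scoring, single-threaded for
reproducibility; stratified k-fold CV metrics are optional (`cv_folds=0`
skips them — the hold-out benchmarks use an explicit split instead, which
is both cheaper and a cleaner estimate). The decision threshold on
predicted probability defaults to 0.5. Predictions always exclude training
compounds and sort by probability, ties by id. Benchmark conditions:
5,000 compounds, 10% carriers, 10% label noise; a 4,000/1,000 split model
provides the hold-out AUROC against true carrier flags, while a production
model trained on all 5,000 ranks a fresh 5,000-compound candidate library,
whose top 34 are scored for carrier enrichment over the planted 10% base
rate. The label-permuted control retrains on five independent permutations
and must average to chance AUROC — a single permuted forest's hold-out
AUROC has a standard deviation near 0.075 (memorized permuted labels
correlate errors across structurally similar compounds), too wide to be a
meaningful single-draw control.

## Dose-response pharmacology

Normalization anchors 0% at the vehicle-control mean and 100% at the
reference-ligand control mean (`response = 100(x − neg)/(pos − neg)`); a
plain-ratio mode is available because "relative to the reference" is
ambiguous in common usage. The 4PL model is the variable-slope logistic on
log10 concentration,
`y = bottom + (top − bottom)/(1 + 10^(hill (log10 EC50 − log10 x)))`,
fit by least squares with quantile-based initialization (extreme
per-concentration means seed the plateaus, the concentration nearest the
midpoint seeds EC50, the sign of the log-concentration/response
correlation seeds the slope). Inhibition fits constrain the slope
non-positive, making `ec50` an IC50. Replicates enter unweighted as
individual points. Non-convergence and span-less (flat) curves return
`converged=False` instead of raising. Potentiation is defined on fitted
tops — `100 × (top_mod − top_base)/top_base` per modulator concentration —
one of several defensible readings (response at a fixed agonist dose and
area-under-curve are alternatives); fitted tops were chosen because the
quantity is otherwise dominated by a single concentration's noise.
The default dilution series is the assay's 2-fold ladder, 0.0625–32 µM.
Parameter-recovery benchmarks plant the true EC50 at the series' geometric
center (~1.4 µM): there both plateaus are sampled and EC50 is identified,
so the measured error reflects the fitter; with a micromolar EC50 near the
top of the ladder the upper plateau is unobserved and the EC50/Emax
correlation dominates the error, a property of the design rather than of
the estimation. Potentiation benchmarks place the baseline and modulated
curves on one shared control set, as they would sit on a real plate —
fitted tops are only comparable on a common normalization scale.

## CSA segmentation

The chain and all constants are fixed by the published algorithm: nucleus
threshold `mode + SD` of the nuclear channel (mode over nonzero
intensities, ties to the lowest bin); nucleus filters at 500 px minimum
area and mean cell-channel signal ≥ `median + 0.5 SD`; cell mask at
`mode + 0.5 SD` with one 4-connected erosion, two dilations, then removal
of pixels below `mode − 0.5 SD`; gradient = gray-erode 3×3 → Gaussian
σ = 3 px → Scharr magnitude → min-max rescale to 8 bits → gray-dilate 5×5;
compact watershed (compactness 0.1) from nucleus seeds within the mask;
then border-object removal, hole filling, 3 erosions + 3 dilations, and
pixel-count CSA. Interpretations the source leaves open: "1-connected" is
read as 4-connectivity everywhere; SDs include zero pixels (only the mode
excludes them); Scharr output is the gradient magnitude; a constant image
rescales to all zeros; the low-intensity strip uses `mode − 0.5 SD`
(a plus sign would duplicate the threshold already applied); multiple
nuclei in one cell produce multiple labels. Per-object morphology runs on
padded bounding boxes, which is exact because the pad exceeds the dilation
reach.

The synthetic micrograph generator places non-overlapping elliptical cells
(one centered circular nucleus each, 16-bit channels, additive clipped
Gaussian noise) and records exact rasterized areas. It emulates the
geometry and intensity structure of the assay, not its texture: real
phalloidin images have filamentous actin, intensity falloff and touching
cells, so the ≤10%-error benchmark demonstrates the algorithm's
correctness of implementation, not its field accuracy. Benchmarks use 30
images of 1536×1536 px with 10–40 cells (areas 2,000–20,000 px), two per
image straddling the border to exercise border removal.

## Numerical and degenerate-input conventions

All generators are pure functions of spec + seed (byte-identical reruns);
the forest is seeded and single-threaded; k-means restarts are seeded.
Degenerate inputs raise typed errors: all-identical residuals
(`DegeneratePlateError`), coincident control means, single-class labels,
all-zero image channels, unpackable image specs, sub-2×2 plates, fewer
than 4 distinct concentrations. The 4PL standard error of EC50 is
propagated from the log10-EC50 covariance by the delta method.

## Known limitations

- Median polish at 10 sweeps is approximately, not exactly, equivariant to
  row/column offsets; B-score differences are below 0.01 units in tests.
- The MCS deduplication count depends on the canonical-fragment rule and
  minimum size; different rules give different "unique pattern" totals on
  the same hit list.
- The fragment grammar cannot represent stereochemistry, charge states or
  tautomers; enrichment and ML benchmarks therefore never exercise them.
- CSA is reported in pixels; no micron calibration is attempted.
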