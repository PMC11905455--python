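# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Study design assumed by the pipeline

Each disease group (AD, CBD, PiD, PSP by default) contributes one pooled
AT8-pulldown sample and one antibody-omission control sample per case;
cases within a disease are the replicate set. All association scoring is
per disease against that disease's own controls — cross-disease
specificity is deliberately not used, because the experimental design
pairs every pulldown with its own omission control.

## MiST scoring

Samples are composition-normalized first (each column's present values sum
to 1), which makes every downstream metric invariant to per-run scaling.
Missing values are treated as zero signal for metric computation — the
standard AP-MS convention that absence of evidence is no signal.

* **Reproducibility** R = −Σ pⱼ ln pⱼ / ln n over the n pulldown replicate
  shares pⱼ of the protein; R = 0 when the protein is absent or seen in at
  most one replicate, R = 1 for perfectly even detection.
* **Abundance** A is the mean normalized quantity over pulldown
  replicates, rescaled by the per-disease maximum so A ∈ [0,1] within each
  scoring context (a global maximum would let one disease's dynamic range
  leak into another's scores).
* **Specificity** S = A_pull/(A_pull + A_ctrl) on the raw (unrescaled)
  means; S = 0 when both are zero, S = 1 when the protein never appears in
  controls.

The composite is a convex combination. Two modes are exposed because the
original tool supports both and the choice is not derivable from the data
schema: fixed weights, defaulting to the published MiST training weights
(w_R, w_A, w_S) = (0.30, 0.08, 0.62), and a PCA mode that min-max scales
the metric matrix, takes the first principal component, orients it so the
specificity loading is non-negative (ties broken toward equal weights),
and uses normalized absolute loadings as weights. A zero-variance metric
matrix falls back to fixed weights with a warning. The association cutoff
is 0.75 and the comparison is inclusive (score ≥ 0.75 passes).

## Differential association

Run on pulldown samples only, across all pairwise disease contrasts, each
BH-adjusted separately (matching per-comparison significance reporting).

* **Filtering**: a protein is kept when present in every replicate of at
  least one disease (the fraction is configurable).
* **Normalization**: log2 followed by per-sample median centering
  computed on the rows present in every sample. This replaces a
  variance-stabilizing affine-arcsinh fit: that transform's maximum-
  likelihood internals are not parameterizable from the outside, median
  centering is transparent, and the normalization step is pluggable.
* **Imputation**: missing entries are drawn from
  Normal(mean_s − 1.8·sd_s, (0.3·sd_s)²) per sample — the left-censoring
  convention that missing label-free values sit near the detection limit.
  Seeded; imputation-dependent results are reproducible only conditional
  on the seed, which is why the seed is a first-class parameter.
* **Moderated t**: per-protein pooled variances s_g² with d_g df; the
  prior (d₀, s₀²) is estimated by matching moments of log s_g² via
  digamma/trigamma inversion, the posterior variance is
  (d₀s₀² + d_g s_g²)/(d₀ + d_g), and p-values use d₀ + d_g df capped at
  the pooled df. When the observed spread of log variances is no larger
  than chi-square sampling noise the prior df is infinite and s₀² is the
  pooled mean variance. The implementation agrees with Bioconductor
  limma's eBayes to ~1e-13 on identical input (asserted in the test suite
  when Rscript/limma is available, with a closed-form fallback oracle).
  `prior_df=inf` can be forced, giving the common-variance z test exactly.
* No fold-change cutoff is applied by default; significance is
  adjusted p < 0.05.

## Overlap significance and ORA

The overlap p-value is P(X ≥ x) for X hypergeometric with the two set
sizes and the universe. Every term
C(nA,i)·C(N−nA,nB−i)/C(N,nB) is evaluated as log-gamma sums and the tail
is accumulated with log-sum-exp, so log10 p is exact even when p
underflows double precision by hundreds of orders of magnitude — overlap
significances around 10^−570 occur in practice for tau-interactome
concordance checks. The default universe is 20,607 (the size of the human
search database used to generate such tables); callers should override it
when their universe differs, and recomputed extreme p-values should be
read as order-of-magnitude checks because the universe behind any
published number may differ. ORA filters terms to [10, 500] universe
genes before testing and BH-adjusts over tested terms.

## Lesion co-localization

Coordinates are 0-based row/col; areas convert via pixel_size_um². The
threshold method is Otsu per channel by default with a `fixed:<v>`
override, because reference workflows rarely record the algorithm;
provenance (method, value, background subtraction) is stored on every
mask. Background subtraction is a white top-hat with a disk of the
requested radius — the morphological analogue of rolling-ball subtraction;
the two differ slightly on sloped backgrounds, which is accepted and
documented here.

Neuropil threads are detected on the AT8 binary mask after removing the
pixels of all manually drawn ROIs (pixel-wise: a thread touching a manual
ROI loses only the overlapping pixels). 8-connected components are kept
when area ≥ 0.01 µm² and fitted-ellipse major/minor axis ratio > 3. Two
notes: at typical 20× sampling (~0.3 µm/px) the area bound is below one
pixel, so it effectively removes nothing — it is kept as the published
default; and the aspect ratio is computed from second-order central
moments with the +1/12 pixel-extent correction, so a single pixel has
aspect 1 (as in standard particle-analysis tools) rather than a degenerate
zero minor axis — without that correction, single-pixel noise specks pass
the filter.

Each lesion is scored as proportion = |overlap ∩ ROI| / |AT8 ∩ ROI| and
classified strong (≥ 0.70), moderate ([0.50, 0.70)), weak ([0.20, 0.50)),
negative (< 0.20). The interior boundaries are half-open; the published
wording fixes "≥ 70%" and "< 20%" explicitly and the two interior
boundaries are resolved to match. An ROI with no AT8-positive pixels
cannot be scored and is skipped with a log entry.

DAB burden: per-channel optical density OD = −log10((I+1)/256), unmixed
with the inverse Ruifrok–Johnston H-DAB stain matrix; tissue is total
OD ≥ 0.10 and burden is the percentage of tissue pixels with DAB density
above 0.15 (both configurable).

## Comparative statistics

Freeman–Halton 2×k exact tests enumerate all tables with the observed
margins (with margin pruning; candidate count bounded by Π(colsum+1)) and
sum the probabilities of tables no more probable than the observed one,
with a 1e-12 relative tie tolerance; above two million candidate tables a
seeded Monte-Carlo estimate over the conditional (Patefield) distribution
is used instead. Bonferroni multiplies by the number of tested pairs.
Dunn's post hoc uses mean-rank z statistics with the Σ(t³−t) tie
correction and Bonferroni by default (chosen for consistency with the
Fisher tests, since no adjustment is standard). Spearman's p uses the
t approximation (adequate at the sample sizes involved); full-enumeration
permutation p is available for n ≤ 9. Lesions are pooled across cases by
default; a per-case stratified analysis can be run by grouping the
per-lesion table before testing.

## Synthetic generators

The generators define the test conditions; their defaults are fixed.

* **Proteomics**: per-protein baseline log2 intensity ~ Normal(20, 2),
  replicate noise Normal(0, 0.5) (a field-typical ~0.5 log2-unit
  replicate CV; the parameter exists because every calibration statement
  about the pipeline needs a within-protein noise scale), associated
  proteins gain log2fc = 3 in pulldowns (5% shared + 2% per disease
  specific), and entries go missing with probability
  sigmoid(−1.2·(log2 I − 16.5)) — intensity-dependent (MNAR) dropout
  giving ~9% overall missingness, typical of DIA protein tables. What it
  does not emulate: correlated protein modules, batch effects, peptide-
  level roll-up artifacts, contaminants. Passing tests therefore
  demonstrate correctness of the scoring machinery under a clean MNAR
  log-normal model, not performance on real tissue data.
* **Histology**: binary-painted lesions at intensity 200 on a zero
  background, optional Gaussian noise. Blobs are disks, threads are
  drifting random walks (40 steps) dilated to ~3 px width and regenerated
  until the fitted-ellipse aspect ratio exceeds 3 (cap 50 attempts),
  coronas are annuli of Gaussian puncta with a filled-annulus ROI
  mirroring manual astrocytic-plaque outlines. The candidate channel is
  painted on a seeded random subset of exactly round(f·N) of each
  lesion's N AT8-positive pixels, so ground-truth overlap is controlled
  to pixel resolution before noise. Not emulated: point-spread blur,
  z-stacks, autofluorescence, spectral bleed-through.
* **Brightfield**: hematoxylin OD 0.5 everywhere, DAB OD 0.8 on a random
  disk mask trimmed pixel-wise to the exact target fraction;
  I = 256·10^(−OD) − 1, the exact inverse of the measurement transform,
  so noiseless round-trips are exact up to uint8 quantization.

## Problem sizes and tolerances

Calibration statements are made over 20 seeds at 1000 proteins (scoring
and differential stages) and 50 scenes at 512×512 (imaging stage) — sizes
at which the Monte-Carlo standard error is comfortably below the asserted
margins. Closed-form checks use absolute tolerances of 1e-6 or tighter;
enumeration oracles are matched to 1e-9 relative.

## Known limitations

* The differential stage is not a bit-for-bit DEP reproduction (different
  normalization internals, seeded imputation); published counts that
  depend on imputation randomness can be reproduced only in
  distribution.
* Extreme overlap p-values depend on the chosen universe; only the order
  of magnitude is meaningful across tools.
* Polygon ROI import is not supported — ROIs enter as integer label masks
  plus a label→type table.
* The thread detector assumes threads are resolvable as separate
  8-connected components; merged or crossing threads are detected as one.
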