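# Methods

This note documents the models, parameter choices and numerical conventions
behind `barcodeood`, and what the synthetic experiments can and cannot say
about real barcode data.

## Synthetic genus communities

The generator produces one genus-level dataset per call, built in four
stages, each driven by an independent child stream of a single root seed
(streams are derived from `(seed, stage-name, ...)` key tuples, so any stage
reproduces in isolation and adding stages never shifts existing draws).

1. **Species tree.** A pure-birth (Yule) tree: exponential waiting times at
   rate 1 per extant lineage, a uniformly chosen lineage splitting at each
   event, and one final waiting period after the last split so terminal
   branches are strictly positive. The tree is rescaled so every
   root-to-tip path equals `tree_height` (expected substitutions/site).
   Between-species divergence of a pair is the path length between their
   tips; `star_tree(n, h)` is provided for experiments that need a
   guaranteed minimum divergence of `2h` between every pair.
2. **Species consensus sequences.** A uniform-random root sequence evolves
   along each branch under the Kimura 2-parameter process
   (transition:transversion rate ratio `kappa`, default 2), with per-site
   relative rates from a profile. The default `"codon3"` profile repeats
   (0.3, 0.1, 2.6) across codon positions — mean rate 1, third positions
   fast — mimicking the rate heterogeneity of a protein-coding
   mitochondrial marker; `"uniform"` and explicit vectors are accepted.
   Branch substitution probabilities use the exact K2P transition
   probabilities, so the distance module recovers branch lengths
   asymptotically (verified at L = 10,000 within 3 binomial SE).
3. **Individuals.** Each species' individuals are the consensus plus
   N ~ Poisson(`target_dw` · L / 2) substitutions at profile-weighted
   sites (a star genealogy), so the expected within-species pairwise
   distance is `target_dw`. No public model of real within-genus
   genealogies was being imitated here; the star shape is the simplest
   process with a controllable within-species distance.
4. **Abundances and partition.** Species sample counts are negative
   binomial (mean `mean_samples_per_species`, dispersion
   `abundance_dispersion`) truncated at 1. Species with >= 15 samples are
   in-distribution (ID); the rest are the OOD fraction. The defaults
   (mean 20, dispersion 1.9) put ~17% of samples into OOD species under
   the 15-sample bar and the 125-sample cap. A single negative binomial
   cannot simultaneously deliver that OOD share *and* a realized mean of
   ~45 samples/species — real surveys reach the latter partly through
   abundant but unconventionally labeled species counted as OOD, a
   mechanism outside this rare-species-only generator — so the defaults
   favor the OOD share, which is the quantity the detection experiments
   depend on.

**Collisions.** `inject_collisions` copies ID sequences into a chosen
fraction of OOD species (every individual of a selected species becomes a
copy of one ID individual) or, with `unit="sample"`, into individual OOD
records, which gives exact sample-level control of the zero-distance
proportion. With `target_dw = 0` the collision fraction equals the FNR
floor exactly, which is how the bound logic is tested.

**What the generator does not emulate:** indels and alignment error,
ambiguity codes, pseudogenes, selection, within-species population
structure, geographic signal, and label noise. Passing results therefore
demonstrate the correctness and calibration of the *methods* under a
clean substitution model, not their field performance on real BOLD-style
data, where shared haplotypes across species and messy labels push all
error rates up.

## Data preparation

Fragments outside (400, 1000) ungapped bp are dropped (strict bounds).
Species above 125 records are subsampled to 125. Fragment windows are
0-based half-open intervals on the alignment — (350, 650) for the 300-bp
fragment, (350, 500) for 150 bp — which is the only reading under which
the stated window coordinates and lengths agree. "Small" databases halve
every species (ceil), keeping at least 5 records per ID species and 1 per
OOD species. The ID data are split 70/30 per species
(`round(0.7n)`, at least one record on each side).

Sequencing noise is applied to test material only — reference databases
are assumed clean. Two modes exist: `exact` replaces exactly
`round(rate·L)` distinct canonical positions per fragment (13/6/3 changes
at 650/300/150 bp and 2%), each with one of the three alternative bases;
`bernoulli` hits every canonical position independently with probability
`rate`. The experiment driver uses `bernoulli` at test time. The reason
is substantive: under a multiple-hit-corrected distance, adding a fixed
amount of random substitution noise shifts the calibration quantiles and
the OOD query distances by the same expected constant (substitution
processes compose additively in the distance estimate), so exact-count
noise provably leaves distance-based FNR unchanged on average. Real
sequencing error varies per read; it is that per-fragment variance —
which the 95% calibration quantile amplifies but the typical OOD shift
does not track — that degrades OOD detection. Bernoulli noise carries
that variance; exact-count noise deliberately removes it.

One-hot encoding maps A/T/G/C to the four columns in that order; any other
letter (ambiguity codes, gaps) becomes an all-zero row and is excluded
from distance site counts (pairwise deletion, with at least 50% joint
coverage required for a defined distance).

## Distances and distance-based detection

K2P: `d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)` with P and Q the transition and
transversion proportions over jointly canonical sites; saturated pairs
(non-positive log argument) are flagged +inf, under-overlapping pairs NaN.
The matrix path computes P/Q via one-hot indicator matmuls (integer counts,
exact in float32) and agrees with per-pair site counting to 1e-12.

Percent identity: best local alignment under match +1, mismatch -2, gap
open -5, gap extend -2 (blastn-like; a gap of length k costs 5 + 2k),
identity = matches / alignment columns. Implemented as an affine-gap
Smith-Waterman with traceback, compiled with numba; verified against an
exhaustive pure-Python dynamic program. The distance used for
classification is `(100 - identity)/100`.

Identification is 1NN with ties broken toward the smallest sample id.
OOD thresholds per species are the 95% (type-7) quantile of within-species
minimum distances; a query is rejected when its nearest-neighbor distance
strictly exceeds the cutoff of the nearest neighbor's species — queries at
the cutoff are accepted. Two calibration sources are available:
leave-one-out minima among the training references
(`distance_thresholds`), and minima of held-out ID samples against their
conspecific references (`query_calibrated_thresholds`). The experiment
driver uses the latter, matching the score-based detectors (thresholds
come from the same, possibly noisy, ID test material the detector will
face) and reproducing the noise sensitivity described above; the
training-only variant remains for leakage-free deployment settings.

## Zero-distance bounds

`fnr_lower` is the fraction of OOD samples sequence-identical to at least
one ID sample: no sequence-based detector can flag them, and the bound is
exactly non-decreasing under window truncation (truncation preserves
equality). `accuracy_upper` is 1 minus the fraction of ID test samples
sequence-identical to a heterospecific training reference. By default any
such match counts as a forced error even when a conspecific reference also
matches; that convention makes the ceiling exactly non-increasing under
truncation. The laxer reading — an oracle may resolve ties toward the
true class — is available (`ties="identifiable"`, or `"half"`), but is
not monotone: truncation can merge a test sample with a conspecific
reference and rescue it from the error set, which breaks the exactness of
the truncation analysis.

## The CNN

Implemented directly in NumPy (forward and backward passes, Adam), which
keeps the package dependency-light and exposes exactly the gradients the
attribution module needs. Architecture: three blocks of [1D convolution
(stride 1, same padding) -> batch normalization -> size-2 max pooling ->
ReLU -> dropout 0.15] with 64/128/128 channels; global average pooling to
a 128-vector; fully connected 128 -> 64 -> n_classes with ReLU and dropout
0.25 between. Inputs are right-padded with zero rows to a multiple of 8 so
the three pooling stages divide evenly. The kernel size defaults to 3,
which places the trainable parameter count at ~1.0e5 for a typical genus
(15 classes), the scale of the published architecture; kernel size and FC
widths are configurable. The penultimate representation used for
Mahalanobis scoring is the 64-unit ReLU layer feeding the final
classifier.

Training: Adam (lr 1e-3, batch 16) on cross-entropy, with early stopping
when the best epoch loss has not improved by 1e-4 for 10 epochs (an
automated stand-in for visual convergence assessment), capped at 200
epochs. Experiments at test scale pass smaller epoch caps; the separable
fixtures converge in ~10 epochs. Inference runs batch norm on running
statistics and disables dropout, so predictions, features and attribution
tracks are deterministic. Backpropagation is verified against finite
differences layer-by-layer and end-to-end.

## OOD scores and calibration

All scores are oriented so that larger means more OOD-like: `-MSP`, the
energy `E(x) = -T log Σ exp(f_k/T)` with T = 1, and the minimum squared
Mahalanobis distance of the penultimate feature vector to class centers
under a tied covariance (pooled within-class scatter / (n - K), plus
`1e-3 · trace/d` on the diagonal for invertibility with small classes).
Published formula details for the energy and Mahalanobis variants used in
the original study live in supplementary material that is not public; the
forms here follow the originally cited definitions, and the squared vs.
unsquared choice and feature preprocessing are exposed as options.

Class cutoffs are the 95% (type-7) quantile of oriented scores of held-out
ID samples grouped by true class; classes with fewer than 5 calibration
samples are flagged low-confidence. At test time the cutoff of the
predicted class applies (nearest-center class for Mahalanobis), with
strict exceedance required for rejection. By construction the
calibration-set FPR is ~5%, exact when scores are distinct and class sizes
are multiples of 20. The ensemble is a majority vote of the three flag
sets and has no threshold of its own.

## Attribution

Grad-CAM: the predicted-class (or a chosen class) logit is backpropagated
to the last convolutional block's feature maps; channel weights are the
position-averaged gradients; the rectified weighted sum is linearly
interpolated from L/8 back to L and max-normalized per sample.
Grad-energy substitutes the energy score as the backpropagated scalar and
needs no target class; it shares the rectification and normalization
conventions (documented choices — the original's normalization is in
non-public supplementary material). Figure-style summaries average
normalized tracks over a sample set, summarize them in non-overlapping
8-bp windows, and compare against per-16-bp-window nucleotide diversity
(mean pairwise mismatch per site, pairwise deletion); 8-bp score windows
are averaged onto the 16-bp grid before the Pearson correlation, which is
reported as missing when either vector is constant.

## Experiment driver and regressions

A replicate prepares the windowed data, optionally halves it ("Small"),
splits 70/30, computes the zero-distance bounds on the clean windowed
split (noise would make "zero distance" ill-defined), injects noise into
the test/OOD material only, trains/indexes on the clean training split,
calibrates thresholds on the ID test scores, and measures accuracy,
FNR@95% and FPR. Within a (dataset, database size, length, replicate)
cell the CNN is trained once and shared across noise levels and the four
CNN-based detectors; seeds derive from the cell key, so `run_replicate`
and `run_grid` produce identical rows. The "Small" halving is applied
before the 70/30 split, so the 5-records floor binds on what enters
training.

Factor effects are OLS with dummy coding against reference levels 650 bp /
Sufficient / no noise / dist_k2p; p-values are reported raw with a
Holm-adjusted column. Determinant selection is LASSO on standardized
predictors with lambda from 10-fold cross-validation under the 1-SE rule
(the largest penalty within one standard error of the minimum CV error);
coefficients are reported back on the original scale and dropped variables
as zeros. With only a couple dozen genera the CV folds are tiny and the
1-SE band very wide, so the conservative rule may retain nothing; the
lambda-min solution (`rule="min"`) is available and reported alongside it
in the shipped analysis. Genus datasets are weighted equally. The accuracy-FNR
correlation is Pearson's r over per-dataset means with a seeded
permutation p-value (10,000 permutations).

## Problem sizes

The default study design (20 replicates, 20 genera) is configurable; the
shipped test suite uses 1-3 replicates, genera of 6-22 species and 10-20
training epochs, and `scripts/acceptance.py` evaluates 3 genera on the
full factor grid (30-epoch CNN training, which these genus sizes need to
converge at 650 bp) plus a 24-genus distance-only sweep for the
determinant regressions. Sizes were chosen so a complete run stays
desk-scale on one CPU while every qualitative conclusion (accuracy/FNR
levels and orderings, noise and truncation directions, bound exactness,
selection consistency) is measured with enough samples to be stable under
the fixed seeds.

## Known limitations

- The synthetic communities are clean by construction; absolute error
  rates are optimistic relative to real survey data.
- The local-alignment identity metric is O(L²) per pair; full grids at
  650 bp are slow, so shipped experiments evaluate it at shorter windows.
- Single-replicate FNR estimates at 150 bp are noisy (small per-class
  calibration sets make the 95% quantile jumpy); directional analyses
  average 2+ replicates per genus.
- Energy/Mahalanobis formula details and Grad-CAM normalization follow the
  cited original definitions where the study's own supplementary
  specification is unavailable; all such choices are configurable and
  documented above.
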