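# Methods

`mifquant` implements a quantitative workflow for multiplexed
immunofluorescence (mIF) images of immune-infiltrated tissue: benchmark a
nuclei instance segmentation, align cyclic staining rounds, call
per-nucleus marker positivity, and compose the calls into hierarchical
immune phenotypes — here the conventional type 1 dendritic cell (cDC1)
panel: identity (CD11c, HLA-DR, BDCA-3), checkpoint state (CD40, PD-L1),
and function (IL-12, CD86, IDO).  Because clinical mIF images are rarely
shareable, the package includes a synthetic field generator with complete
per-cell ground truth; every downstream stage is validated against it.

## Synthetic fields

A field is drawn in two steps.

**Phenotypes.** Each of `n` cells is assigned a phenotype from a
hierarchical mixture (`PhenotypeMixture`): cDC1 with probability
`frac_cdc1` (default 0.17, an immune-rich disease-free-like field); given
cDC1, one of the four CD40/PD-L1 subsets from `p_cd40_pdl1` (default
0.20 / 0.25 / 0.325 / 0.225, with CD40−PD-L1+ the largest subset); given
the subset, one of the eight IL-12 × CD86 × IDO combinations from
`p_func`.  cDC1s are positive for all three identity markers; non-cDC1
cells may carry single identity markers off-target (defaults: CD11c 15%,
HLA-DR 20%, BDCA-3 3%, modelling other myeloid and MHC-II+ cells) but
essentially never all three, so the triple-positive gate is exercised but
not contaminated (expected contamination ≈ 0.1 percentage points).  A
`metastatic()` preset lowers `frac_cdc1` to 0.06 and biases function
toward IDO.

**Rendering.** Nuclei are convex ellipses with truncated-normal radii
(mean 7 px, sd 1.5, clipped to [3.5, 11]) placed uniformly by rejection
sampling; centers may approach 0.8× the sum of radii, so nuclei touch and
overlap mildly, with later placement winning contested pixels — this
deliberately exercises instance separation.  The nuclear channel renders
nucleus interiors (log-normal amplitude around 180).  Marker channels are
perinuclear rings (membrane/cytoplasmic stains do not fill the nucleus):
each cell's ring is the nearest-nucleus expansion of its label by the ring
width (default 2 px).  Marker amplitudes follow a two-mode log-normal law —
median 25 for negative cells, 250 for positive, log-sd 0.35, i.e. a 10×
separation of roughly 4.6 log-sd.  Only marker-*positive* cells deposit
specific ring signal; a marker that is off everywhere yields an
identically-zero clean channel, with nonspecific intensity carried
entirely by the additive background (default 8) and Gaussian read noise
(sd 3, clipped at 0).  The low amplitude mode remains in the truth table
as the modelled residual intensity of negative cells.

A second staining round is derived from the same scene by resampling the
noise-free channels under a known rigid transform and adding fresh noise,
emulating imperfect re-localisation of the field between imaging days.

All randomness threads from one integer seed through a fixed
`numpy.random.SeedSequence` spawn order (phenotype draws, then geometry,
then per-channel noise); equal seeds give bit-identical scenes.

**What the generator does not emulate:** illumination gradients and
vignetting, spectral spillover between channels, autofluorescence texture,
non-convex or lobed nuclei, spatial clustering of phenotypes (placement is
uniform), and staining-round-specific degradation.  Tests passing on these
fields therefore demonstrate correctness of the *computational* chain
under its stated noise model, not robustness to every real-world artefact.

**Dataset utilities.** `split_dataset` partitions items into
train/validation/test by counts (e.g. 12 images → 8/2/2) or ratios.
`augment_dataset(pairs, factor=k)` expands a training set k-fold using
axis-preserving geometry (90° rotations and axis flips, applied jointly to
image and mask so integer labels survive exactly) plus multiplicative
intensity jitter on the image only; `factor=0` means no augmentation and
returns the originals — so factor 5 turns 8 pairs into 40.

## Registration

Rounds are aligned with a 2D rigid model (`RigidTransform`: rotation about
the field center plus translation; exact inverse and composition).  The
estimator assumes approximate prealignment (defaults: |shift| ≤ 10 px,
|rotation| ≤ 5°) and is deterministic: a coarse 1° rotation grid is
refined to 0.1° and then 0.02°; at each candidate angle the translation is
solved by subpixel phase cross-correlation of the nuclear channels, and
candidates are scored by normalised cross-correlation (NCC) over the
interior (a margin of the search radius is excluded).  NCC is invariant to
global intensity scaling, so photobleaching between rounds does not bias
the estimate.  The score is reported as a quality value in [−1, 1]; below
a configurable floor (default 0.2 — a package choice, no community
standard exists) the result is flagged low-quality rather than rejected.
Resampling is bilinear; pixels mapped from outside the field are flagged
in a validity mask, never extrapolated.  On synthetic two-round scenes the
estimator recovers transforms within 0.5 px and 0.25°.

## Segmentation and its evaluation

Deep-learning segmenters are out of scope; their label masks enter through
`import_external_labels`.  The in-repo baseline — Gaussian smoothing, Otsu
threshold, marker-controlled watershed on the distance transform with
seeds merged below a minimum separation, minimum area 30 px, consecutive
relabelling — exists so the full pipeline runs end to end on a laptop; on
default synthetic scenes it reaches AP ≈ 0.85–0.91 at T = 0.5.

Evaluation follows the standard detection framework.  Candidate
(ground-truth, prediction) pairs are those with nonzero pixel overlap,
scored by IoU = |∩|/|∪|.  At threshold T, matches require IoU strictly
greater than T (a tie at exactly T is a non-match).  Two matching policies
are implemented: `one_to_one` (default) matches greedily by descending IoU
with each instance used at most once (ties broken by lower ground-truth,
then prediction id); `literal` counts a prediction as TP whenever *some*
ground-truth mask exceeds T, which can validate several predictions
against one ground-truth cell.  The policies agree whenever the overlap
graph above threshold is a partial matching; both are exposed so the
discrepancy can be reported when it is nonzero.  From TP/FP/FN:
precision = TP/(TP+FP), recall = TP/(TP+FN),
average precision = TP/(TP+FN+FP) (the three-count summary, not the area
under a PR curve), F1 = harmonic mean of precision and recall.  Any 0/0
is defined as 0 with a warning.  Multi-image evaluation pools counts
before computing metrics (micro) and also retains per-image curves for a
macro mean, since either convention is defensible.  The implementation is
tested for exact agreement with an independent brute-force pixel-set
implementation on hundreds of random mask pairs.

## Marker classification

Cell signal is measured over the nucleus plus a perinuclear ring: the ring
is the morphological expansion of the nucleus by `ring_width` (default
3 px — a package choice), with contested pixels assigned to the nearer
nucleus.  Features per marker: nucleus mean, ring mean, mean over the
union (the per-cell MFI), and the fraction of union pixels above a
reference intensity recorded at extraction time.

Two classification routes:

* **Thresholding** calls a cell positive when at least `pixel_fraction` of
  its pixels exceed the reference intensity.  The default fraction is 0.2:
  with ring-borne signal the ring is only ~30–40% of the nucleus ∪ ring
  support, so a positive cell's attainable fraction tops out well below
  one-half, and 0.2 sits cleanly between the positive plateau and the
  near-zero fraction of negative cells at a mid-mode reference.
* **Few-shot logistic regression** mimics interactive annotation: the
  analyst supplies a handful (typically 5–10) of positive and negative
  exemplar nuclei; a ridge-penalised logistic regression (C = 1) on the
  three features, standardised on the exemplars, classifies the rest.
  The ridge keeps the fit stable in the few-exemplar regime; the fit is
  deterministic.  Exemplars always retain their annotated class, and a
  `refine_classifier` step folds analyst corrections back into the
  exemplar set and refits, modelling the interactive revise loop
  non-interactively.  Exemplars come from a CSV or are drawn from the
  synthetic ground truth.

Classifier quality is summarised as distance-to-truth: the absolute
difference between predicted and true population percentages over all
nucleated cells, in percentage points — the natural error measure when the
deliverable is a population abundance.

## Phenotyping

A `GatingSchema` names populations as conjunctions of marker calls under a
parent hierarchy; the default tree is cDC1 = CD11c+ HLA-DR+ BDCA-3+, the
four CD40/PD-L1 subsets beneath it, and the eight IL-12/CD86/IDO
combinations beneath each subset.  Gating is a pure function of the calls
(idempotent, order-independent).  Abundances are percentages of all
nucleated cells in the field; subset fractions are percentages of their
parent and must partition it (an empty parent yields an explicitly flagged
undefined result, never silent zeros or NaN).  Per-patient values should
be means over that patient's fields before any group statistics.

Per-cell MFI is normalised by a per-image background constant — the median
intensity outside all nuclei and rings — and reported on a log10 scale;
this removes per-image illumination scale while keeping units arbitrary.
High/low expressers are split at an Otsu cutpoint on the *pooled* log10
MFI of all compared groups (pooling keeps one uniform cutpoint; a pooled
median is available as a fallback), and the cutpoint is always reported.
Identical values are flagged degenerate and assigned low.

`emulate_visual_scoring` reproduces the manual counting convention of
estimating a population from a fixed sample (conventionally 100 cells per
field): it draws without replacement and reports the sample percentage.
It is unbiased but substantially noisier than the full census, which the
tests demonstrate directly.

## Statistics

Three-group comparisons (e.g. non-tumor skin vs metastatic vs disease-free
patients) use one-way ANOVA for the overall effect plus Tukey HSD for all
pairwise comparisons; the pairwise tests are not gated on the ANOVA (which
would make the familywise error conservative), and Bonferroni-adjusted
t-tests are available as an option.  Two-group comparisons use a
two-sided Student's t-test (equal-variance by default, Welch optional).
Significance stars use the conventional strict thresholds * p < 0.05,
** p < 0.01, *** p < 0.001, **** p < 0.0001.  Under a simulated null the
any-pair rejection rate of the three-group procedure is calibrated at the
nominal 5% within binomial error.

## Numerical choices and problem sizes

Default test and validation scenes use 250-cell fields of 360 × 360 px
(registration scenes: 120 cells, 256 × 256), pooling 20 replicate fields
(5,000 cells) for mixture-recovery checks; the package defaults for a
production field are 1,600 cells on 1,024 × 1,024 px, matching a densely
infiltrated tissue field.  Watershed flooding ties resolve by lower label
id; greedy matching ties by lower id; all RNG flows through
`numpy.random.default_rng` seeded per run.  Label TIFFs are written as
unsigned 32-bit for headroom beyond 65k instances.  Coordinates are
0-based, row-major; transforms act on (x, y) = (column, row) points.

## Known limitations

The baseline segmenter under-splits heavily overlapping nuclei and is not
a substitute for trained instance segmenters; registration is strictly
rigid (no affine or deformable component) and assumes the rotation lies
within the search window; MFI normalisation assumes background pixels
dominate the area outside cells; the statistics module implements only the
normal-theory tests above (no nonparametric or mixed-effects options); and
the generator's simplifications listed earlier bound what synthetic
validation can claim about real tissue.
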