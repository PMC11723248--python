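# Methods

## The problem

Extrusion bioprinting trials are expensive, and the literature reporting
them is heterogeneous: different hydrogels, different printers, different
endpoint properties (uniformity factor, expansion ratio, porosity,
rheological moduli, ...), each on its own scale. This package implements
an information-fusion + perturbation-theory machine-learning (IFPTML)
pipeline that merges such heterogeneous assays into one binary
*printability* outcome and learns a single multi-property classifier
from monomer molecular descriptors and assay conditions.

## Information fusion and discretization

Each assay is one measurement `v_ij` of a property `c0` under conditions
`c1..c9` (extrusion pressure kPa, speed mm/s, nozzle gauge, inner
diameter um, layers, three temperatures degC, ethanol flag). A print is
*good* (`f_obs = 1`) when `v_ij` lies inside the property's acceptance
interval `[lim_inf, lim_sup]`, inclusive on both sides, and *poor* (0)
otherwise. The two-sided rule is the operative one: curated cut-off
tables carry both limits, and case-study expansion values are classed
poor for falling *below* range. When no curated interval exists,
`derive_cutoff_range` scans symmetric half-widths around the desired (or
mean) value — by default 50 evenly spaced widths up to the data
half-range — and keeps the interval whose good/poor tally is most
balanced (`min |n1 - n0|`, both classes non-empty, ties to the narrower
interval). Asymmetric curated intervals are stored verbatim, including
printed anomalies (an average outside its own limits); we deliberately
do not reconcile them. One unit rule exists: porosity below 1 is read as
a fraction and converted to percent before comparison.

## Perturbation featurization

For an ink of one or two monomers, descriptor vectors are mixed by
normalized concentration weights, `D_k(ink) = sum_c w_c D_k(monomer_c)`,
which makes mixing permutation-invariant and insensitive to a common
concentration rescaling. Descriptors are then min-max scaled to [0, 1]
on the training rows (unseen values extrapolate without clipping;
constant descriptors map to 0 and are flagged). The model input for one
assay is

    [ f_ref , dD_k(c_j) for every descriptor k and condition j ]

where `dD_k(c_j) = D_ki − <D_k(c_j)>` is the deviation from the mean of
the scaled descriptor over training assays sharing the same value of
condition `c_j` (a Box–Jenkins moving-average-style operator), and
`f_ref = p(f=1 | c0)` is the empirical good-print prior of the measured
property. Scaling on raw descriptor magnitudes would make thresholds on
`dD` meaningless across descriptors; unit-interval scaling is what makes
split thresholds of order 0.01–0.5 interpretable.

Three conventions matter in practice:

- **Missing conditions are a group of their own.** The merged literature
  cannot guarantee complete condition records, and imputation would
  corrupt the conditional means. Missing is an explicit marker end to
  end.
- **Conditional means, the reference table and the scaling are fitted on
  the training partition only.** A condition value never seen in
  training falls back to the global descriptor mean (and the global
  positive rate for `f_ref`). A dedicated test asserts that fitting the
  means on all rows would produce a different validation matrix, i.e.
  that the pipeline cannot silently leak.
- **Continuous conditions group by exact value** (optionally binned via
  the `binning` parameter for sparse data).

The defining identity — every `dD_k(c_j)` column has mean zero within
every training group of `c_j`, to 1e-9 — is asserted as an invariant.

## Model families

All four families share the scikit-learn contract plus
`selected_features_` and probability-of-good `predict_proba`; class
labels threshold the probability at 0.5 (no threshold tuning anywhere).

- **LDA + RFE** (`LDARFEClassifier`): linear discriminant analysis with
  recursive feature elimination, dropping the smallest
  standardized-coefficient feature each round (block size configurable)
  down to 10 survivors; a 100-resample bootstrap records in-bag and
  out-of-bag Sn/Sp per iteration.
- **Decision tree** (`TreeClassifier`): at most 40 leaf nodes on the top
  15 features. Feature ranking averages impurity importance over the
  bootstrap-resampled preliminary trees rather than trusting a single
  fit: perturbation columns of one descriptor under different conditions
  are nearly collinear, and a single greedy tree attributes their shared
  importance to an arbitrary member of that group, which makes the
  condition attribution of the ranking unstable; bagging the ranking
  resolves it. 100 bootstrap iterations are then trained on the reduced
  columns and the iteration with the best validation balanced accuracy
  `(Sn + Sp)/2` is kept — both Sn and Sp are the headline metrics, so
  their mean is the natural "best result" criterion. Probabilities are
  leaf class fractions; `extract_tree_report` reads the top splits
  (feature, threshold, population share) for family-style analysis of
  the first tree levels.
- **MLPC** (`MLPCClassifier`): dense multi-layer perceptron; the
  100-100 hidden stack is the reference architecture family. An empty
  hidden list degrades, with a warning, to plain logistic regression.
- **Deep ANN** (`DeepANNClassifier`): dense ReLU stack 64-32-32-32
  (the shallower 64-32-32 variant is supported via the `hidden`
  parameter), sigmoid output, Adam optimizer, binary cross-entropy loss,
  trained for exactly `epochs` passes at the given batch size with early
  stopping disabled so the loss history length equals the epoch count.
  The supported tuning grid is epochs {100, 200, 500, 1000, 2000} x
  batch {32, 64, 128}, with 1000 x 32 the reference profile. The
  network is built on scikit-learn's `MLPClassifier`, whose log-loss
  objective is exactly binary cross-entropy for binary targets.

Evaluation reports sensitivity, specificity and accuracy as percentages
with the observed class sizes `n_j` as denominators, and rank-based
(Mann–Whitney, midrank-tied) AUROC. An empty denominator class yields an
explicit NaN, never a silent zero. One fixed stratified 70/30 split,
shared across families, is the default comparison protocol.

## Condition-grid prediction

`scan_conditions` sweeps two conditions (typically pressure x speed)
over value grids while pinning the others at a base setting (reference
base: 25 G nozzle, 254 um, 1 layer, 25 degC everywhere, no ethanol),
synthesizing one assay row per cell and per property; `c0` is set to the
property being scanned, which is how one model serves all endpoints.
Cells are pointwise `predict_proba` calls — no interpolation — and are
banded low (< 0.33) / medium / high (>= 0.66) for rendering; the band
thresholds are plain configuration, not model state.

## The synthetic corpus

The generator emulates the structure of the real merged database: 1568
assays, 10 hydrogels, 16 properties, ~20% binary inks, condition pools
drawn from reported settings (pressures {25, 30, 35, 48} kPa, speeds
{1, 7, 10, 25} mm/s, 254 um among the diameters), a good:poor balance
targeting 757:1568 positives, and a ~5% missing rate on two temperature
conditions. Outcomes come from the perturbation functional form itself:
a latent score sums three planted coefficients times true `dD_k(c_j)`
features (computed with the generated population's own conditional
means), plus Gaussian noise (scale 0.5), through a logistic link; the
intercept is solved by bisection so the expected positive fraction hits
the target exactly (with only 10 hydrogels the score distribution is
lumpy, and a closed-form intercept would let the balance drift by seed).
Measured values are then back-synthesized inside or outside each
property's generated acceptance interval so that re-fusing the corpus
reproduces the drawn outcomes exactly — asserted as a round-trip
invariant.

Two generator choices deserve justification:

- **Condition–hydrogel affinity (0.7).** Each hydrogel favours one value
  of each condition pool. Merged literature corpora behave exactly this
  way (each source study prints its own materials at its own settings),
  and the association is what makes the conditional means genuinely
  condition-dependent — without it, `dD_k(c_j)` is nearly identical for
  every `j` and recovering *which* condition a planted feature belongs
  to would be ill-posed for any method.
- **Planted effect sizes (16, −14, 12).** Calibrated so the planted
  linear score separates the synthetic classes about as well as the real
  corpus is separated by its fitted models (held-out Sn/Sp in the
  mid-80s). Weaker coefficients would emulate a noisier corpus than the
  one this pipeline was designed for.

What passing on this corpus shows: the pipeline recovers a signal
expressed in its own functional form, at realistic size, balance,
confounding and noise. What it does not show: performance under
descriptor families with real covariance structure, under model
misspecification (outcomes not generated by the perturbation form), or
on inks outside the training hydrogel set.

## Problem sizes used in the automated checks

The acceptance suite runs the full pipeline at the default corpus size
(1568 assays) across five generation seeds for the recovery check and
twenty for the null-signal guard; unit tests use 250–400-assay corpora,
which fit the same structure at a fraction of the cost. The stochastic
performance criterion (held-out Sn and Sp >= 80%) is evaluated on the
five-seed mean; feature recovery (>= 2/3 of planted features) is
required at every seed.

## Numerical choices and degenerate inputs

Inclusive interval boundaries; ties in the cut-off search break toward
the smaller half-width; constant descriptors scale to zero and are
flagged; min-max extrapolates rather than clips; single-class training
labels, all-identical cut-off values, zero total ink concentration and
unresolvable monomers all raise immediately with named offenders. All
stochastic elements (splits, bootstraps, iteration seeds, weight
initialization) descend from one seeded generator per run, and every
pipeline stage hashes its artifacts into a run manifest, so a replay
with the same config and seed is verifiably identical.

## Known limitations

Descriptor computation is out of scope: descriptor tables are consumed
as CSV from external calculators. The exact fitted trees/weights of any
particular published model are not reproducible without its training
split and seeds, so leaf-probability tables and split thresholds printed
elsewhere serve as structural references here, not as regression
targets. Cut-off ranges are global per property, never recalibrated per
study; outcomes are strictly binary.
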