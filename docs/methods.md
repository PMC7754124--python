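# Methods

## Scope and data model

The pipeline classifies liver tissue (HCC, MFCCC, non-tumour) from
2-minute positive-mode PESI-MS acquisitions of tissue homogenates,
recorded as full-scan continuum spectra over *m/z* 10–2000. An
`Acquisition` holds one sample's time-stamped scans on a shared *m/z*
grid; the pipeline reduces it to ten 10-second averaged
`FragmentSpectrum` objects, centroided `PeakList`s, and finally rows of a
TIC-normalized `FeatureMatrix` (fragments × aligned bins) carrying
sample/patient/label metadata. Labels form a closed three-value set;
the cohort field (which study arm a sample belongs to) is used only to
select task rows, never as a feature.

## Preprocessing

**Fragment split.** A scan at time *t* belongs to window
⌊*t*/10 s⌋; windows 0–11 are formed and windows 10–11 discarded, because
late-run needle contamination depresses and destabilizes the signal.
Fragments are arithmetic means of their scans; an empty kept window is an
error (it would silently change the 10-rows-per-sample geometry).

**Centroiding.** A grid point is a peak iff it is a strict local maximum
with intensity ≥ `noise_k` × MAD of the fragment (default 5) and
≥ `min_rel_intensity` × base peak (default 0.001). Peak *m/z* is refined
as the intensity-weighted centroid of the three grid points around the
apex. These thresholds are this package's choices; the vendor's
centroiding algorithm is not published. A flat or all-zero fragment
yields an empty peak list, not an error.

**Alignment.** All peaks of all fragments are pooled, sorted, and split
into bins wherever the gap between consecutive *m/z* values exceeds the
0.5 Da tolerance — i.e. single-linkage clustering cut at the tolerance,
which is deterministic and independent of sample order. Chained bins can
span more than the tolerance end to end; consecutive member gaps never
do. Multiple peaks of one fragment falling in a bin are summed (this
conserves TIC; max-pooling would not). Bin centroids are
intensity-weighted mean *m/z*.

**Normalization.** Each row is divided by its own sum after alignment
(i.e. on the picked, aligned peaks, not the raw continuum), making rows
compositional with sum 1 (tolerance 1e-9); the operation is idempotent
and scale-invariant. Zero-sum rows are an error naming the fragment.

## PLS-DA

NIPALS PLS2 on column-mean-centred X against mean-centred one-hot class
membership, X- and Y-deflation per component, inner tolerance 1e-10,
max 500 iterations, initialized from the maximal-variance Y column so the
fit is deterministic. The first weight vector equals the dominant left
singular vector of X'Y, which the tests check against an SVD oracle.
Mean-centring only (no unit-variance scaling): rows are compositions on
a common scale, and autoscaling would inflate near-empty bins. Two
components by default — what a score plot shows. PLS-DA is a separation
diagnostic here; classification uses SVM/RF.

## Classification and evaluation

Folds are assigned to **patients** (stratified by cohort and by the
label multiset the patient contributes, shuffled within stratum by a
seeded RNG, dealt round-robin with staggered starts), so all fragments
of a patient — tumour and paired non-tumour sample alike — share a fold.
Every cross-validation run re-asserts that train/test patient sets are
disjoint.

SVM: RBF kernel, C = 1, gamma = 1/(n_features · var), on per-feature
standardized inputs with standardization learned on training rows only.
RF: 500 trees, √p feature subsampling, seeded. The original study's
hyperparameters are unpublished, so these defaults are documented and
config-overridable; consequently the synthetic-recovery and
arithmetic-reconciliation results, not real-data accuracy matching, are
the package's validation surface.

Error taxonomy: false positive (true non-tumour → any tumour class),
false negative (true tumour → non-tumour), misclassified (HCC ↔ MFCCC,
3-class task only), concordant (exact match). Counts always sum to the
task total. Sensitivity = concordant tumour / all tumour; specificity =
concordant non-tumour / all non-tumour; 3-class summaries add per-class
recalls.

**Majority vote.** A sample is concordant iff ≥ ⌈n/2⌉ of its n fragments
are correct (5 of 10). The sample-level predicted label is the modal
fragment prediction; a modal tie is flagged and counted as an error on
the side of the true label (conservative). Note the edge case: a binary
sample with exactly 5 of 10 correct is *concordant* by the counting rule
yet has a tied modal label; it appears as concordant in the verdict and
as an error in the modal-label confusion. With 10 fragments this only
arises on exact 5–5 splits.

## Synthetic cohort generator

The generator emulates the study design (117 + 105 and 50 + 46 samples,
paired samples sharing a patient) and the acquisition geometry (120 s,
1 scan/s, *m/z* 10–2000 on a 0.1 Da grid). Expected apex intensity of
peak *j* at time *t* for class *c*:

    A_j(t) = exp(b_j + e_cj + u_p) · d(t) · ε,   ε ~ LogNormal(0, scan_sd²)

with base log-intensities b_j uniform on [log 10³, log 3·10⁴], patient
effect u_p ~ N(0, patient_sd²) shared by a patient's paired samples,
and d(t) = exp(−(t − t₀)/τ) after onset t₀ (defaults t₀ = 100 s,
τ = 10 s), so the discarded windows 10–11 are visibly degraded. Peaks
are Gaussian in *m/z* (σ = 0.15 Da) with ≥ 1 Da spacing, plus a
truncated Gaussian noise floor (σ = 5 counts). Multiplicative log-normal
effects were chosen because ion currents are positive and
heteroscedastic; no noise model is published for the instrument.

Defaults: 60 background peaks and 8 discriminative peaks per contrast
(disjoint sets; tumour-type peaks move HCC and MFCCC in opposite
directions, non-tumour is never shifted), class effect δ = 2 log-units,
patient_sd = 0.3, scan_sd = 0.15. δ = 2 was chosen as the "strong
signal" condition: it yields near-perfect cross-validated recovery,
consistent with the >94% accuracies the method is meant to exhibit when
classes genuinely separate; δ = 0 is the null condition, under which
cross-validated accuracy must be statistically indistinguishable from
chance. Because the patient effect multiplies all peaks equally, TIC
normalization removes it almost exactly — which both mirrors why the
real protocol normalizes on TIC and makes null-cohort fragments nearly
i.i.d., justifying the binomial calibration interval.

What the generator does **not** emulate: isotope patterns, adducts,
mass-dependent resolution, drift in mass calibration, inter-patient
biological heterogeneity beyond a global intensity effect, steatosis /
fibrosis / inflammation gradients in non-tumour tissue, or polarity
effects. Passing tests therefore demonstrate that the *pipeline* is
correct and calibrated, not that real tissue classes are separable.

## Problem sizes and numerics

The acceptance script and heavy tests use the full 318-sample study
design (3,180 fragments, ~84 aligned bins) for signal recovery and task
counts, and a balanced 60-sample cohort (600 fragments) for the null
calibration; smaller narrow-band cohorts drive the fast unit tests. Text
round-trips format floats as `%.17g`, which reproduces IEEE doubles
exactly. Score-column orthogonality is enforced at 1e-8 relative; TIC
row sums at 1e-9. QC matching is nearest-neighbour with ties broken
toward lower *m/z*; default QC tolerances (0.5 Da mass, 30% ratio) are
this package's choices, and the shipped PPG reference table is synthetic
(the monitored ion list of the real daily check is unpublished).

## Known limitations

- The 3-class task's published fragment percentages cannot be reconciled
  with any derivable task size, so the reconciliation covers the two
  binary tasks and the sample-level concordances whose denominators are
  known; the 3-class taxonomy itself is implemented and exercised on
  synthetic data.
- mzML reading is minimal (profile MS1, 32/64-bit float arrays, optional
  zlib); it exists to map external data onto `Acquisition`, not to cover
  the full standard.
- NIPALS explained-X-variance fractions are not guaranteed monotone for
  PLS (unlike PCA); the model validates only that they lie in [0, 1].
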