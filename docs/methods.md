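# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of `teafp`.  Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The measurement model

One injection yields a *fingerprint*: the detector trace sampled on a
fixed retention-time grid (0–25 min, step 0.01 min, 2501 points), one
trace per detection channel — UV absorbance at 280 nm and fluorescence
at 280/350 nm (excitation/emission).  The whole trace is the feature
vector; no peaks are detected, integrated or identified.  Two facts
about this kind of data drive the design:

* **Detector sensitivity drifts.**  Lamp intensity declines slowly over
  an analytical sequence of ~130 injections, scaling whole traces by a
  factor that depends on injection order.  A pooled QC (equal-volume
  mix of every study extract) injected at the start and after every ten
  samples tracks this drift.
* **Retention times jitter.**  Small per-injection shifts (~0.02 min
  s.d.) decorrelate otherwise identical traces and must be aligned away
  before any variable-wise model is meaningful.

## Synthetic study generator

The generator (`teafp.synthetic`) emulates a 107-sample study of five
tea varieties and chicory with the class sizes 35 (black) / 20 (green) /
10 (oolong) / 12 (red) / 10 (white) / 20 (chicory).  Each class is a
`ClassTemplate`: a crowded set of Gaussian peaks (13–26 per class) over
the 1–19 min elution window with fixed centers, widths (σ 0.06–0.12 min)
and per-channel amplitudes.  The templates encode the qualitative
structure such studies report:

* all teas share an intense marker peak at 11.0 min;
* chicory has more UV peaks than any tea but its UV amplitudes are
  100-fold lower than the weakest tea's;
* white tea is the most UV-intense; black and green are the most
  FLD-intense and the most UV-peak-rich among teas; red and chicory
  carry the most FLD peaks;
* white tea consists of two sub-templates (5 + 5 lots), the second of
  which adds a chicory-like side pattern — this is what makes white tea
  the hard case in classification and prediction.

A *sample* (commercial lot) is a template with per-peak lognormal
amplitude factors (mean 1, CV `amp_cv`, default 0.05, shared across
channels since both detectors see the same extract).  A realized
injection is

    trace = s(i) * [ Gaussian sum with per-injection retention shift + baseline ] + noise

with `s(i) = (1 + slope*(i-1)/(n-1)) * exp(w_i)` the sensitivity factor
(default slope −0.15 across the sequence, Gaussian random-walk s.d.
0.005 per injection), a smooth two-cosine baseline with random phases
(amplitude 2 % of the class maximum), and white noise with s.d. 0.5 %
of the class maximum amplitude.  The pooled-QC ideal trace is the
unweighted mean of all sample ideal traces; blanks are baseline + noise
only.  `GeneratorConfig.drift_factors` accepts an explicit sensitivity
array, which the tests use to hold the factor constant over each
nearest-QC cell when demonstrating exact drift cancellation.  All
randomness flows from one integer seed through keyed generator streams;
identical (config, seed) pairs give bit-identical datasets.

What the generator does **not** emulate: peak tailing and co-elution
shape distortion, gradient-dependent baseline chemistry, inter-peak
correlation beyond the shared lot factor, heteroscedastic detector
noise, and real compound identities.  Passing tests therefore show that
the chemometrics recover the structure this model encodes — drift,
jitter, lot variability, class patterns, linear mixing — not that they
would meet the same error bounds on any particular real instrument.

## Pretreatment chain

Fixed order: smoothing → baseline correction → alignment → (optional)
QC division → autoscaling.

* **Smoothing**: Savitzky–Golay, window 11 points, polynomial order 3 —
  the chemometric default; preserves peaks of σ ≥ 6 points while
  attenuating white noise.
* **Baseline**: asymmetric least squares (Whittaker smoother with
  asymmetric weights), λ = 1e5, p = 0.01, 10 iterations, solved as a
  symmetric pentadiagonal banded system per iteration.
* **Alignment**: segment-wise integer-lag shifts (10 segments, maximum
  shift 20 points) maximizing the inner product with a reference trace
  (the mean QC trace in full-sequence work, the mean calibration trace
  in mixture studies).  Candidate lags are visited by increasing |lag|
  and scored with zero-filled gaps, so featureless segments stay
  unshifted; output gaps are filled with the boundary value.
* **QC division**: each trace is divided point-wise by the QC nearest
  in injection index (ties to the preceding QC, which always exists
  because a QC opens the sequence), as `(x + ε) / (q + ε)` with
  ε = 0.1 % of the QC trace maximum.  Because ε scales with the
  realized QC trace, a sensitivity factor shared by sample and QC
  cancels exactly, and every QC row becomes exactly all-ones.
* **Autoscaling**: column-wise mean-centering and unit-variance scaling
  (sample s.d.); columns with s.d. < 1e-12 are zeroed.  Prediction rows
  are always scaled with training moments only.  In the model
  workflows the autoscaling lives inside the PLS estimators, which
  store the training moments — this is the same final stage, placed
  where leakage is structurally impossible.

The order QC-division-after-alignment (and after smoothing/baseline) is
a configuration choice; the correction itself is order-insensitive for
pure multiplicative drift.

## PLS, PLS-DA and model selection

NIPALS PLS with X- and Y-deflation (convergence 1e-10, ≤ 500 iterations
per LV; sign convention: the largest-magnitude element of each weight
vector is positive; an exhausted X or Y residual ends extraction early).
NIPALS was chosen over SIMPLS for transparency: every intermediate
quantity is oracle-checkable, and the first component is reproduced
literally in a test.  Coefficients are `B = W (P'W)⁻¹ Q'` in
autoscaled-X space.

Cross-validation uses venetian blinds (test fold *k* = samples
*k*, *k*+*s*, …, default *s* = 10 capped at the sample count), each fold
rescaled on its training rows only.  The LV count is the *first
important minimum* of the error curve, operationalized as the smallest
count whose error is within rel_tol = 2 % of the best error at any
larger count.  PLS-DA cross-validates the misassignment rate rather
than RMSECV, matching how classification models are reported; the
paired-model threshold is 0.5 on the chicory response with ties
assigned to the tea class, so adulterant calls are conservative.
The 70/30 calibration/prediction split is stratified per class so the
ten-sample classes appear in both sets.

## Adulteration studies

Each study takes one tea extract and one chicory extract (fresh lots
drawn from the class templates), mixes them linearly in intensity —
absorbance and fluorescence are additive at these concentrations — at
the calibration levels 0/20/40/60/80/100 % chicory and validation
levels 15/25/50/75/85 %, five replicates each differing by fresh noise
(s.d. 0.5 % of the tea-extract maximum, the same detector-noise level
the generator uses).  The prediction set (15/50/85 %, five replicates)
uses different extracts: a new lot for every class, and for white tea
the *other* sub-template, so prediction genuinely changes composition,
not just noise.  Mixtures are preprocessed with the same chain minus QC
division (the standalone design contains no QC injections).  Reported
errors are RMSEs in percentage points of adulterant; pooled over levels
for the prediction set.  `max_lv` defaults to 8 with 10 venetian-blind
splits on the 30 calibration rows.

## Numerical choices and degenerate inputs

* Zero-variance response → error; zero-variance columns are zeroed, not
  dropped, so column indices remain stable.
* Equidistant-QC ties resolve to the earlier QC; assignment ties to the
  tea class; LV-selection plateaus resolve to the smallest count.
* PCA is computed by SVD on the already-scaled matrix; explained
  variance is squared singular values over total sum of squares; sign
  convention as in PLS.
* The 2501-point grid keeps every matrix desk-scale (the largest is
  130 × 2501 doubles); the full default study, all ten adulteration
  studies and all ten paired models run in well under a minute on one
  CPU, which is the problem size all shipped tests and the acceptance
  script use.

## Known limitations

* The in-silico mixing is exactly linear; matrix effects, detector
  saturation and volume errors of physical mixture preparation are not
  modeled, so calibration errors here are optimistic lower bounds.
* With thousands of autoscaled variables and 30 calibration rows, the
  noise-dominated variables inject a small shrinkage of predictions
  toward the calibration mean on fresh data; it is visible as
  symmetric bias at the extreme levels of the external-validation set
  and grows if fingerprints get sparser or noisier.
* The first-important-minimum rule can select one LV fewer than the
  error optimum when the CV curve is nearly flat; the 2 % tolerance is
  deliberate (parsimony) but is exposed as a parameter.
* Classification rates on ten-sample classes rest on three-sample
  prediction sets; a single misassignment moves the rate by 33 points.
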