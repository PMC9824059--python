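# Methods

`gaitsurface` implements a classification framework for detecting irregular
walking surfaces from a single body-worn tri-axial accelerometer, together
with a synthetic-cohort generator that makes every stage testable without
access to human-subject recordings. This note documents the models, the
conventions, and the design choices that were genuinely open.

## Problem setting

A pedestrian walks over stretches of good and irregular pavement while a
100 Hz accelerometer records linear acceleration at the ankle, the hip, or
the head. Each gait cycle (stride: heel strike to next heel strike of the
same foot) is classified as having occurred on a Good or an Irregular
surface. Irregular ground perturbs stride timing and the magnitude of
acceleration pulses, and intermittently interrupts a stride outright, so the
information lives in per-stride gait features and their short-term
variability rather than in raw signal windows.

## Synthetic cohort generator

The generator is a first-class, tested component, not a fixture. Each
subject walks with subject-specific random effects; each stride renders a
smooth three-channel template of Gaussian pulses; surface effects perturb
the event stream.

**Gait template** (phase within stride, amplitude in g, width as stride
fraction): vertical V — heel-strike impulse (0.03, 0.85, 0.025), mid-stance
trough (0.30, −0.45, 0.09), push-off (0.62, 0.35, 0.05); anteroposterior AP —
one dominant heel-strike peak (0.00, 1.00, 0.022) that anchors segmentation,
and a mid-cycle trough (0.55, −0.35, 0.06); mediolateral ML — low-amplitude
sway (0.25/0.75, ±0.18, 0.12). Amplitudes are calibration constants of the
generator, not claims about any particular cohort.

**Subject random effects**: base stride period ~ Normal(1.10 s, 0.05 s);
amplitude scale ~ Normal(1.0, 0.12); timing-variability scale ~
LogNormal(0, 0.4), clipped to sensible ranges. The timing-variability scale
makes some subjects naturally steadier walkers than others; without it,
leave-one-subject-out (LOSO) evaluation would be equivalent to pooled CV and
would saturate.

**Surface effects**: good pavement has stride-period jitter CV 0.02 and
pulse-amplitude perturbation SD 0.05; irregular ground has jitter CV 0.06,
amplitude perturbation SD 0.25, and interrupts each stride with probability
0.3. An interrupted stride has its period inflated by a factor 1.25 and an
added V/ML transient (a stumble); the surface label stays Irregular —
interruption is intermittent, not a label change.

**Nonstationarity**: a slow per-subject AR(1) "gait state" (lag-1
correlation 0.8) multiplies the jitter and amplitude-perturbation SDs by
exp(0.7·state). Natural gait drifts over tens of strides; a stretch of good
walking can look locally variable and vice versa. This is what keeps single
strides from being trivially classifiable.

**Sensor locations**: one stride-event stream per subject drives all three
locations, so recordings arrive sample-aligned with shared heel-strike
ground truth and identical per-sample labels (this stands in for the
physical-sensor timestamp synchronization a real deployment needs). Body
acceleration is attenuated at the hip (×0.5) and head (×0.3) relative to
the ankle. Surface-induced amplitude *deviations* and interrupt transients
attenuate by an extra factor of attenuation^1.75 — impact-related
high-frequency content is damped by soft tissue more steeply than the
fundamental gait pattern (the exponent is a calibration constant of the
generator). Sensor noise (white, SD 0.05 g, plus equal-SD
baseline wander low-passed at 0.8 Hz) is *not* attenuated; the wander does
not average out within a stride and therefore sets the noise floor that the
attenuated surface effect at the hip and head has to beat. Together these
produce the intended structure: surface information is strongest at the
ankle, weak and mutually similar at hip and head, while stride-timing
information (shared event stream) is location-independent.

**Default schedule**: 120 s per subject, four irregular stretches of 10.5 s
interleaved with five good stretches of 15.6 s, so the walk starts and ends
on good pavement (65:35 Good:Irregular time split).

What the generator does **not** emulate: biomechanical forward dynamics,
distinct irregular sub-surface types (grass vs. debris etc. are pooled into
one Irregular class), gyroscope/magnetometer channels, turning or stopping.
A passing test suite therefore shows the *pipeline* behaves as specified
under the stated statistical structure; it does not certify performance on
any real cohort.

## Stride segmentation

Heel strikes are detected on the ankle AP channel: zero-phase 4th-order
Butterworth low-pass at 10 Hz; dominant stride period from the highest
*local* autocorrelation peak at lags 0.4–2.5 s (requiring ≥ 0.15 of the
lag-0 energy — noise autocorrelation decays without a local peak, so
constant or noise-only signals raise a no-gait error); local maxima with
prominence ≥ 0.5 × SD of the filtered signal and minimum separation 0.6 ×
the estimated period. Hip and head recordings of a subject are segmented
with the ankle-derived heel strikes. Strides outside (0.4 s, 3.0 s) are
discarded as turns or pauses. A stride's label is the majority of its
per-sample labels; ties go to Irregular, the positive class. On the default
generator, detection recovers > 95% of true heel strikes within ±30 ms
(measured in the test suite at > 99%).

## Gait features (40 per sensor)

Twenty base features per stride; magnitude features are the **mean**
per-sample value over their window — mean Euclidean norm √(ML²+V²+AP²) for
the VM family, mean |·| for single-direction variants. The mean (rather
than a sum) makes magnitude features invariant to stride duration so that
they carry information separate from stride time; this aggregation
convention is a documented choice. Windows: whole stride (VM, LVM, VVM,
AVM); initial 5% (VM5); double stance = [−10%, +10%] around the initial
heel strike, the negative half taken from pre-stride context and truncated
at bout start (VMD family); mid-stance = [25%, 35%] of the cycle (VM30
family — the cycle's "30%" point with a ±5% window, width being another
documented choice); heel-strike max and SD features over the initial 10%
(LHM/LHSD, VHM/VHSD, AHM/AHSD; sample SD); stride time ST. Each base
feature also gets a between-stride variability feature: the sample SD over
a centered window of five strides within the bout, truncated at bout edges,
zero for bouts of fewer than three strides. Window width five is small
enough to stay mostly within one surface stretch and large enough for a
stable SD.

## Feature selection

Features are standardized (zero mean, unit variance) before selection.

**Elastic net.** The ranker fits an L1+L2-penalized model over a grid of
mixing parameter α ∈ {0, 0.1, …, 1} and penalty weight λ ∈ 10^{−4..0}
(9 log-spaced values), choosing (α, λ) by stratified five-fold CV AUC and
refitting on the full training set; features are ranked by |coefficient|
with an alphabetical tie-break (zeros included, so a fully shrunk model
falls back to alphabetical order). Because the response is binary, the
default objective is the elastic-net-penalized **logistic** loss (λ maps to
the inverse of sklearn's `C` times n); the squared-error variant is
available behind `loss="squared"`. The grids bracket the optima one expects
for this problem family (λ of order 10⁻³–10⁻², small-to-moderate α).

**mRMR-FCQ.** Greedy forward selection; a candidate's score is its one-way
ANOVA F-statistic against the class label divided by its mean |Pearson
correlation| with the already-selected set (F alone when the set is empty;
zero-variance candidates score 0; the denominator is floored at 10⁻¹²).
The absolute value keeps redundancy positive, following the FCQ
formulation's intent; ties break alphabetically.

**Profiling and subset sizing.** Inside LOSO, each iteration contributes
its top-10 list; features are profiled by selection frequency. Equal-
frequency features are added **batch-by-batch** to an AUC-vs-subset-size
curve (repeated stratified five-fold CV, default model hyperparameters),
and the knee of the best-performing model's curve is located with the
Kneedle algorithm (min-max normalize both axes, difference curve d = yₙ −
xₙ, candidate knees at local maxima of d, first candidate whose following
values drop below the sensitivity-adjusted threshold; sensitivity 1.0; a
straight line has no knee, and a single-batch curve yields the full set).
The selector whose subset achieves the best AUC with the fewest features
wins.

## Classification protocol

Five classifiers: SVM (RBF kernel; cost and kernel coefficient searched),
random forest (trees, depth, split/leaf minima, features per split),
logistic regression (inverse penalty), AdaBoost (stumps, learning rate),
and gradient-boosted trees (depth, learning rate, trees, row/column
subsampling). Hyperparameters are tuned per LOSO iteration by randomized
search (20 draws by default) scored with stratified five-fold CV AUC.

Inside every fold the order is **standardize → SMOTE → fit**: the scaler is
fitted on the fold's training part only, and SMOTE oversamples the minority
(Irregular) class to 50:50 by interpolating between a minority sample and
one of its 5 nearest minority neighbours, in standardized space so
nearest-neighbour geometry is not dominated by feature scale. Test data are
never resampled or used for scaling. SVM probabilities come from sigmoid
(Platt) calibration of the decision scores on internal CV predictions.

The metric is the rank-based AUC (Mann–Whitney; ties count ½), with
Irregular as the positive class; it is undefined (an error) when one class
is absent. For the sensor-location comparison, the per-LOSO-iteration
metric is the mean AUC of repeated stratified five-fold CV **on the
training subjects** with all 40 features and default hyperparameters (the
held-out subject stays untouched; computing it on the held-out subject
instead is a flag away). The three locations of an iteration are evaluated
on the same fold partition — their rows are the same strides — so the
comparison is paired and fold-split noise cancels from the location
contrasts. Note a structural property of this protocol: the per-iteration
metrics within a location are pseudo-replicates of one dataset (iterations
share almost all strides), so the location's own noise realization never
enters the ANOVA's within-group variance; the test is consequently
anti-conservative under a true null and its small p-values should be read
as descriptive, not calibrated. One-way ANOVA across the three locations, followed
by Tukey's HSD (studentized range; equal group sizes by construction, with
Tukey–Kramer applying automatically otherwise), tests whether location
matters; `reject` ⇔ adjusted p < α ⇔ simultaneous CI excludes zero. Groups
with zero within-group variance short-circuit to the documented
conventions (identical groups: F = 0, p = 1, never reject).

## Post-processing

Per-stride predicted probabilities are aggregated over sliding windows of k
consecutive strides (step 1) within subject; the window score is the
arithmetic mean probability and the window truth is the majority stride
label (ties → Irregular; windows never span subjects or bouts). Because
interruption and perturbation are intermittent, per-stride scores are noisy
around class-conditional levels and averaging improves AUC as k grows. At
mean stride time ≈ 1.10 s, a k = 5 window corresponds to about 5.5 s of
walking — the minimum measurement span this approach needs.

## Numerical and degenerate-input conventions

Seeds: every stochastic component takes a master seed and derives
per-fold/per-model streams from it; identical configs reproduce outputs
bit-for-bit (the event stream of a subject is drawn independently of
location so the three sensors stay aligned). Standardization uses
population SD (sklearn convention); constant columns map to zero. SMOTE
reduces k with a warning when the minority class is ≤ k and refuses fewer
than 2 minority members. Variability features use sample SD (ddof = 1).
Strides shorter than 20 samples raise a feature-extraction error naming the
stride. Recording CSVs are validated on read: uniform sampling within 1%,
no gaps over 2 sample intervals, known labels; violations raise schema
errors citing the line.

## Problem sizes used in the shipped tests and acceptance script

The packaged test suite runs the full protocol at reduced scale — cohorts
of 4–8 subjects (10 replicate cohorts of 8 subjects with 60 s bouts for the
location study, 10 cohorts of 5 for the null study), randomized search
budgets of 2–8 draws, and single-repeat five-fold CV for location metrics —
sizes chosen to exercise every code path and the stated statistical
properties with adequate power. The
acceptance script simulates a single 120 s Good-surface ankle recording
and reports the mean detected stride time over the retained strides.

## Known limitations

* The generator's surface effect is phenomenological (timing + amplitude
  perturbations + interrupts), not biomechanical; absolute AUC levels on
  synthetic cohorts say nothing about absolute performance on real data.
* Stride segmentation assumes a single dominant AP peak per stride; gait
  styles or sensors violating that need re-tuned detection constants.
* The elastic-net λ↔C mapping uses the full-sample n inside grid-search
  folds, a standard approximation; the grid is searched along a warm-started
  penalty path (strong to weak shrinkage) with solver tolerance 10⁻³,
  ample for coefficient ranking.
* Relative model robustness to subject differences is not a property the
  generator reproduces: increasing the between-subject variance does not
  degrade tree ensembles more than the SVM on synthetic cohorts, so
  conclusions about which classifier generalizes best across subjects
  require real data.
* Tukey HSD assumes approximately normal, equal-variance metric
  distributions across LOSO iterations; with 5–12 values per group this is
  an approximation accepted by the protocol.
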