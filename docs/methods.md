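# Methods

This note documents the models, estimators and design choices in `popcode`:
what is being simulated, how information is estimated, which parameters
matter, and what the synthetic data can and cannot tell you about real
afferent recordings.

## The scientific question

Peripheral tactile information is carried by populations of mechanoreceptive
afferents of several classes with different receptive-field sizes,
adaptation properties and frequency sensitivities. Because microneurography
records one fiber at a time, population-level questions — how information
scales with innervation density, whether classes carry redundant or
complementary information, and how much of the code lives in spatial
(which-afferent) versus temporal (when-exactly) structure — are studied by
simulation. `popcode` implements that analysis chain end to end on a
synthetic spiking model with the qualitative response properties of SA1, RA
and PC afferents.

## Stimulus model

A circular probe indents the skin along a ramp-and-hold trajectory; once the
plateau is reached a sinusoid is superimposed, ending when the ramp-down
begins. Feature grids (probe size 1–4 mm; ramp amplitude 0.3–1.2 mm; ramp
time 10–50 ms; frequency 0–200 Hz) define an 800-condition factorial design.
Choices the stimulus description leaves open, fixed here once:

- **Trial duration 0.5 s**, ramp-down mirroring the ramp-up; this leaves
  ≥ 0.4 s of hold, enough to estimate phase locking at every grid frequency.
- **Base sine amplitude 0.1 mm.** No value is dictated by the design; 0.1 mm
  makes the stated ±0.05 mm amplitude jitter a ±50% relative perturbation,
  so vibration-evoked firing rates overlap across trials and rate alone is
  a noisy frequency cue (timing is the reliable one, as in real PC data).
- **"Size" is probe radius** (edge at `size_mm/10` cm along the line).
- **Simulation step 0.1 ms** (resolves 200-Hz locking well before the 2-ms
  analysis binning); sine phase starts at 0; depth clipped at 0.
- **Motor noise** jitters probe location (±0.3 mm, along the line), sine
  amplitude (±0.05 mm, clamped at 0) and ramp amplitude (±0.1 mm), each
  uniform per trial.

## Afferent model

Afferents terminate along a line radiating from the contact site (1 cm for
SA1/RA, 5 cm for PC). Areal density maps to a line count through a 1-cm-wide
strip, `N = round(density × length)`; afferents are evenly spaced with a
seeded dither under a quarter of the spacing.

Per afferent, drive(t) = w(distance) × rectify(static + dynamic), with

- static part: `static_gain × depth` (SA1 only);
- dynamic part: gains on |velocity| and |acceleration| after a 2nd-order
  Butterworth band filter, optionally passed through a saturating
  nonlinearity `g·x/(g+x)`;
- `w(x) = exp(−x / rf_length_constant)`, measured from the probe **edge**
  for SA1/RA (so probe size changes recruitment) and from the probe
  **center** for PC (so PC drive is independent of probe size by
  construction).

Spikes come from a leaky integrate-and-fire unit (membrane time constant
τ, absolute refractory period, threshold 1 with Gaussian noise redrawn after
every spike). An LIF with threshold noise was chosen over Poisson sampling
deliberately: it produces the phase locking and spike-time precision that
the temporal-jitter analysis must be able to destroy.

Class parameters are calibration constants, not fitted claims. They were
chosen once so that the standard qualitative properties hold, and then
frozen:

| parameter | SA1 | RA | PC |
|---|---|---|---|
| RF length constant (cm) | 0.10 | 0.8 | 100 |
| static gain (/mm) | 2.0 | 0 | 0 |
| velocity gain (/(mm/s)) | 0.05 | 0.12 | 0 |
| acceleration gain (/(mm/s²)) | 0 | 0 | 6e-4 |
| band filter (Hz) | lowpass 50 | lowpass 60 | none |
| drive saturation | — | 2.5 | 1.3 |
| refractory (ms) | 5 | 2.5 | 3 |
| membrane τ (ms) | 5 | 4 | 2 |
| threshold noise SD | 0.15 | 0.15 | 0.15 |

Rationale for the load-bearing choices:

- **SA1** small RF and static gain give sustained, recruitment-graded
  responses: probe size and indentation depth are coded spatially and by
  rate; the 50-Hz lowpass on the velocity term lets SA1 spikes align to
  low-frequency vibration without responding at PC frequencies.
- **RA** is velocity-driven with a 60-Hz lowpass (flutter band), silent during
  static holds, bursts at ramp on/offsets; a medium RF gives it coarser
  spatial resolution than SA1.
- **PC** is acceleration-driven (the acceleration's own ω² scaling provides
  the high-frequency emphasis) with strong saturation and a 3-ms refractory
  period, which yields roughly one-spike-per-cycle
  entrainment: frequency is carried by precise spike timing while spike
  counts overlap across conditions (amplitude jitter modulates how many
  cycles recruit a spike). The RF length constant (100 cm) vastly exceeds
  the 5-cm line, making PC sensitivity effectively uniform — consistent
  with Pacinian receptive fields spanning whole hand regions — so PC
  afferents are statistically exchangeable and per-trial afferent
  permutation barely affects their code, while temporal jitter destroys it.

Neural noise is threshold noise only; all environmental noise lives in the
stimulus jitters.

**Common random numbers across probe sizes.** Per-trial random streams are
keyed by (amplitude, ramp time, frequency, trial) — excluding probe size —
so two conditions differing only in size see identical stimulus jitter and
threshold-noise draws. PC rasters are therefore *bitwise identical* across
sizes (their drive does not depend on size), making "PC carries no size
information" exact at the raster level rather than approximate.

## Decomposition

Spike trains are binned at 2 ms and assembled into `R ∈ R^(M×TN)`
(afferent-major, time-minor along the flattened axis; the convention is
arbitrary but fixed). Non-negative matrix factorization (`R = HW`,
Frobenius loss, coordinate descent, seeded random initialization, max 500
iterations, tol 1e-4, via scikit-learn) gives K spatiotemporal modules.

Module count selection uses a 25% selection set, stratified by condition:
explained variance `1 − ‖R−HW‖²_F/‖R‖²_F` is swept over K until the gain
from one more module falls below 1 percentage point; the variance at that
point is the density's *saturation level*; saturation levels are averaged
across the densities of a class into a class-level threshold; the final K
per density is the smallest K reaching that threshold (densities that
cannot reach it are flagged and keep their saturation K). An all-zero
response matrix is defined to have explained variance 1 with zero factors.

The analysis (75%) set is never refit: its activation coefficients are
obtained by per-trial non-negative least squares against the fixed modules
(deterministic; no random initialization). Because the NMF initialization
is random, the whole chain is repeated across instantiations (50 at paper
scale, 5 in the desk profile) and every reported dispersion is the SD
across instantiations.

A spatial-only control decomposition (whole-trial counts → spatial modules;
per-bin non-negative projection, K_space × T coefficients per trial) is
provided for robustness checks.

## Decoding and information

Each stimulus feature is decoded separately from the same H. The decoder is
a softmax multinomial logistic regression (equivalent to the
one-vs-rest-of-S_n−1 parameterization, with simpler tie handling), L2
penalty, L-BFGS, regularization strength picked from 7 log-spaced values
10⁻³…10³ by stratified 5-fold cross-validated cross-entropy on the training
half of the analysis set (ties → strongest regularization), then refit.
The analysis set is split 50/50 stratified into train/test; joint
class-set decoding concatenates the per-class activation coefficients
trial-wise (per-class NMF is always fit separately), and never mixes train
and test trials across classes.

Mutual information is the plugin estimate on the test-set confusion matrix,
with 0·log 0 = 0, reported in bits and normalized by `H(S) = log₂ Sₙ`. No
bias correction is applied: compressing the response to one decoded label
per trial is itself the bias-control strategy, and the quantity is
documented as a lower bound. Complementary and redundant information are
the linear combinations given in the README; their sum equals the
reference-class information by construction, and the pipeline asserts this
to 1e-12 bits.

The saturation density of an information-vs-density curve is the smallest
density whose mean information reaches the top-density asymptote minus a
tolerance, defaulting to max(SD across instantiations at the top density,
2% of the stimulus entropy).

## Perturbations

- **Spatial shuffle:** one afferent permutation per trial, applied to all
  time bins (the only reading that permutes "the order of afferents in R"
  while acting on all bins at once); per-bin population counts are
  conserved exactly.
- **Temporal jitter:** each spike shifted by an independent uniform draw in
  ±2/5/10 ms *before* binning; spikes leaving the trial window are
  discarded (wrapping or reflecting would inject artificial periodic
  structure); refractory violations after jitter are permitted.

Perturbed data are projected onto the original modules and decoded with the
frozen decoder. Small *increases* of estimated information after a
perturbation occur and are expected: the estimator is a lower bound whose
tightness varies, so such increases indicate no usable structure at that
scale, not extra information.

## Experiment profiles and problem sizes

- `paper`: 800 conditions × 40 trials, 16 log-spaced densities in
  [1, 140] per class, 50 NMF instantiations, finger-preset combination
  densities (SA1 30 / RA 40 / PC 10), strategy comparison at a 10
  afferents/cm² baseline. Long-running; intended for batch use.
- `desk` (default for tests and the acceptance script): probe sizes
  1–4 mm, amplitudes {0.3, 1.2} mm, ramp time 30 ms, frequencies
  {0, 80, 120} Hz (24 conditions), 20 trials, densities {5, 40}/cm² for
  SA1/RA and {1, 8}/cm² for PC (so both classes span 5 → 40 afferents),
  5 instantiations, perturbations on size and frequency. Runs in ~6
  minutes on one CPU. The frequency pair 80/120 Hz is deliberately chosen
  to be separable mainly by spike timing at 2-ms resolution, so the
  temporal-jitter analysis has structure to destroy.
- `micro`: a seconds-scale smoke profile.

The desk grid trades the full factorial for wide coverage of each feature
axis; entropies are lower (e.g. 2 bits for size, log₂3 for frequency), so
normalized information is the comparable quantity across profiles.

## What the synthetic data do and do not show

The generator reproduces the *qualitative* class properties listed above —
sustained SA1 responses with spatial recruitment, RA onset/flutter
responses, PC high-frequency phase locking with size- and depth-invariance —
and the analysis reproduces the population-level signatures that follow
(class specialization by feature, density saturation for spatially coded
features, complementarity between classes, spatial-vs-temporal dissociation
under perturbations). It does **not** reproduce any fitted afferent model's
firing rates or timing precision, hand geometry, SA2 afferents, hairy skin,
shear forces, moving stimuli or surface-wave propagation. Numerical
information values therefore characterize this simulator under these study
conditions; passing tests certify the pipeline's correctness and the
qualitative biology, not quantitative agreement with recordings.

## Numerical and reproducibility notes

- All randomness derives from one master seed through keyed
  `numpy.random.SeedSequence` streams (placement, stimulus, neural noise,
  splits, NMF initialization, decoder CV, perturbations). Stream keys
  depend on *content* (class, density, condition, trial, instantiation),
  not call order, so the same cell computed in different contexts is
  bitwise identical, and pipeline reruns produce byte-identical CSVs.
- Decoder ties at equal posterior resolve to the lowest outcome index;
  equal CV loss resolves to the smallest C.
- The NMF coordinate-descent solver may hit its iteration cap on hard
  desk-scale matrices; this is surfaced as a warning and bounded by the
  explained-variance bookkeeping rather than treated as an error.
- Degenerate inputs are defined explicitly: zero response matrices (EV 1,
  zero factors), zero-width jitter (identity), single-afferent populations
  (spatial shuffle refuses, N ≥ 2 required), conditions with fewer than 2
  trials (split refuses).

## Known limitations

- The 1-D receptor line ignores 2-D receptive-field scatter; spatial
  effects are upper-bounded by the line geometry.
- The LIF front end has no adaptation, so SA1 "slow adaptation" is only
  implicit in the gain structure; onset dynamics are coarser than real
  fibers'.
- The plugin-MI-of-confusion construction saturates near the stimulus
  entropy; with few outcome values, ceiling effects can hide differences
  between strong codes (visible for ramp amplitude at desk scale).
- Strategy comparison (double density vs add a class) requires the baseline
  and doubled densities in the simulated grid and is only enabled in the
  paper profile.
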