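# Methods

`mmnpipe` is a simulation-plus-analysis pipeline for mismatch-negativity
(MMN) studies of psychosis risk.  It has two halves: a synthetic-EEG
generator that emulates a four-group clinical-high-risk cohort recorded
in an auditory oddball paradigm, and an analysis chain (preprocessing,
sensor-level MMN peaks, fixed three-regional-source estimation, cohort
statistics) that can be applied to those recordings — or, in principle,
to any 32-channel BrainVision recording with the same event markers.

## Paradigm

One continuous block of 2,400 binaural tones at a 500 ms stimulus onset
asynchrony (20 minutes): 1,896 standards (1000 Hz, 100 ms, 80 dB) and
168 each of duration (50 ms), frequency (1200 Hz) and intensity (70 dB)
deviants, with at least two standards between any two deviants and the
first two events forced to standards.  Deviant slots are drawn uniformly
from all gap-respecting placements through an exact combinatorial
bijection (minimum-gap subset sampling), so generation is O(n), never
retries, and cannot fail for the default counts.  A stricter optional
mode additionally forbids two consecutive deviants of the same kind
(sequential constrained assignment with restart).

## Volume conductor and electrode geometry

The head is three concentric spherical shells — brain, skull, scalp —
with outer radii 71/79/85 mm and conductivities 0.33/0.0042/0.33 S/m
(standard literature values).  Dipole potentials are computed from the
Legendre-harmonic expansion; for each degree the radial coefficients are
solved from the interface continuity conditions with a per-shell
normalized basis, which keeps the linear systems well conditioned up to
the default 60 terms.  A convergence bound on the harmonic tail raises a
diagnostic error for dipoles too eccentric for the configured
truncation.  In the homogeneous-conductivity limit the solver agrees
with the closed-form single-sphere solution to ~1e-10 relative error
(tested to 1e-6 at eccentricities up to 0.8).

The 32-channel cap holds 31 extended 10-20 scalp electrodes plus one
infraorbital EOG channel, referenced to FCz.  Idealized positions are
taken from the canonical 10-20 angular table (via MNE's standard
montage), re-centred on a least-squares sphere, projected onto the 85 mm
scalp radius, and made exactly left-right symmetric so mirror-symmetry
properties of the forward model hold to machine precision.

Three regional sources (three orthogonal unit dipoles each) sit at
atlas centroids of the left/right transverse temporal gyrus,
RS1 = (−41, −26, 11) mm and RS2 = (+41, −26, 11) mm, and the anterior
cingulate, RS3 = (0, 25, 25) mm; the atlas coordinates are used directly
in the sphere frame (origin at the sphere centre).  All three are
overridable through the run configuration.  Units contract: moments in
nAm, potentials in µV; ~10 nAm at these depths produces ~0.5–1 µV at the
vertex, matching the scale of published sensor and source values.

## Synthetic cohort

Groups: 50 healthy controls (CON), 74 basic-symptoms-only (BS), 74
meeting both basic-symptoms and ultra-high-risk criteria (UHR&BS), and
13 UHR-only subjects; 3/10/2 of the risk-group subjects carry a
transition-to-psychosis flag (15 of 161).  Per-subject generative
frontal/temporal MMN source amplitudes for the duration condition are
drawn from the published group moments (e.g. control frontal source
13.95 ± 7.17 nAm versus 7.7–9.2 nAm in the risk groups); subjects
meeting UHR criteria instead draw from the published
transition/non-transition moments (frontal 5.21 ± 2.89 versus
8.29 ± 4.68 nAm), which places the transition deficit in the generative
model.  Frequency- and intensity-deviant amplitudes use control-level
moments for every group, because no group structure was reported for
those conditions.  Draws are winsorized at a 0.5 nAm floor — clipping
rather than resampling, so sample means stay within a fraction of a
percent of the nominal moments.  Covariates (age, SIPS positive and
negative scores, GAF, sex counts) are drawn at the published per-group
moments, independent of the source amplitudes.  Control GAF/SIPS values
are not part of any analysis; controls receive nominal healthy values
(GAF 85 ± 5, SIPS 0).

Event-related source activity: standards evoke a biphasic obligatory
response at the two temporal sources (unit-peak N1-like bump at 100 ms
with a smaller opposite lobe, subject-specific amplitude ~20 nAm);
deviants evoke the same plus an MMN component at all three sources — a
raised-cosine bump of 100 ms full width at a subject-specific latency
(normal around 200 ms, clipped to 160–240 ms, snapped to the 2 ms sample
grid).  MMN dipole orientations are fixed inferior-pointing unit vectors
(the frontal source tilted posteriorly), producing the classic
fronto-central negativity with mastoid polarity inversion.

**Measured-units calibration.**  The published source amplitudes are
themselves measurements taken through a band-pass/baseline/peak-picking
chain, so the generator defines profile amplitudes in measured units:
the injected MMN component is scaled by 1/g(latency), where g is the
deterministic peak gain of the analysis chain on a unit bump.  g is
computed from the chain itself — zero-phase 1–20 Hz filter, 100 ms
baseline, 150–250 ms peak window — including the paradigm's exact
lag-structure correction: each deviant contributes standards at lags
±1/±2 (504/1,896 of all standards per lag) whose baseline-corrected
epochs pick up the deviant's filter tails and slightly depress the
standard average.  g ≈ 0.90 at 200 ms.  Nothing in g is fitted to
pipeline output; disabling calibration (`measurement_calibrated=False`)
injects raw template peaks instead.  With calibration on, the full
noiseless pipeline returns configured amplitudes within ~1 % for
profiles whose three deviant conditions share amplitudes; differing
per-condition amplitudes leave a residual cross-condition leakage of
order 1 % of the across-condition mean (through the shared standard
average), which is why the calibration-identity tests pin the
per-condition amplitudes.

Background noise is Gaussian, spectrally shaped to a 1/√f tilt inside
1–45 Hz, and spatially half independent per channel, half mixed through
a Gaussian kernel in scalp distance (4 cm correlation length, applied as
the Cholesky factor of the mixed covariance) to emulate
volume-conducted background activity.  Its amplitude is calibrated so
the RMS after the 1–20 Hz analysis filter equals the profile's
`noise_rms_uv` (default 8 µV), using the filter's power response rather
than empirical renormalization.  Blinks arrive as a Poisson process
(default 0.1 Hz) with a stereotyped 400 ms raised-cosine waveform,
+70 µV at the frontal pole decaying posteriorly and −80 µV on the
infraorbital EOG channel.  Recordings are expressed against the FCz
reference by subtracting the reference site's forward-projected
potential.  Everything is reproducible from the master seed
(per-subject seeds via one generator stream).

What the generator does **not** emulate: ongoing rhythmic EEG (alpha
spindles), saccades and slow ocular drift, line noise, bad channels,
latency jitter across trials within a subject, or any dependence of
covariates on source amplitudes.  Passing tests therefore demonstrate
correctness of the analysis chain under the stated generative model,
not robustness to every artifact class of real recordings.

## Analysis chain

Fixed order, matching the narrative order of standard ERP practice:
average re-reference over the 31 scalp channels (EOG excluded from the
mean) → zero-phase band-pass (second-order Butterworth high-pass at
1 Hz cascaded with second-order low-pass at 20 Hz; the forward-backward
application preserves MMN latency and doubles the effective rolloff) →
500 ms epochs with 100 ms pre-stimulus baseline → artifact rejection →
subject gate → per-condition averaging.

Rejection: a trial is discarded if any scalp channel exceeds ±120 µV
absolute post-baseline amplitude (the amplitude criterion is absolute,
not peak-to-peak; configurable) or if the EOG peak-to-peak amplitude in
the epoch exceeds 60 µV — the operationalization of "eye movement
detected", since no published threshold exists.  Ocular artifacts are
rejected, not corrected.  Subjects with fewer than 60 % accepted trials
are excluded (the boundary itself is kept).  Edge-truncated epochs are
flagged, never silently dropped.

Sensor MMN: deviant-minus-standard difference waves; peak = most
negative single sample in the closed 150–250 ms window at Fz, F3, F4,
Cz, C3 and C4, ties broken toward the earliest latency.  Point-peak was
chosen over mean-around-peak because the target quantity is a peak
amplitude; per-subject latency is free within the window.

Source estimation: the lead field of the three fixed regional sources
(31 average-referenced channels × 9 components) is inverted with the
Moore–Penrose left pseudo-inverse (unregularized; the default matrix has
condition number ≈ 9, and the identity `inverse @ leadfield = I₉` holds
to 1e-8).  A Tikhonov ridge is available via configuration for noisier
montages.  Source activity = peak of the Euclidean orientation-norm
magnitude inside 150–250 ms; an orientation-invariant scalar was chosen
because regional sources have no privileged orientation; mean-in-window
is available as an option.  The residual scalp variance fraction of each
fit is reported.

A deliberate simplification: the original workflow derived the source
model from the grand average with an iterative distributed-imaging
localization step before applying it per subject.  Here the three source
locations are fixed anatomically, so "model creation" reduces to
lead-field construction; distributed imaging is out of scope.

## Statistics

One-way fixed-effects ANOVAs compare each sensor/source measure across
the four groups (and controls versus all at-risk subjects); pairwise
group contrasts use pooled-variance two-sample t tests with Bonferroni
adjustment (`min(1, m·p)`; Welch optional).  Pearson correlations (sex
coded 0/1, hence point-biserial) relate the duration-condition source
activities to age, sex and GAF.  Transition models are logistic
regressions on the UHR-criteria subset only: source predictors inverse
coded (×−1, so odds ratios read as risk per SD of deficit) and all
continuous predictors z-transformed on the analysis subset (the models
are fit there, so the subset's moments are the relevant scale).
Unadjusted mode fits one single-predictor model per variable; adjusted
mode fits one joint model over sex, age, the three source activities,
GAF and the two SIPS scores (mutual adjustment).  Wald 95 % intervals;
perfect separation is detected and reported as an error rather than
returned as runaway estimates.  No correction across measures beyond the
per-measure ANOVAs is applied.

## Numerical behaviour under noise, and what recovery tests show

With the default 8 µV in-band noise, the averaged difference wave
carries ≈0.66 µV of noise per channel (≈156 accepted deviant trials).
The unregularized inverse of three deep regional sources amplifies this
to 7–11 nAm per source component (inverse row norms 11–17 nAm/µV), so
the peak-of-norm activity of a 14 nAm source is measured around
25–30 nAm: single-subject regional-source amplitudes at this channel
count and SNR are strongly noise-inflated, an intrinsic property of the
estimator geometry rather than an implementation artifact (whitening by
the exact noise covariance changes component SDs by <2 %).  Estimates
remain monotone in the true amplitude, so group contrasts survive in
direction, but they are strongly attenuated: the noise floor both
inflates every group mean and compresses between-group differences
relative to the generative moments, so the frontal-source group effect
in a default cohort is detectable yet far weaker than the generative
effect size would suggest.  The noiseless calibration identity (recovery within 2 %) and
the noisy monotonicity are both under test; exact recovery of absolute
single-subject amplitudes under default noise is not a property this
estimator can have, and the documentation and tests treat it
accordingly.

## Problem sizes used in the test suite

The suite simulates the full default cohort (211 subjects, 20-minute
recordings) once in a session-scoped fixture for the group-separation
and recovery checks, a handful of single subjects for calibration and
determinism checks, and an 8-subject smoke cohort for the end-to-end
command-line run.  The transition-model replicate check draws
subject-level source activities directly from the generative moments
(20 replicates of 87 subjects) — the EEG layer adds only measurement
noise and would not change the direction of the effect.

## Known limitations

- Single-subject source amplitudes are noise-inflated (see above); the
  pipeline reports them raw, as the emulated workflow does.
- The spherical head model and atlas-fixed source locations ignore
  individual anatomy; BEM/FEM models and localization are out of scope.
- The blink model is a single stereotyped waveform; rejection thresholds
  tuned for it may behave differently on real ocular artifacts.
- Frequency/intensity deviant conditions are processed throughout but
  carry no group structure by default.
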