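# mmnpipe

Simulation and analysis pipeline for **mismatch negativity (MMN)** studies
of psychosis risk.

In an auditory oddball paradigm, rare "deviant" tones embedded in a
stream of identical "standard" tones evoke the MMN — a fronto-central
negative deflection of the event-related potential (ERP), peaking
100–250 ms after the deviant.  MMN amplitude reductions, especially for
duration deviants, are among the most reliable electrophysiological
findings in schizophrenia and appear already in clinical-high-risk
states.  Source-level analyses model the MMN as arising from bilateral
auditory-cortex generators plus a frontal (anterior-cingulate) generator,
and frontal-source deficits in particular appear to separate risk groups
and predict transition to psychosis better than scalp amplitudes do.

`mmnpipe` makes that whole analysis chain open, testable and runnable
without access to clinical data, by pairing it with a cohort-scale
synthetic-EEG generator:

- **paradigm** — the constrained pseudo-random oddball sequence: 2,400
  tones at 500 ms onset asynchrony; 79 % standards and 7 % each of
  duration/frequency/intensity deviants, ≥2 standards between deviants.
- **synthetic cohort** — 32-channel, 500 Hz raw EEG (FCz reference) for
  a four-group cohort (50 controls; 74 basic-symptoms, 74 combined,
  13 ultra-high-risk subjects; 15 transitions), with group-specific
  frontal-source MMN amplitudes, coloured sensor noise and blink
  artifacts; BrainVision export.
- **forward model** — analytic three-shell spherical head model with a
  Legendre-series dipole solution (verified against the closed-form
  single-sphere oracle) and lead fields for three fixed regional sources
  RS1/RS2 (left/right auditory cortex) and RS3 (anterior cingulate).
- **preprocessing** — average reference, 1–20 Hz zero-phase band-pass,
  500 ms epochs with 100 ms baseline, ±120 µV and EOG artifact
  rejection, 60 % subject acceptance gate, condition averaging.
- **MMN measures** — deviant-minus-standard difference waves; peak
  amplitude/latency in 150–250 ms at Fz, F3, F4, Cz, C3, C4; regional
  source waveforms via the pseudo-inverse of the lead field, with
  per-source activity = peak of the orientation-norm magnitude.
- **statistics** — group ANOVAs with Bonferroni post-hocs, correlation
  matrices, and unadjusted/adjusted logistic transition models on the
  UHR-criteria subset (source predictors inverse coded and
  z-transformed).

The model, in the field's usual notation: scalp data follow
`v(t) = G s(t) + n(t)`, with `G` the channels × (3 × 3 orientations)
lead field (µV/nAm) of the three regional sources, `s(t)` the source
moment time courses (nAm) and `n(t)` coloured noise.  Source waveforms
are estimated per sample as `ŝ(t) = G⁺ v(t)` on the average-reference
EEG channels, and the per-source activity is
`max_{150 ≤ t ≤ 250 ms} ‖ŝ_k(t)‖₂`.

See `docs/methods.md` for the generative model, calibration, numerical
choices and known limitations — including why single-subject source
amplitudes are systematically noise-inflated at this channel count.

## Worked example

Simulate a two-subject mini-cohort and run the full analysis:

```python
from mmnpipe.cohort import CohortDesign, simulate_cohort
from mmnpipe.forward import HeadModel
from mmnpipe.inverse import build_source_model
from mmnpipe.montage import build_montage
from mmnpipe.pipeline import process_recording

montage, head = build_montage(), HeadModel()
model = build_source_model(montage, head)
design = CohortDesign(
    group_sizes={"CON": 1, "BS": 1, "UHR&BS": 0, "UHR": 0},
    transition_counts={}, master_seed=42,
)
profiles, recordings, meta = simulate_cohort(design, montage, head)
for profile, raw in zip(profiles, recordings):
    gate, diffs, surface, sources = process_recording(raw, model)
    dur = sources[sources.condition == "duration"]
    fz = surface[(surface.condition == "duration") & (surface.channel == "Fz")]
    print(f"{profile.subject_id} ({profile.group}): "
          f"accepted {gate.acceptance_ratio:.1%}, "
          f"Fz MMN {fz.amplitude_uv.iloc[0]:+.2f} µV at {fz.latency_ms.iloc[0]:.0f} ms")
```

prints

```
S000 (CON): accepted 93.6%, Fz MMN -1.71 µV at 170 ms
S001 (BS): accepted 93.4%, Fz MMN -1.52 µV at 204 ms
```

93–94 % of the 2,400 trials survive artifact rejection (blinks account
for most losses), and the duration-deviant difference wave shows the
expected fronto-central negativity of one to two microvolts.  The
`sources` frame holds the corresponding regional-source activities in
nAm; at the default noise level single-subject estimates sit well above
their generative values and group contrasts are attenuated — an
intrinsic property of unregularized deep-source estimation at this
channel count that the methods note quantifies.

A command-line workflow covers the same ground stage by stage, writing
BrainVision files, QC tables and a report bundle:

```bash
mmnpipe run-all --outdir out --seed 3 --smoke   # 8-subject smoke cohort
mmnpipe simulate --outdir out ...               # or stage by stage:
mmnpipe preprocess --outdir out
mmnpipe mmn --outdir out
mmnpipe sources --outdir out
mmnpipe stats --outdir out                      # -> out/summary.json
```

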