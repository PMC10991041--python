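# Methods

## Signal model

The package treats the camera as a ballistocardiographic sensor: cardiac
and respiratory activity move the body surface, and those motions modulate
the reflected intensity the camera integrates over a facial ROI. The raw
observable is the ROI-mean luma trace, sampled at the frame rate. Within
the trace, respiration occupies roughly 0.25–0.8 Hz (15–48 breaths/min)
and the pulse 1.5–4.2 Hz (90–250 beats/min — the plausible range for the
primates this method targets); illumination drift and sensor noise occupy
the rest of the spectrum. All processing operates on this one-dimensional
trace; no skin-color (photoplethysmographic) information is used, which is
what makes the approach viable for densely haired, strongly pigmented
animals.

## Pipeline stages and parameters

**Color conversion.** RGB is converted to YCbCr with the conventional
studio-swing matrix; the multiply acts on RGB scaled to [0, 1] and the
offset [16, 128, 128] is on the 0–255 scale, so Y spans [16, 235]. Two
presets exist: `"paper"` (the default, coefficients 65.841 / −39.797 /
−18.2214 in three entries) and `"bt601"` (the ITU-R BT.601 values 65.481 /
−37.797 / −18.214). The difference is in the third decimal and is
immaterial downstream, since only the temporal variation of Y is used.

**Tracking (MOSSE).** A correlation filter learned in the Fourier domain,
with Bolme-style preprocessing (log, zero-mean unit-norm, Hann window) and
eight random affine augmentations at initialization. Defaults: learning
rate η = 0.125, Gaussian target σ = 2 px, denominator regularization
ε = 1e−5, peak-to-sidelobe ratio threshold 5.0 for declaring target loss.
The filter is translation-only (no scale term), the update uses the patch
at the newly located position, and the ROI for intensity extraction is the
tracked box itself. There is no re-detection after loss: segments are
truncated, and only loss-free runs of at least 100 s (`min_segment_s`)
enter validation. A deliberate relaxation: a recording that never lost the
target is analyzed even when shorter than 100 s (down to one HR window),
since the strict rule exists to exclude loss-corrupted stretches, not
short clean clips.

**Band-pass.** Third-order Butterworth, applied forward–backward
(`sosfiltfilt`) so the effective response is the squared magnitude and the
phase is exactly zero — detected peak times stay aligned with any
reference trace. Applying the cardiac band twice changes a passband tone
by < 4% (ripple squared), which the tests assert.

**CEEMDAN.** Implemented directly: envelope sifting with cubic splines
through local extrema, mirror extension of the two outermost extrema at
each end, Cauchy stopping criterion 0.2 (max 50 sifting iterations). The
complete-ensemble construction perturbs the running residual at stage *k*
with the *k*-th EMD mode of each white-noise realization, scaled to
`noise_std × std(residual)`, extracts one mode per realization, and
averages; subtracting each stage's mode from the residual makes
reconstruction exact by construction (observed error ~1e−16 relative).
Defaults: `noise_std = 0.2` (relative), `ensemble_size = 100`,
`max_imfs = 9`, fully seeded. The test suite and acceptance runs use
ensemble sizes of 8–40 where the full 100 would add runtime without
changing outcomes; the default remains 100.

**Cardiac IMF selection.** Candidates are IMFs whose dominant frequency
(Hann periodogram peak with parabolic interpolation) lies in the cardiac
band. Noise-assisted decompositions can split one oscillation across
neighbouring modes — a documented artifact of envelope sifting with
injected noise; prototyping the improved-CEEMDAN variant showed the split
persists there too. The selector therefore merges all candidates whose
dominant frequency agrees within 15% of the strongest in-band candidate
back into a single component and reports the lowest merged index. On
band-limited input this yields IMF 1, the nominal behaviour; the index
moves past 1 only when the first mode is out-of-band noise. If no IMF is
in-band the segment is declared unusable rather than guessed at.

**Pulse statistics.** Peaks: local maxima with minimum separation
`60/max_bpm` s and prominence ≥ 0.3 × the trace standard deviation (the
detector's own parameters; the counting formula `HR = 60·p·F_r/n` then
fixes the windowed rate). Windows are non-overlapping, 10 s by default,
which quantizes a window's HR to 6 BPM steps; a window with no detected
peak reports missing (NaN), not zero. Interbeat intervals outside ±25% of
the mean *raw* interval (computed once, not iterated, per segment) are
discarded as artifacts of missed or spurious peaks.

**Validation metrics.** Session mean error % is defined on session means,
`100·|mean(video) − mean(ref)|/mean(ref)` — the reading that reproduces
the worked arithmetic 100·|152.7 − 153.1|/153.1 = 0.26%. The absolute
value is used (signs are not compared). Pearson r is computed on windowed
HR series paired by start time (±0.5 s alignment tolerance); at least ten
paired windows are required, and a constant series yields r = NaN rather
than an error so the other metrics survive. The KS test uses the exact
two-sample distribution at small sample sizes and the asymptotic
Kolmogorov distribution (effective n = n_a·n_b/(n_a+n_b)) at large ones;
the crossover follows scipy's default and the two agree to well under a
percent where they meet. A 10,000-permutation oracle in the tests confirms
the exact p to within 0.02 on 30-draw samples.

## Synthetic generator

`SynthSpec`/`make_video` render a textured face patch on a flat
background. The patch's luma is modulated by
`A_c·sin(φ_hr(t)) + A_r·sin(2π f_rr t)` with defaults A_c = 1.0 and
A_r = 0.5 intensity units on the 0–255 scale (deliberately subtle, the
regime the method claims), per-pixel Gaussian noise (default σ = 0.5),
global sinusoidal illumination drift (default amplitude 2.0 at 0.1 Hz)
and an optional integer motion path for the patch. The cardiac phase
integrates a scalar or piecewise heart-rate schedule; with the optional
`hrv_std` (default 0) successive beat intervals get independent Gaussian
jitter, and `make_ppg` places its reference pulses on the *same* seeded
beat sequence, so video and reference share ground truth. Amplitudes are
specified on the luma scale (the generator converts to the equal-RGB pixel
increments that produce them). All randomness flows from one seed;
fixtures are regenerated at test time, never stored.

What the generator does **not** emulate: physiological pulse morphology
(systolic/diastolic shape, dicrotic notch), skin-color variation,
non-rigid facial motion, camera compression artifacts, and realistic
illumination spectra. Passing tests therefore demonstrate that the
pipeline recovers a known modulation under noise, drift and rigid motion —
not that it handles every failure mode of real enclosure footage.

## Problem sizes

Default test/acceptance conditions: 110 s recordings at 25 fps, 160×120
frames with a 48×48 face patch, heart rates 96–180 BPM, per-pixel noise up
to 8 intensity units (ROI averaging over 2304 pixels keeps the trace-level
SNR above 5 dB), sway up to 10 px. The end-to-end recovery check runs 20
such recordings; the acceptance script runs 12 and adds validation against
synthetic reference traces at `hrv_std = 0.05` s.

## Known limitations

- **Interval quantization vs the KS test.** At 25 fps, interbeat intervals
  are quantized to 40 ms. When the true beat-to-beat spread is comparable
  (SDNN ≲ 100 ms), the KS test between video intervals and a 100 Hz
  reference detects the quantization mismatch itself once a session
  provides ~200+ intervals, driving D to ~0.15–0.2 and p toward 0 even
  though means, spreads and windowed HR agree closely. The acceptance
  script reports the KS D/p it actually measures under these conditions;
  capturing fine-grained variability needs a higher frame rate.
- **No re-detection.** After target loss the tracker is not re-seeded;
  long occlusions simply end the segment.
- **Translation-only tracking.** Head rotation or approach/retreat changes
  appearance and scale; the filter adapts through its running average but
  the box size is fixed.
- **Band-limited rates.** Heart rates outside 90–250 BPM are outside the
  cardiac band-pass and invisible to the pipeline by design.
- **MP4 decode** requires an imageio video plugin; frame directories are
  the dependency-free path.
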