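# Methods

## The measurement model

The analysis treats motion as change: for a frame *img_i* and a reference
*img_ref*, the image |*img_i* − *img_ref*| is bright wherever structure
moved and black where nothing changed, and its mean grey value is a scalar
proxy for how much tissue displaced between the two time points. No
optical flow, tracking, or segmentation is involved; consequently the
output is a *relative* measure in arbitrary intensity units — valid for
kinetics and for comparisons within a recording (and across recordings
made under identical optics and exposure), but not an absolute length or
force.

Two traces derive from the same primitive:

* **Contraction trace** — a fixed reference frame, chosen in diastole.
  Values accumulate displacement relative to the relaxed state, so the
  trace rises during contraction and returns to baseline on relaxation.
* **Velocity trace** — reference = previous frame; values measure
  displacement per interframe interval. Index 0 has no predecessor and is
  defined as 0 so both traces stay length-aligned with the stack.

Assumptions: the camera and the sample mount are stationary (rigid drift
of the whole field reads as motion); illumination is constant (global
brightness modulation reads as motion everywhere); and, for amplitude
interpretation, moving structure must keep overlapping its reference
position — see *Saturation* below.

## Automatic reference-frame selection

The relaxed reference is found from the velocity trace: each frame is
scored by the mean of |velocity| over a centered window of ±`window`
frames (default 5, i.e. an 11-frame window), and the global minimum of
that smoothed score wins, ties going to the lowest index. The windowing
makes the choice robust to a single spuriously quiet frame inside a
contraction. The default half-width of 5 frames corresponds to 25–70 ms at
typical 70–200 frames/s recordings — short relative to a diastolic
interval, long relative to shot noise.

## Noise masking

Camera noise contributes a constant offset to every mean difference and
dilutes amplitudes by the non-moving background area. The mask isolates
pixels that move above the noise floor in three steps: (1) the maximum
projection, over the whole recording, of the difference stack against the
reference; (2) a binary threshold at the projection's mean grey value plus
one population SD, *strictly* greater; (3) restriction of every mean to
mask pixels.

Two numerical choices deserve note. The strict inequality makes a uniform
projection (a static or globally-flickering recording) yield an *empty*
mask, which is raised as a degenerate-mask error rather than silently
analyzing everything; the pipeline then downgrades to unmasked analysis
with a prominent warning (configurable to hard-fail). And restriction —
mean over mask pixels — differs from multiplying the stack by the binary
mask and averaging the whole frame only by a constant factor (the mask
coverage). Restriction keeps amplitudes independent of how much dead
background the field of view happens to contain, which is the point of the
mask; the price is that masked amplitudes are normalized per recording
(each recording's own mask area), so *cross*-recording amplitude
comparisons should use unmasked traces or multiply the masked trace by its
logged coverage. The parameter-recovery validation therefore runs the
noiseless amplitude grid unmasked.

## Saturation and the reliability check

Displacement is read from the area of changed pixels, which grows with
offset only while the moving structure still overlaps its position in the
reference frame — beyond its own extent (or beyond the period of a
repetitive internal texture) the difference image stops growing and
amplitude saturates, while timing parameters remain valid. Since velocity
is the time derivative of displacement, the rectified first difference of
the contraction trace, |Δcontraction|/Δt, should overlap the velocity
trace when no saturation occurs. The pipeline computes their Pearson
correlation as the *overlap score* and flags suspected saturation below a
configurable threshold (default 0.8; a convention, not a measured
constant). On clean synthetic beats the score is ≈ 1.0; the striped
test cell driven past its stripe period drops to ≈ 0.67.

For repetitive biological texture (organized sarcomeres), a Gaussian blur
of the frames before differencing (σ = 10 px is the recommended setting)
suppresses the texture and restores amplitude linearity; blurring the
frames rather than the difference images is deliberate, since the texture
is a property of the frames.

## Beats and kinetic parameters

The field does not define contraction onset and end operationally on such
traces, so this package fixes a convention and exposes it: a beat is a
maximal excursion above `baseline + threshold_fraction × (max − baseline)`
(default fraction 0.10); the onset is the last sub-level sample before the
peak walked back to the nearest local minimum (strict descent, so flat
diastolic stretches stop the walk immediately), and the end is the
symmetric forward walk. Peaks closer than `min_rr` (default 0.25 s, a
240 /min ceiling — raise for zebrafish) to a larger peak are suppressed.
Per beat: amplitude = peak − baseline, t₁ = peak − onset, t₂ = end − peak,
contraction duration = t₁ + t₂ by construction, R-R = time to next peak
(absent for the last beat). Beats truncated by the recording edges are
dropped and logged.

Baselines: the global baseline is the 5th percentile of the trace, robust
to short diastolic intervals. *Fast mode* instead assigns each beat the
trace value at its onset local minimum — the diastolic level immediately
preceding the upstroke — which tracks drifting baselines and near-
sinusoidal high-rate traces where no common diastolic level exists. On
slow, well-separated beats the two agree to within the trace's resolution.

Rhythm statistics summarize successive peak-to-peak intervals: mean R-R,
rate = 60/mean, and the coefficient of variation (population SD / mean) as
a scalar irregularity index.

## Sampling-rate requirements

t₁ and t₂ are quantized at the frame interval, so a 50 ms upstroke sampled
at 25 frames/s (40 ms/frame) carries tens of milliseconds of error while
200 frames/s recovers it exactly; recordings of fast cardiac upstrokes
should exceed ~70 frames/s. The validation measures this by decimating one
200 frames/s synthetic movie, which isolates sampling from rendering.

## The synthetic generator

The generator emulates the geometry of the classic validation inputs, not
their photorealism:

* **Block** — a bright square on black background translating out-and-back
  at two programmed speeds (x, y, or diagonal), integer-snapped so the
  difference signal is *exactly* proportional to offset and the
  plateau-velocity ratio of a (v, 2v) movie is exactly 2. One hold frame
  at each turnaround provides true zero-motion frames. Ground truth:
  per-frame offsets, swept-pixel set, quiescent frames.
* **Artificial cell** — an ellipse (default semi-axes 42 × 34 px in a
  128 px frame) whose both semi-axes shrink by A·p(t) pixels, where p(t)
  is a raised-cosine ramp up over t₁ and down over t₂, repeated n beats at
  period R-R with beats centered in their period. The raised cosine is a
  canonical smooth profile chosen once; the linearity claims tested are
  profile-independent. The boundary is anti-aliased (sub-pixel coverage
  shading) because temporal-parameter recovery needs sub-pixel boundary
  motion; frames are then quantized to integer grey levels on the 8-bit
  scale so fixtures round-trip bit-exactly through TIFF. The repetitive
  variant adds an internal stripe pattern (period 5 px) that contracts
  with the material, provoking saturation at amplitudes beyond the period.
* **Noise and drift** — additive zero-mean Gaussian pixel noise (clipped
  to the valid range, seeded) and a linear diastolic intensity drift in
  grey levels per second.

Default study conditions used by the validation suite: amplitude grid
{3, 6, 9} px with t₁ ∈ {50, 100, 200} ms and t₂ ∈ {100, 200, 400} ms at
150 frames/s, 2 beats at 1 Hz; block contrast 200 grey levels with noise
σ = 40 (contrast-to-noise 5) over 10 noise seeds. These sizes keep every
pipeline run on a laptop CPU in seconds while leaving the measured
quantities comfortably inside their tolerances.

What the generator does *not* model — and hence what passing tests do not
establish about real data: optical physics (defocus, exposure-time
dependence of amplitudes, shading), sample drift, heterogeneous and
three-dimensional deformation fields, and biological beat-to-beat
variability. Amplitude units remain arbitrary throughout; converting to
force or shortening requires a per-setup calibration that is out of scope.

## Known limitations

* No motion direction or vector field — the measure is scalar by design.
* Whole-field drift or illumination flicker is indistinguishable from
  contraction; recordings should avoid both.
* Amplitudes saturate for motion beyond structure extent or texture
  period; the reliability score warns but cannot correct this.
* Masked amplitudes are per-recording units (see *Noise masking*).
* AVI/MP4 input requires an ffmpeg-capable imageio plugin at run time;
  TIFF stacks and image directories need none.
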