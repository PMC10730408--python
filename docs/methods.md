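# Methods

## Overview

`larvascreen` implements a high-throughput behavioral phenotyping analysis
for 6 dpf larval zebrafish arrayed in 9 mm wells of a 100-well plate. The
pipeline has five stages: (1) a queryable encoding of the two-hour
stimulus paradigm, (2) pose extraction from grayscale video frames,
(3) swim-bout detection and post-stimulus response classification, (4) a
94-metric behavioral vector per larva, and (5) mutant-versus-sibling
screening statistics. A synthetic-cohort generator with known ground truth
drives every stage so the full chain is testable without recorded video or
genotype data.

## The behavioral paradigm

Four assay blocks run in fixed order:

| Block | Stimuli | Recording |
|---|---|---|
| VMR | lights off 10 min (unrecorded), lights on 8 min, lights off 8 min | continuous, 20 fps |
| LF | 15 light flashes, 500 ms, 30 s ISI | 500 ms/stimulus, 500 fps |
| DF | 5 trains of 14 dark flashes (1 s; ISI 30 s for train 1, 10 s after); trains 1, 3, 5 recorded | 1 s/stimulus, 500 fps |
| ASR | 10 low + 10 medium (20 s ISI); 10 × [PPI1, PPI2, PPI3, PPI4, High] (20 s ISI); 30 high at 1 s ISI | 200 ms/stimulus, 500 fps |

PPI1–PPI4 are high-intensity acoustic pulses preceded by a low/medium
prepulse with a 50 or 300 ms lead. ISIs are interpreted onset-to-onset
(the standard convention in the startle literature, and the only reading
under which the 1 s-ISI habituation train is well defined). Unrecorded
stimuli stay in the timeline with `recorded=False` so habituation indices
are unambiguous. Acoustic intensities are ordinal (low/medium/high); no
physical calibration (dB, m/s²) is modeled.

## Tracking

Frames are background-subtracted (clipped at zero: the larva is brighter
than the IR background), Gaussian-blurred, and thresholded; the larva is
the largest connected component (area ties broken by lowest label in
row-major order) and its position the intensity-weighted centroid. Blur
sigma (1.0 px) and threshold (10 intensity units) are configuration
parameters with defaults tuned on the rendered fixtures; the source videos
published no values.

Five tail points are placed by stepping 5 px at a time along the blurred
body image from the centroid, each step choosing the direction (within a
±106° forward arc, with parabolic sub-grid refinement) that maximizes the
interpolated intensity. The initial direction is the brighter of the two
body ends probed at 11 px — beyond the head radius — which selects the
tail because it is the longer extension. Orientation is the angle of the
vector from the first body point to the centroid (the choice of direction
only affects the sign of orientation changes, which are reported as
magnitudes). Curvature is the sum of **unsigned** angles between
successive segments of the centroid-plus-tail-points polyline; unsigned
because every downstream rule is a one-sided magnitude threshold.

Missing frames (no supra-threshold pixels) propagate as gaps; a response
window with more than 20% missing frames is excluded from event
extraction (configurable; the original dropout policy is unpublished).
Pixel coordinates are 0-based, x rightward, y downward; the pixel scale is
10 px/mm, so a 9 mm well has a 45 px radius.

## Bouts and response classification

A bout starts at the first of ≥ 2 consecutive frames with centroid
displacement > 0.7 px and ends at the frame preceding the first 2
consecutive frames at or below that threshold; movement contributes to
kinematics only within bouts. A bout still above threshold when the series
ends is kept and flagged truncated. Movement onset inside a response
window reuses the bout criterion at the block frame rate (the only
movement definition the analysis specifies).

Classification, with strict inequalities throughout (equality falls to the
lower class; an ASR latency of exactly 20 ms — possible at 500 fps — is an
LLC):

* **LF**: react if max curvature > 0.5 rad and latency > 15 ms; movements
  at ≤ 15 ms are "too early". No O-bend class exists for LF.
* **DF**: O-bend if max curvature > 1.75 rad; react if 0.5–1.75 rad; same
  too-early gate.
* **ASR**: SLC if max curvature > 0.8 rad and latency < 20 ms; LLC if
  > 0.8 rad and latency ≥ 20 ms; react if 0.5–0.8 rad. The too-early gate
  is published for LF/DF only and is off for ASR by default
  (`too_early_applies_to_asr`).

## The 94 metrics

60 VMR (10 base metrics × 6 bins: first minute, last minute and full span
of lights-on and lights-off; a bout belongs to the bin containing its
start), 9 LF, 11 DF, 14 ASR. The event assays share a nine-metric summary:
response frequency, no-movement frequency, and means of latency, maximum
bend, maximum angular velocity (rad/frame at the native 500 fps),
orientation change (wrapped to [0, π]), displacement, distance, duration.
Feature means are taken over all events passing the movement and latency
gates, not only over classified responders. DF adds O-bend frequency and
O-bend habituation; ASR adds SLC/LLC frequencies, the sensitivity index,
PPI and startle habituation.

Derived indices:

* habituation (DF) = 1 − (O-bend freq over the last 14 recorded flashes ÷
  freq over the first 14); the unrecorded trains cannot contribute, so
  "first/last 14" map to recorded trains 1 and 5.
* habituation (ASR) = 1 − (SLC freq over the last 10 stimuli of the
  1 s-ISI train ÷ SLC freq over the 10 no-prepulse high stimuli at 20 s
  ISI). Those ten baseline stimuli — the "High" events inside the PPI
  repetitions, the only high-intensity 20 s-ISI stimuli in the paradigm —
  also anchor PPI, the sensitivity index and the nine ASR summary metrics.
* PPI = 1 − (SLC freq over the 10 PPI4 stimuli ÷ baseline SLC freq).
* sensitivity index = trapezoidal area under SLC frequency at ordinal
  intensities 1, 2, 3 (arbitrary units, since physical intensities are
  uncalibrated).

The ratio indices are implemented as `1 − a/b` — the convention under
which complete suppression scores 1 for any baseline — rather than the
typeset `(1 − a)/b`; `literal_ratio_formulas=True` restores the literal
reading. Both habituation and PPI are undefined (missing) when the
baseline frequency is zero. The well's "outer rim" is radial distance
beyond 2/3 of the well radius (configurable; no published boundary).
Missing values propagate as missing and are never zero-filled.

## Screening statistics

Homozygous mutants are compared with siblings (wild types + heterozygotes;
configurable to het-vs-wt for lines with gross homozygous defects) by
two-tailed unpaired Student's (pooled-variance) t tests per metric, per
experiment. Metrics with p < 0.05 in **two independent experiments** pass
the reproducibility filter. Values are then normalized within experiment
by the mean sibling value (absorbing run-to-run variation), pooled, and
re-tested with a Bonferroni threshold of 0.05/94 (m stays 94 even when
some metrics are missing for a line). Effects are reported as
mutant−sibling mean differences in sibling SD units on the pooled
normalized data, the scale of the screen heatmaps; significant cells are
masked ('#'). A single-experiment path (used when a second run is
impossible) skips the reproducibility filter and is flagged in the output
provenance. Numerically constant groups are resolved explicitly (t = 0,
p = 1 for equal means; a zero-variance, unequal-means pair is reported as
the degenerate 0-limit) rather than letting rounding noise produce
spurious t statistics. One-way ANOVA (with pairwise pooled-t summaries)
serves multi-genotype contrasts such as double-mutant comparisons.

## The synthetic cohort generator

A cohort is ~50 larvae from a heterozygous incross (Mendelian 1:2:1
wt:het:mut), each genotype carrying a parameter set:

* spontaneous bouts: Poisson counts per VMR phase (defaults 30/min in
  light, 60/min in dark — the dark-phase elevation characteristic of the
  assay), placed without overlap via the uniform-spacing construction with
  a 150 ms refractory gap; log-normal speeds (median 0.05 px/ms) and
  durations (median 250 ms);
* stimulus responses: Bernoulli with probability
  `p · (1 − h)^(k−1) · (1 − ppi)`, where p is the kind/intensity baseline
  (dark flash 0.95, light flash 0.8; acoustic 0.1/0.5/0.9 at
  low/medium/high), h the per-stimulus habituation rate (default 0.06)
  applied within decaying trains, and the PPI factor (default strength
  0.6) applies to prepulsed stimuli. Habituation decays across the whole
  70-flash DF series (k = 1…70) and within the 30-stimulus 1 s-ISI
  acoustic train; the widely spaced LF and 20 s-ISI acoustic blocks do not
  decay. Responses draw a class (acoustic: SLC 0.85/LLC 0.15; dark flash:
  O-bend 0.9/react 0.1), then latency and peak curvature from truncated
  normals whose bounds keep the draw on its class's side of the
  classification boundaries (SLC latency mean 10 ms < 20; LLC/O-bend
  means 45/60 ms > 20), so latent labels are recoverable and
  classification accuracy on latent responses exceeds 0.99.
* responses preempt spontaneous bouts in their window, keeping ground
  truth unambiguous.

Two output levels share the same latent draws. The **trajectory path**
synthesizes poses: response curvature follows a raised-cosine pulse whose
grid-aligned peak equals the drawn amplitude exactly, and tail points are
built with the total bend spread equally over the four joints, so the
tracking-side curvature recovers the drawn value exactly. The **event
path** feeds the latent records directly through the same classification
and metric code, skipping pose synthesis; it exists because screen-scale
calibration (hundreds of cohorts) would be dominated by 500 fps pose
synthesis. In the event path the VMR well-position statistics are drawn
from the uniform-in-well stationary distribution (mean radius 2R/3, rim
occupancy 1 − (2/3)²) instead of integrating a path.

The frame renderer draws a Gaussian head blob plus a tapered tail along
the posture on a dark background; the head is offset so the rendered
intensity centroid coincides with the pose centroid (which is what the
tracker estimates, and mirrors the real animal, where the head dominates
body mass).

What the generator does **not** emulate: biophysically realistic swimming
(beat-and-glide dynamics, tail oscillation during bouts), per-larva
parameter heterogeneity within a genotype, multi-larva occlusion, optics
(vignetting, reflections at well edges), or circadian drift. Passing tests
therefore demonstrate that the analysis recovers the statistical structure
it assumes — not that it is robust to every artifact of real video.

## Closed-form expectations and calibration

Recovery checks compare cohort metric means with exact expectations under
the generating parameters. For the ratio indices the per-larva estimator
`1 − L̂/B̂` is handled exactly: L and B are independent Poisson-binomial
counts, so `E[1 − L̂/B̂ | B > 0] = 1 − E[L̂] · E[1/B̂ | B > 0]`, with the
baseline distribution enumerated by dynamic-programming convolution.

Screen calibration simulates null screens (all genotypes share
parameters) through the full two-experiment procedure; the family-wise
false-positive rate over 200 screens of 50 larvae is required to stay at
or below 0.05. Power is checked by planting a 3-sibling-SD shift on one
metric in the mutant group of both experiments and requiring detection and
a masked heatmap cell.

## Numerical choices and problem sizes

* Boundary ties: strict inequalities exactly as the rules state.
* A response window's drawn latency is clamped so the movement fits the
  recording window; the tracker-measured latency is the drawn latency
  quantized up to the 2 ms frame grid.
* Test and acceptance problem sizes are chosen so the full suite runs on a
  single CPU in minutes: 10,000 random series for the bout oracle, 200
  larvae for parameter recovery, 200 null screens for calibration, 9
  rendered poses spanning curvature 0–2.4 rad for tracker accuracy.
  These sizes give Monte-Carlo error comfortably inside the asserted
  tolerances.
* Tail tracing uses cubic image interpolation; bilinear interpolation
  leaves ±0.3 px lateral wiggle that the unsigned angle sum rectifies into
  a ~0.3 rad upward bias on straight bodies.

## Known limitations

* The tracker's curvature estimate carries a smooth corner-rounding bias
  of about −0.07 rad per radian of true bend (max ~0.17 rad at 2.4 rad)
  from the Gaussian rendering/blur chain; it is well inside the 0.2 rad
  fixture tolerance but is systematic, not noise.
* Student's t on ratio-index metrics (habituation, PPI) inherits their
  skewed small-sample distributions; the screen's reproducibility filter
  plus Bonferroni keeps the family-wise rate controlled, but single-metric
  p-values for these indices should be read cautiously.
* The single-experiment screen path has no reproducibility protection by
  construction and is flagged in provenance for that reason.
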