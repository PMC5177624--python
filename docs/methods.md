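# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `stepthrow`, in the order data flows through the
package.

## Coordinate conventions and units

All quantities are SI.  The laboratory frame is right-handed with the
origin at the midpoint between the medial foot borders at stance:
x = medio-lateral (ML), y = antero-posterior (AP, forward), z = up.
Left-sided steps are reflected about the AP axis and relabelled as
right-sided before any analysis, so "+ML" always means "toward the
stepping side"; every scalar result is reflection-invariant by
construction and the pipeline tests assert it exactly.  Events are stored
as times in seconds from recording start and converted to sample indices
only at the point of use, which keeps the mixed 1000 Hz (force) / 200 Hz
(marker) rates from ever sharing an index space.

Targets are specified in polar form about the stepping foot's start:
medial/central/lateral at 35 cm and 0°/25°/50° from the AP axis (rotating
laterally), proximal/central/distal at 25° and 20/35/50 cm.  All four
central-to-peripheral displacements are 15 cm to the nearest centimetre
(the on-ray jumps exactly, the equal-length jumps as the chord
2·35·sin 12.5° = 15.15 cm).

## Analysis pipeline

**Filtering.** Zero-lag (forward–backward) 2nd-order Butterworth, 30 Hz
for force/CoP and 15 Hz for markers.  The two passes square the magnitude
response, so the gain at the cut-off is exactly 0.5 — a closed-form test
oracle.  Zero-phase filtering is acausal: a transient's influence leaks a
few milliseconds backward, which bounds how sharply any onset can be
timed.

**CoM kinematics.** Acceleration is the summed plate force divided by
body mass, with the mean over quiet stance (recording start to target
illumination; at least 250 ms required) subtracted per axis, so standing
still reads as zero acceleration.  Velocity is the cumulative trapezoid
of (ML, AP) acceleration with v = 0 at pre-step initiation; the
quiet-stance assumption makes earlier anchors equivalent up to noise.
Jerk is the first central-difference derivative of the filtered
acceleration (one-sided at the ends); differentiating the 30 Hz-filtered
signal keeps the scheme consistent with the zero-lag pipeline.  CoM
*position* is deliberately not estimated — double integration over a
whole trial is unreliable — and vertical velocity is not analyzed.

**Combined CoP.** The force-weighted average of the per-plate CoPs;
plates carrying less than 1 N of vertical load contribute nothing (the
stepping plate during swing).  An optional extra low-pass before CoP
differentiation is exposed (`cop_vel_smooth`, off by default) since
whether additional smoothing is applied there is a free choice.

**Events.** Initiation: earliest time after illumination at which the ML
CoP velocity toward the stepping foot exceeds 5 cm/s at *every* sample of
a 50 ms window ("exceeds" strict; boundary equality does not count —
configurable by changing the threshold).  Foot lift: first stepping-side
vertical force sample below 1% of body weight, where body weight is the
measured quiet-stance summed vertical force (fallback: mass·g with
g = 9.81 m/s²).  Landing: first post-lift time at which ML, AP and
vertical hallux speeds are simultaneously below 2 cm/s (per-axis
comparison, not the 3-D norm).  Final foot position: mean of the three
stepping-foot markers at the landing sample.  Jump trials are excluded
when the trigger fired at or before initiation, or when led-on fell
within 150 ms of foot lift (the margin is not dictated by the protocol;
150 ms = the 100 ms physiological minimum plus a 50 ms observation
buffer, exposed in config and logged per trial).

**Modulation latency.** Constant-central trials of a subject, aligned at
detected initiation, define at every aligned sample the mean and sample
covariance of (ML, AP) jerk.  The envelope is a *dispersion* ellipse —
boundary at the χ²₂ quantile of the level (5.99 at 95%) — because
individual trials are tested for membership; a mean-confidence ellipse
would shrink with the number of reference trials and flag essentially
every trial immediately.  A small-sample prediction variant
(F-quantile with (1+1/n) inflation) is available by config.  Singular
per-sample covariances are floored at 1e-10 of the mean eigenvalue scale
and flagged.

A jump trial already outside the envelope when the new target lit up is
excluded from latency statistics (reported separately).  Otherwise the
divergence search starts 100 ms after led-on — the shortest latency at
which visuomotor corrections of leg trajectory or ground-reaction force
are considered physiologically possible — and the latency is the start of
the first excursion that (i) persists 80 ms, where returns inside the
envelope shorter than 20 ms are bridged, and (ii) reaches four times the
squared boundary radius within those 80 ms.  Rules (i)–(ii) exist because
a literal "first sample outside a 95% envelope" over a 100–250 ms search
window is structurally biased: even for an unmodulated trial drawn from
the reference law, each effectively independent sample has a 5% chance
of lying outside, so first-crossing times accumulate and pull the
recovered latency tens of milliseconds early (measured −20 to −45 ms on
synthetic cohorts).  Genuine modulations overshoot the boundary by two
orders of magnitude and stay out through foot lift, with ~10 ms dips
whenever the corrective jerk crosses zero — hence bridging short gaps and
confirming by magnitude discriminate cleanly, and because the reported
latency is the *start* of the qualifying excursion, neither rule delays
it.  With these defaults the recovered pooled median tracks injected
medians of 150/223/350 ms within ±12 ms, with 96–100% detection and a
3–7% at-jump exclusion rate.

**Group statistics.** 2-D outcomes (CoM velocity at foot lift, foot
placement) are paired within subject by subtracting each subject's
constant-central mean, then tested with one-sample Hotelling's T² against
zero (the multivariate paired t-test): T² = n x̄ᵀS⁻¹x̄,
F = (n−p)/(p(n−1))·T² on (p, n−p) df.  Group means are displayed with
Hotelling confidence ellipses
{μ : n(x̄−μ)ᵀS⁻¹(x̄−μ) ≤ p(n−1)/(n−p)·F₀.₉₅}.  Normality is screened with
Mardia's multivariate skewness (n·b₁,₂/6 ~ χ²₄) and kurtosis
((b₂,₂ − 8)/√(64/n) ~ N(0,1)) in their classical asymptotic forms —
small-sample corrections are deliberately omitted; at n = 10 the screens
are indicative only.  The kurtosis expectation uses the maximum-likelihood
covariance (divisor n), under which E[b₂,p] → p(p+2).  Mardia's skewness
is computed through the whitened third-moment tensor (O(n·p³)) rather
than the n×n Gram matrix, so large Monte-Carlo samples are cheap.
Univariate temporal variables go through a one-way repeated-measures
ANOVA; Greenhouse–Geisser ε = tr(A)²/((k−1)tr(A²)) with A the
double-centered condition covariance (ε ≡ 1 for k = 2); Huynh–Feldt is
not implemented.  Families of comparisons are Bonferroni-controlled at
α = 0.05.  Latency enters its ANOVA as the per-subject median (the
distribution is skewed); this is configurable in principle by aggregating
differently upstream.

## The synthetic-trial generator

The generator emulates the statistical structure of the stepping
protocol, not musculoskeletal dynamics.  Per 16 trials and subject: 8
constant-central, 1 constant trial to each peripheral target, 1 jump
trial to each peripheral target — so 160 trials give 120/40
constant/jump, P(jump | central illuminated) = 1/3, peripheral selection
probability 0.083 within the constant condition, sides balanced in every
cell, order shuffled under the seed.

**Vertical force / CoP.** The stepping plate loads as a quarter-sine over
the first 45% of the base pre-step duration, then unloads quadratically
so that the 1% body-weight crossing lands exactly at the scheduled
foot-lift time; the trailing plate carries the complement.  Per-plate
CoPs are fixed under the foot centres, so the combined CoP shift toward
the stepping foot — and the 5 cm/s initiation signature — emerges from
the load transfer itself.  The 80 N trigger latency is an *outcome*: a
truncated-normal draw (location solved so the truncated mean equals the
96 ms target, SD 43 ms) sets the loading amplitude that makes the noisy
force difference cross 80 N at that latency; the trigger is then found on
the generated signal, so "below 80 N strictly before the trigger" holds
by construction.  Led-on follows 16.5 ms later.

**Horizontal force.** One raised-cosine (sin²) net-force pulse per axis
integrates to `throw_gain · target_vector` (default gains −0.35/s ML,
+0.75/s AP: the body is thrown away from the stepping foot and forward,
at ~0.28 m/s AP for the central target).  The pulse duration is a
*subject-level* tempo template (75% of the subject's mean pre-step);
trial-to-trial duration variability (SD 77 ms within, 45 ms between
subjects, 561 ms mean) is realized in the unload/lift timing instead.
This matters: per-time-point envelopes presuppose that reference trials
are phase-aligned, and tying the pulse to the per-trial duration
decorrelates the traces and invalidates the comparison.  In jump trials a
raised-cosine AP braking pulse (25 N, 80 ms — the initial non-specific
"braking" response) and per-axis corrective raised-cosines spanning
modulation onset to foot lift add exactly the velocity change the new
target requires.  Raised-cosine onsets make jerk build from zero, as a
neuromuscular transient does; a pulse family with a jerk step at onset
would leak backward through the zero-phase filter and bias detected
latencies early by tens of milliseconds.

**Timing.** Modulation onset = led-on + a log-normal reaction latency
(median 223 ms, log-SD 0.5, giving an IQR near 160 ms).  Foot lift in
jump trials is delayed by N(69, 55) ms, and additionally deferred when a
late reaction would otherwise put the modulation within 120 ms of foot
lift — the generator guarantees the event ordering initiation < trigger
< led-on < modulation onset < foot lift < landing, at the cost of a
slightly heavier prolongation tail for slow reactions.  Draws that would
not fit the recording are capped.

**Noise.** Sensor noise is band-limited Gaussian added at each channel's
native rate: 0.05 N per force axis, 0.05 mm per CoP axis (80 Hz band),
0.1 mm per marker axis (20 Hz band) — instrument-grade figures for
laboratory force plates and active-marker systems after anti-alias
filtering.  On top of this, a slowly varying motor-execution fluctuation
(3.5 N per horizontal axis, 1–3 Hz band) is ramped on at initiation, so
quiet stance stays quiet (double-integrated drift before illumination is
under 1 mm) while pre-step jerk variability is dominated by smooth,
trial-coherent structure — the regime in which a per-time-point envelope
detector is meaningful.  Swing is a rigid minimum-jerk translation of the
foot markers (10s³−15s⁴+6s⁵; vertical bell 64s³(1−s)³, 5 cm peak)
beginning 80 ms before the force-defined lift (heel-off precedes the 1%
crossing), landing at the subject's ideal position (target centre plus a
fixed 5 mm-SD subject bias, emulating self-defined accuracy) plus 8 mm
placement scatter.

**Ground truth** records, per trial, the true initiation, trigger,
led-on, modulation onset, foot lift (threshold rule applied to the clean
sampled force), landing (threshold rule on the clean hallux track),
landed position and CoM velocity at foot lift — all in the
right-canonical frame so they compare directly with the pipeline's
reflected analyses.

## What the generator does and does not establish

Passing parameter recovery on synthetic cohorts shows that the detectors
and statistics measure what the generator injected under realistic noise,
sampling rates and trial counts.  It does not certify performance on real
recordings, whose jerk variability need not be amplitude-like, whose
anticipatory waveforms are richer than sine-family pulses, and whose CoP
dynamics couple to the CoM through inverted-pendulum mechanics the
generator deliberately omits.  The trailing foot's second step, EMG, and
vendor motion-capture formats are out of scope; trial data move through a
plain-text bundle (YAML metadata + CSV series, 12-significant-digit
floats, byte-deterministic writes).

## Problem sizes

Default test and acceptance runs use scaled cohorts — 2 subjects × 32
trials for structural checks, 6 subjects × 80 trials per injected-latency
condition for parameter recovery, 10,000 Monte-Carlo replicates for test
size and ellipse coverage — sizes at which Monte-Carlo error is well
below the tolerances being asserted.  The full default protocol
(10 × 160) runs through `stepthrow run-all` in a few minutes.
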