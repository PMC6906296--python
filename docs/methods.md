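# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic cohort does and does not emulate, and the
design choices made where the underlying protocol left the design open.

## Signal models and extractors

### Gait events

Assumption: during walking, the ankle's sagittal angular velocity is close
to zero while the foot is loaded (stance) and shows a single dominant
positive pulse during swing. The extractor:

1. band-passes the signal with a 4th-order zero-phase Butterworth filter,
   0.5–6 Hz (stride rates and their low harmonics);
2. finds mid-swing peaks above `peak_threshold_deg_s` (default 40 °/s, well
   above postural noise and well below swing peaks of 200–400 °/s) with a
   minimum separation of 0.4 s (no physiological stride is faster);
3. brackets each peak with the last upward / first downward crossing of
   `edge_threshold_deg_s` (default 10 °/s);
4. refines both edges from the pulse's half-amplitude width measured on a
   10 Hz low-passed copy: for a symmetric unimodal pulse the half-amplitude
   points sit exactly one quarter width inside each edge, so
   `edge = half-crossing ∓ width/2`, with all crossings linearly
   interpolated for sub-sample resolution.

Step 4 exists because a fixed absolute threshold on the flanks is
systematically *inside* the true pulse edges by ≈ T_swing·acos(1−2θ/A)/2π
per edge — about 50 ms for a 0.4-s swing at θ/A = 10/250 — which would
swamp the two-sample-period accuracy the rest of the pipeline is built to.
The refinement removes this bias without giving up the robustness of
threshold-crossing detection (`refine_edges=False` reverts to the bare
scheme). On noise-free synthetic bouts the refined detector recovers step
counts exactly and per-stride phase times to under 3 ms at 100 Hz; with
10 °/s additive noise, counts stay within ±1 and median stance within
0.05 s.

Stance of stride *i* is `toe_off(i+1) − heel_strike(i)`; the last swing of
a bout therefore has no stance. Session summaries use medians (robust to
occasional mis-bracketed strides) and pool both ankles; summaries over
fewer than 3 complete strides are flagged low-confidence. "Mobility
activity time" is interpreted as the duration of the timed-up-and-go task
window (mean over the three repeats) — the time the subject needs to
complete the mobility task.

### Turns

A turn is a sustained yaw-rate excursion: the 1.5 Hz low-passed |ω| must
exceed 15 °/s, the episode is expanded outward to the 5 °/s crossings,
gaps < 0.2 s are merged, and episodes with |∫ω dt| < 45° are discarded
(steering corrections are not turns). The span is then shrunk to the raw
signal's 5 °/s support because zero-phase low-passing smears sharp edges
outward and would otherwise dilute `mean velocity = |angle|/duration`.
The angle itself is always the trapezoid quadrature of the **raw** yaw
over the detected span, so filter gain cannot bias it; the peak is the raw
max |ω|. Signed angles are kept internally; summaries use magnitudes.

A single turn has no velocity spread, so the session-level max/mean/std
velocity features are across-turn aggregates: mean of per-turn maxima,
mean of per-turn means, and the population standard deviation of per-turn
means (a clinic session has at least three TUG turns). Mean velocity is
`|angle|/duration` rather than mean |ω| (config-switchable): it is
insensitive to how much near-zero padding the detected span contains.

### Postural sway

Two input paths. A 2-D displacement track (mm) is consumed directly —
per-axis path length Σ|Δx| and max–min excursion in the mediolateral and
anterior–posterior axes; this path admits exact analytic oracles (a
sinusoid of amplitude A at frequency f for time T has 1-D path 4AfT and
excursion 2A). The realistic path takes tri-axial acceleration: gravity is
the window-mean vector, horizontal components are band-passed 0.1–2 Hz
(postural sway band) and doubly trapezoid-integrated with a linear detrend
after each integration. Detrend-after-integration was chosen over
high-passing the displacement for its simpler contract. Known limitation:
filter/integration edge transients inflate the max–min excursion estimate
(path length stays within ~10 % on analytic input); both metrics remain
linear in the input amplitude, which is what the correlation analysis
uses.

### Activity classification (free-living)

The original study used a proprietary deep neural network; downstream
analyses need only the labels, so a transparent threshold classifier with
the same label set stands in. Per 5-s window of the wrist stream:
accel-magnitude variance below 0.01 (m/s²)² → idle; dominant frequency of
the demeaned magnitude spectrum in 0.6–1.4 Hz (stride-rate band) with the
dominant bin holding > 25 % of 0.5–4 Hz band power → walking; 1.4–3.5 Hz
with magnitude std > 2 m/s² → running; anything else → other. Labels are
3-window majority-smoothed and merged into bouts. This is a stand-in
contract (≥ 90 % window accuracy on the synthetic schedule), not a claim
about the original classifier. Wear detection: accel variance above a
noise floor or any gyro activity. Days need ≥ 10 strides for a gait median
(medians over fewer are unstable).

### Sleep and fatigue

Inter-beat intervals during tagged sleep are ectopic-filtered (outside
300–2000 ms, or > 20 % off an 11-beat running median) and cut into 5-min
epochs (≥ 30 beats each, else invalid); per epoch: mean IBI, SDNN, RMSSD.
REM staging is an explicit seed-free rule — RMSSD > 32.5 ms ⇒ REM — being
the midpoint of the generator's planted NREM/REM short-term variability
scales (20 vs 45 ms), followed by 3-epoch majority smoothing. Epoch length
and the threshold are documented constants, not fitted at run time. Leg
movements: 0.5–10 Hz band-passed accel magnitude, enveloped by a 0.25-s
moving RMS (raw oscillation zero-crossings would fragment one movement
into many sub-threshold pieces), events ≥ 0.5 s above 0.1 m/s², merged
within a 5-s refractory period, reported per hour of tagged sleep. PVT
features exclude false starts and report the mean delay over the whole
test and the first 1/3/5/7 valid challenges.

### Statistics

MSFC-4 z-scores are referenced to this cohort (the classic choice when no
external reference population is named; an external reference table is
accepted). Timed tests enter negated so higher always means better; the
9HPT alternative convention (z of 1/time) is behind `nhpt_mode`. Spearman
ρ is the Pearson correlation of midranks with pairwise deletion; its
p-value uses the two-sided t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df,
which reproduces published (ρ, p) pairs at n = 23 to the printed precision
— evidence it is the convention used in practice. Storey q-values estimate
π̂₀ on the λ grid 0, 0.05, …, 0.90 with a cubic-polynomial extrapolation
to λ = 1, clipped to (1/m, 1]; q(p₍ᵢ₎) = min over the tail of π̂₀·m·p₍ⱼ₎/j.
With π̂₀ = 1 this is exactly Benjamini–Hochberg (verified against a
brute-force implementation). One q-value family = all features against one
clinical measure, matching the per-column significance convention of the
reported tables. The k-day variability curve draws random contiguous
k-day blocks and reports the RMS deviation of block medians from the
full-period median, per subject and cohort-averaged.

## The synthetic cohort

A latent disability d ~ Uniform[0, 1] drives every planted parameter
through linear effect functions `base + slope·d + N(0, sd·noise_scale)`,
with signs mirroring the observed feature–disability correlation
structure: stance time 0.55 + 0.35·d s, stride rate 0.95 − 0.35·d Hz
(|rate slope| = stance slope keeps swing = 1/rate − stance strictly
increasing), peak turn velocity 220 − 120·d °/s, sway amplitudes
≈ 1 + 6·d mm, TUG duration 8 + 8·d s, PVT delay 280 + 120·d ms, HRV RMSSD
45 − 20·d ms, REM fraction 0.24 − 0.10·d, leg movements 2 + 8·d per hour,
idle fraction 0.45 + 0.25·d. EDSS is a quantile map of (noisy) d onto the
half-step grid 1.0–6.5; MSFC-4 subtests are linear in d with noise sd set
to 25 % of their full-range effect. The default stance noise sd (0.12 s)
was calibrated once, by Monte-Carlo on the closed-form plan
(`planted_population_spearman`), so the planted population
Spearman(stance, composite) is ≈ −0.6; with `noise_scale = 0` every
planted feature is a deterministic strictly monotone function of d and
the sample correlation is exactly ±1.

Signals: raised-cosine pulses for swing and turn (smooth, band-limited,
analytically integrable — ∫A(1−cos 2πt/T)/2 dt = AT/2, so A = 2·angle/T);
sway as low-pass-filtered Gaussian walks scaled to a target RMS (or exact
sinusoids for oracles), emitted as displacement with acceleration derived
as the second numeric derivative on demand — the balance extractor is
thereby testable on both its easy and its hard input; per-beat IBIs as an
AR(1) (φ = 0.8) around stage-dependent means with innovation sd
rmssd·√((1+φ)/2), which plants the stage RMSSD exactly; sleep movements as
enveloped 3 Hz bursts. Free-living days are compressed wear streams built
from idle/walking/other blocks drawn with probabilities set by the planted
idle fraction (every day keeps at least one walking block — a day with
literally zero walking would make the daily gait median undefined).
Ground truth (event schedules, stage sequences, block schedules, planted
parameters) is emitted alongside every signal.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: soft-tissue and mounting artifacts, sensor drift
and clock skew, pathological gait asymmetries beyond parameter shifts,
turning strategies other than a single smooth pulse, real sleep
architecture (only two-stage cycles), PPG beat-detection errors beyond
simple ectopics, and any missing-data or non-wear patterns beyond
timestamp gaps. Compliance behaviour (high/declining/low weekly wear) is
planted directly as weekly hours, not derived from simulated non-wear.

## Numerical choices

* All filters are Butterworth applied forward–backward (`sosfiltfilt`):
  zero phase, so event times are not lagged.
* Threshold crossings are linearly interpolated between samples; this is
  what lets a noise-free cohort survive extraction with strictly monotone
  feature maps (sample-grid quantization would create ties).
* Windows are half-open [start, end); annotation slicing rounds sample
  boundaries toward the window interior.
* Degenerate inputs: an all-zero gait trace yields an empty stride list
  (not an error); an empty turn list yields a count-0 summary; a constant
  variable makes Spearman ρ undefined (NaN, excluded from q-families);
  zero-variance z-score references raise with the subscore named.
* Determinism: every generator takes a seed; cohort generation spawns
  per-subject child seeds from a `SeedSequence`, so cohorts are
  reproducible and subjects independent.

## Problem sizes

Defaults mirror the study conditions: 23 subjects, in-clinic protocol with
a 30-s balance window, three TUGs and a 2-min walk at 100 Hz, 56 free-living
days, 7-h nights. Tests and the acceptance script run the same code on
deliberately smaller instances (shortened walk tests, compressed 10–60-min
days, 6-h nights, 2–8 day free-living periods) chosen so the full suite
exercises every path at meaningful sizes; all thresholds and effect sizes
are the defaults above, never per-test values.

## Known limitations

* The auto (annotation-free) segmenter separates quiet from active spans
  by energy only; stand/balance/sit cannot be told apart without
  annotations and share one merged quiet window, labelled by protocol
  order with reduced confidence.
* Sway excursion from the acceleration path inherits integration edge
  transients (see above); between-subject comparisons remain valid through
  amplitude linearity.
* The REM rule is a two-class HRV threshold, not polysomnography; its
  accuracy contract is defined only against the generator's stage
  parameters.
* Turn detection assumes the device yaw axis is the body-vertical gyro
  axis per the location mapping (chest and ankle: axis 2); other mountings
  need the config override.
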