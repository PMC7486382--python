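# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and the limits of what the tests demonstrate.

## Coordinate model

All positions are screen pixels with the origin at the top-left, x
rightward, y downward, phone in portrait (height ≥ width). A
`ScreenGeometry` (width, height, px/cm, viewing distance) performs every
unit conversion. Pixel density is a required, device-specific input —
there is no device table — so cm-valued results are conditional on the
configured device. Visual angle uses the full-extent chord,
`deg = atan(extent_cm / distance_cm)`; at 25–40 cm this maps a 0.46 cm
error to 1.05–0.66 degrees. The default viewing distance when a trace
carries none is 30 cm, the midpoint of the comfortable 25–40 cm phone
range. Off-screen estimates are kept; snapping onto the screen rectangle
is an explicit, idempotent step applied where an analysis requires valid
screen locations.

## Gaze network

Two convolutional towers with **shared weights** process the two
128×128×3 eye crops (left crop mirrored so both eyes share chirality).
Design points that the architecture description leaves open, and how
this implementation resolves them:

* **Padding** — "same" on all conv layers. This yields the spatial trace
  128 → 64 (conv s2) → 32 (pool) → 16 (conv s2) → 8 (pool) → 8 (conv s1)
  → 4 (pool), i.e. 2048 features per tower, and a total of 166,294
  trainable parameters (~170 K). Valid padding would give ~142 K and is
  rejected.
* **Dense wiring** — of the five hidden widths (128, 16, 16, 8, 4), the
  first three form the landmark pathway (input: the 4 corner landmarks
  normalised by frame width/height), the last two the combination
  pathway on concat(tower_L 2048, tower_R 2048, landmarks 16) = 4112
  inputs. The 4-unit layer is the penultimate ReLU whose activations
  feed personalization; the head is linear (unbounded coordinates).
* **Crop geometry** — square crop centred on each eye's corner midpoint
  with side 1.5× the inter-corner distance (keeps brow/sclera context),
  zero-padded at frame edges, bilinearly resized.
* **Loss and optimiser** — mean Euclidean distance in screen cm (so
  training error is directly the reported error metric), Adam with a
  100-step linear warmup and step decay (×0.3 at 50% of steps, ×0.1 at
  80%), batch 16, all randomness seeded. The linear head carries a
  constant output offset initialised to the mean training target, so an
  untrained network predicts the screen centre; this removes a large
  constant from the optimisation.
* **Dying-ReLU protection** — the dense funnel is narrow (8 then 4
  units), and from-scratch training on small corpora can silence most of
  it permanently, capping the network at one or two active pathways. Two
  optimizer-level safeguards keep it healthy without touching the
  architecture: the warmup above (the violent first Adam steps are what
  kill units), and periodic revival — every 50 steps (during the first
  80% of training) any dense unit inactive across a 64-frame probe batch
  gets fresh He-initialised incoming weights, a small positive bias, and
  cleared optimizer state. Fine-tuning, which starts from a trained
  network, disables both.
* Targets are trained in cm (converted through `ScreenGeometry`), and
  the network is implemented in NumPy with explicit backpropagation;
  convolution is an im2col matrix product, and the first layer skips the
  (unused) input gradient.

## Personalization

Fine-tuning updates all layers, with "convergence" operationalised as
early stopping: evaluation on an interleaved hold-out split of the
calibration session every few steps, stop after 10 non-improving
evaluations, restore the best weights. The interleaved split assigns
every fifth frame per marker to hold-out so both halves cover the
screen. The lightweight head is one ε-insensitive support-vector
regressor per coordinate (RBF kernel, C = 20, ε = 0.01 cm, kernel scale
by the median heuristic on pairwise feature distances); per-coordinate
regressors were chosen over a single multi-output model for simplicity
and because the coordinates have unrelated error structure. Both pooled
(multi-user) and per-user fine-tuning are supported — the desk-scale
study treats the base cohort training as the pooled stage and fine-tunes
per-user. Evaluation snaps estimates to the screen, median-aggregates
per distinct marker, and reports cm error per marker; participants with
mean hold-out error above 1 cm (strict inequality) are excluded.

## Event detection

The raw 30 Hz trace is smoothed with a bilateral filter: Gaussian
weights in time (σ = 100 ms, truncated at ±3σ) and in Euclidean screen
distance (σ = 200 px), which attenuates jitter while preserving saccade
steps. Velocity is a central difference (one-sided at the ends) of the
smoothed trace, converted to deg/s via the chord arctangent; samples at
or above 22 deg/s are saccades (equality counts as saccade — the
boundary convention is arbitrary but fixed and tested). Runs are broken
at inter-sample gaps above 100 ms, with no interpolation across gaps.
Fixation runs shorter than 100 ms (measured on the raw run span) are
dropped; surviving events are padded to the midpoints toward their
neighbouring samples, because the sample grid quantises the true
transition times — this halves the boundary bias at 30 Hz and keeps
events non-overlapping. Saccade amplitude uses the flanking fixation
centroids when both exist, else the boundary samples. Per-stimulus
aggregation discards the first 800 ms after stimulus onset (the eye is
still in flight), snaps, then takes the componentwise median.

## Task protocols

* **Prosaccade** — 800 ms central fixation, then a pulsating target
  (60→168 px, 3 pulses over 1000 ms) uniform over the screen; latency is
  the time from onset to the first saccade-labeled sample; trials with
  latency < 80 ms would be anticipatory and are flagged by convention.
* **Pursuit** — circle of radius `distance·tan(7°)` centred on screen,
  clockwise (y-down convention) from the right-most point; the box is
  the concentric square of the same half-extent and period; the zig-zag
  sweeps top-left to bottom-right. The default period (8 s) and the box
  geometry are free choices, configurable. Tracking error is the mean
  gaze–target distance in cm at time-matched samples.
* **Search** — a jittered rejection-sampled display with exactly one
  target differing in orientation (Δθ) or colour intensity; minimum
  centre spacing 3× item radius. The target-hit radius defaults to 1.5×
  item radius (no criterion is standard; it is configurable).

## Saliency and reading analytics

Fixation maps round locations to the nearest pixel; saliency maps apply
a Gaussian with σ = "blur width" in px (24 default; 67 ≈ 1° of mobile
viewing angle). The σ-interpretation of "filter size" is a documented
choice. Blurring reflects mass at the grid boundary, so it is linear and
conserves total mass exactly. Gaze entropy is the Shannon entropy (bits)
of the normalised map at its native grid resolution; absolute entropies
are therefore resolution-conditional, and the grid shape is always
reported alongside. Heatmap agreement uses Pearson correlation at the
pixel level and over per-object mean saliencies (≥ 3 masks); baselines
are a shuffled-stimulus pairing and a centred Gaussian.

Reading gaze is mapped to page coordinates by step-interpolating the
scroll log (`page_y = screen_y + offset(t)`); fixations spanning a
scroll event should be split at the event before mapping. The
height-normalized dwell share of a region label is
`(dwell share / height share)` renormalised across labels to sum to
100% — chosen because the two-region report pairs must be complementary;
this definition is invariant to splitting regions within a label. Task
difficulty is % incorrect per task; associations use Spearman rank
correlation with a seeded permutation test (average ranks under ties).

## Synthetic data

The generator exists to make the whole pipeline testable with known
ground truth; realism is explicitly a non-goal.

* **Eye frames** — a 256×160 grey face strip with two bright eyeballs
  (r = 30 px) whose dark irises (r = 11 px) are displaced from the eye
  centres by `gain · (gaze − screen centre + user bias)` with
  gain = 1.7 px/cm, plus additive Gaussian pixel noise (σ = 0.02) and
  fixation jitter (σ = 0.05 cm). The radii and gain are sized so that
  (a) the worst-case displacement (corner gaze plus maximum bias) stays
  inside the eyeball and (b) the signal is strong enough for the network
  to learn reliably from ~1,200 frames — the generator's purpose is a
  learnable stand-in, and a signal too subtle for desk-scale training
  would defeat it. The linear gaze→iris model makes the
  estimation problem solvable by the small network at desk scale while
  exercising crops, landmarks, training and the SVR head. Synthetic
  users differ by a constant gaze bias ~N(0, 0.8 cm) per coordinate —
  the base model cannot remove an individual's bias, personalization
  can, which is exactly the effect under study. What this does **not**
  emulate: head pose, lighting, blinks, eyelid occlusion, camera optics;
  passing tests bound pipeline correctness, not real-world accuracy.
* **Scanpaths** — fixations are stationary with jitter and log-normal
  durations (median ≈ 280 ms); saccades follow minimum-jerk profiles
  with main-sequence durations (≈ 21 ms + 2.2 ms/deg), guaranteeing
  super-threshold mid-flight velocity so I-VT ground truth is well
  defined; prosaccade latencies are a shifted gamma (shift 80 ms,
  shape 4) with mean 210 ms; pursuit trails the target by a configurable
  lag (default 100 ms); traces are sampled at 30 Hz with σ = 20 px
  position noise.
* **Search behaviour** — before each fixation the target pops out with a
  probability that rises sigmoidally in contrast; otherwise the searcher
  fixates a random unvisited item and recognises the target on landing.
  High contrast therefore ends search in ~1 fixation independent of set
  size; low contrast degenerates to a serial scan that grows with set
  size — the two classic effects, present by construction and recovered
  through the full detection pipeline.
* **Reading cohort** — per task, the generative relevant-dwell share
  decreases linearly in difficulty (80% at difficulty 0, slope −0.55 per
  % incorrect, σ = 3 noise) and answers are wrong with probability equal
  to the difficulty; 10 tasks span difficulties 0–60%.

## Study sizes and numerical choices

The desk-scale studies are sized to run in minutes on one CPU: base
training uses 20 synthetic users × 60 frames (700 Adam steps), the
held-out user's session has 400 frames over 40 markers, fine-tuning runs
up to 150 steps with early stopping, and behavioural studies use
100–200 trials per condition. Float32 is used throughout the network;
the Euclidean loss is smoothed with a 1e-12 epsilon at zero; SVR feature
scales use up to 400 subsampled points for the median heuristic;
permutation tests use 5,000–10,000 shuffles. Degenerate inputs (empty
datasets, < 2 distinct markers, zero-mass maps, constant maps, unsorted
traces, overlapping intervals or regions) are rejected with explicit
errors rather than silently handled.

## Known limitations

* The renderer's linear gaze→iris mapping makes personalization easier
  than on real faces; the measured order-of-magnitude error reduction on synthetic
  users is an upper bound on what the same pipeline achieves on camera
  data.
* At 30 Hz, saccade latency and fixation boundaries are quantised to
  ~33 ms; the midpoint padding removes the systematic half of that bias
  but not the jitter.
* Absolute gaze entropies depend on grid resolution and are not
  comparable across resolutions.
* Landscape orientation, multi-display setups, blink/microsaccade
  detection and face/landmark detection are out of scope; landmarks are
  an input.
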