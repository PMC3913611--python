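# Methods

This note documents the models, conventions and design choices behind
`prefdyn`, in the order data flows through the package.

## Normalization

Each frame is registered by a similarity transform with no rotation:
all landmarks are scaled uniformly by `100 / d` about the left-eye
center (`d` = distance between the two eye-cluster means) and the
left-eye center is then placed at (100, 100). Both canonical
conditions — left-eye center at (100, 100) and inter-eye distance
100 px — hold simultaneously and the map is idempotent.

*Why scale about the eye center?* A transform that first translates
the left eye to (100, 100) and then scales about the image origin
would displace the eye center again; composing scale-about-center with
the translation is the only order in which both conditions can hold at
once. This composition is this package's resolution of an ambiguity in
the procedure it implements, not a claim about the original study's
code.

Head roll is deliberately left uncorrected — the procedure registers
position and scale only — so descriptors see genuine rotational
movement as mobility.

Frames whose eye centers are closer than 1e-9 px are rejected as
degenerate (guards the division without excluding any realistic
geometry).

**Middle third.** Frame selection keeps 0-based indices
`[floor(n/3), floor(2n/3))`. For `n` not divisible by 3 this keeps
between `floor(n/3)` and `ceil(n/3)` frames; boundary conventions at
this granularity do not affect the statistics appreciably, and the
half-open rule is deterministic and order-preserving.

## Descriptors

Per frame: center = landmark mean, dispersion = mean Euclidean
distance to the center. Per video: `d_std` (population standard
deviation of the dispersion series) and `d_maxmin` (its range). Per
landmark: the same two summaries of the landmark's
distance-to-frame-center series, concatenated over the 66 landmarks as
[66 ranges, 66 standard deviations] — a 132-d feature vector.

Conventions and numerics:

- **Population standard deviation** (divide by n) everywhere, for the
  video statistic and the per-landmark features alike. One convention,
  applied uniformly and encoded in the tests.
- **Order-independent reductions.** The statistics are functions of
  the multiset of frames, not of their order. Standard deviations sort
  the values before the two-pass computation so that any frame
  permutation yields a bit-identical result (floating-point summation
  is order-sensitive otherwise).
- `frame_center`/`frame_dispersion` accept arbitrary point counts so
  closed-form geometries (e.g. square corners) can be used in tests;
  the video-level path enforces the full 66-landmark set.
- Descriptors operate on the frames they are given; normalization and
  middle-third selection are composed by the caller (the pipeline does
  preprocess → describe), keeping each stage separately testable.

## Baseline predictor

The decision rule compares one statistic across the pair. Domains
split by the direction of the preference–mobility link: for cartoons
and paintings the higher-mobility video is predicted preferred; for
people and animals the link is reversed (more motion at the less
appealing animate stimulus), so the lower-mobility video is predicted
preferred. Exact ties (|s1 − s2| ≤ 1e-12) deterministically predict
slot 1 and are flagged; ties are measure-zero on continuous data.

Accuracy per domain is compared against a fair coin using the exact
one-sided binomial tail P(X ≥ k), X ~ Binomial(n, ½), via
`scipy.stats.binomtest`; domains are evaluated independently with no
multiplicity correction. The correlation between per-pair human
accuracy and the algorithmic difference score is Pearson by default
(`method="spearman"` available) — the choice between the two is not
determined by the problem, so both are exposed.

## Learned pipeline

Pair features are differences of the two videos' 132-d vectors; labels
are +1 when slot 1 is preferred, −1 otherwise. The classifier is a
scikit-learn pipeline: `StandardScaler` → `PCA` (variance fraction
0.95 by default, full SVD) → `SVC` with RBF kernel.

Standardization before PCA is an addition of this package: the range
half and the std half of the feature vector live on different scales,
and an unscaled PCA would be dominated by the larger one.

Hyperparameters γ ∈ {1e-4 … 1e2} and C ∈ {1e-2 … 1e4} (log-spaced, 7
points each, configurable) are tuned by fitting on 80% of the training
pairs and scoring on the held-out 20% (stratified, seeded); the
pipeline is then refit on the full training set with the winners. The
80/20 internal split, the 10-fold / 10-repetition default protocol,
the 95% normal-approximation CI over repetition means, and the PCA
fraction are this package's defaults, all exposed in `SvmConfig`.

Every fitted model carries an audit record (which pair keys entered
any fitting step, the internal split, the grid scores); cross-validation
reports include per-fold train/test keys so leakage checks can verify
that standardization, PCA and tuning never saw held-out pairs.

## Synthetic data generator

The generator emulates the structure the method assumes, with these
components and defaults (template pixels; inter-eye distance 120 px,
i.e. a face filling a 640×480 webcam frame):

| parameter | default | meaning |
|---|---|---|
| `fps` | 24 | recording rate (Hz) |
| `durations` | 3 s (people/paintings/animals), 7 s (cartoons) | video length per domain |
| `rigid_jitter_sd` | 1.0 px | per-frame whole-face translation SD |
| `landmark_noise_sd` | 0.5 px | i.i.d. localization noise SD |
| `mobility_base` | 2.0 px | baseline burst amplitude |
| `mobility_gap` | 2.0 px | extra amplitude for the mobility-linked video |
| `burst_rate_hz` | 2.0 /s | expression bursts per second |
| `burst_duration_range` | 6–18 frames | burst length (0.25–0.75 s) |
| `burst_landmark_span` | 12–24 | contiguous landmarks per burst |
| `boundary_surge` | 2.0 | jitter/noise multiplier in first and last thirds |

Noise magnitudes are order-of-magnitude choices for webcam-quality
landmark tracking (sub-pixel to ~1 px at this face scale); the true
noise level of any real dataset is unknown, and all values are exposed
in `SimConfig`. Two named regimes exist: `strong_signal()` (gap 8 px,
noise 0.3 px — the signal clearly dominates, used to demonstrate
decoder recovery) and `null_signal()` (gap 0 — preference carries no
mobility information, used for chance-level checks).

Modeling choices worth recording:

- **Bursts are a rate, not a count.** Expression events are modeled at
  a fixed temporal rate (bursts/second), so the 7 s cartoon videos
  carry proportionally more events than the 3 s videos. Burst onsets
  are *stratified* — one burst per equal time slot, uniform within the
  slot — so events cover the whole recording, including the
  middle-third analysis window, in every realization; with fully
  uniform onsets a video could by chance express none of its mobility
  inside the analyzed window, contradicting the generator's own
  semantics (the pair's mobility difference is its defining property).
- **Radially outward displacement.** Burst displacements push the
  affected landmarks away from the face center under a raised-cosine
  envelope, guaranteeing that bursts increase frame dispersion — the
  simplest generative link between "mobility" and the D statistics.
- **Surge applies to jitter and noise, not bursts.** Rigid translation
  alone is invisible to the (translation-invariant) descriptors, so
  the onset/offset surge also scales the landmark noise; this is what
  makes the middle third measurably calmer than the full video.
- All randomness flows through explicitly passed
  `numpy.random.Generator`s seeded per (seed, domain, target, pair);
  no global state, bit-identical outputs for identical inputs.

**What the simulator does not capture.** Real spontaneous faces have
correlated, structured motion (action units, rigid rotation,
speech-like mouth cycles), non-Gaussian and temporally correlated
tracking noise, occlusions, and inter-subject variation in face shape
and expressiveness. Passing tests on synthetic data therefore
demonstrates that the *pipeline* is correct and that the decoding rule
recovers the encoded mobility link — not that real videos are this
decodable. On the real task, accuracies far below the strong-signal
regime are expected.

## Problem sizes used in checks

The test suite and the acceptance script size their simulations to
exercise the full design while remaining quick: the complete factorial
design (384 pairs / 768 videos) for decoder recovery and design
counts; 500 pairs for null-accuracy checks; 200 videos for descriptor
oracles; reduced designs (~40 pairs, 5 folds × 3 repetitions, 3×3
hyperparameter grids) for cross-validation hygiene checks.

## Known limitations

- No rotation correction: head roll contributes to the descriptors.
- The baseline's domain reversal is hard-coded from the known
  direction of the preference–mobility link; applying the package to a
  new domain requires choosing a direction.
- The CSV dialect is this package's own; real datasets need a reader
  plugin (`read_landmark_video(reader=...)`).
- The binomial comparison treats pairs as independent; pairs sharing a
  target are not strictly independent in the real design.
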