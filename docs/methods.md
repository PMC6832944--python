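# Methods

## The problem and the approach

Large surveillance studies record raw triaxial acceleration (in g, 80–100 Hz)
from wrist-worn devices. Supervised activity classifiers trained on one such
dataset transfer poorly to others, and labelling free-living data is
expensive. `acticlust` implements the alternative: an *unsupervised* model of
broad physical-behaviour types that is fitted once, stored completely as
plain text, and blindly reapplied to independent recordings so that cluster
memberships stay comparable across studies and populations.

The pipeline is:

1. **Windowing.** Labelled activity bouts are trimmed by 30 s at each end to
   drop transitional movement; the signal is cut into 10-s non-overlapping
   (tumbling) windows, the trailing partial window discarded. A window
   carries a label only when it lies entirely inside a single trimmed bout —
   this prevents mixed-label windows; windows straddling boundaries stay
   unlabelled.
2. **Features.** Per sample: SMV = √(x²+y²+z²); ENMO = max(0, SMV−1)
   (negatives flattened); per-axis orientation angles to the horizontal
   plane, angle_a = atan(a/√(b²+c²))·180/π ∈ [−90°, 90°]. Per window: nine
   order statistics per axis (max, min, mean, median, p10, p75, p90, SD,
   variance), mean/max/median ENMO, min/max/mean/median/SD of each angle,
   and the dominant frequency and its power from the periodogram of the
   window's ENMO series — 47 candidates in all.
3. **Selection and scaling.** Features correlate with an intensity-ranked
   class code; those with |Pearson r| ≥ 0.12 are retained. A canonical
   24-feature list (one frequency feature, ten magnitude statistics,
   thirteen angle statistics) is shipped so downstream use does not depend on
   rerunning selection on any particular dataset. Features are min–max
   scaled with training-set extrema; the extrema travel with the model.
4. **Clustering.** k-means with K = 10 — deliberately more clusters than the
   nine activity types, so heterogeneous behaviours can split
   (over-clustering) — k-means++ seeding, 10 restarts, Lloyd iterations to
   assignment stability. The fitted state (K, feature names, normalization
   extrema, centroids, seed) is serialized as self-describing JSON with
   full-precision decimal floats; reapplication is a pure nearest-centroid
   assignment and therefore bit-reproducible anywhere.
5. **Evaluation.** Clusters are letter-named A–J by ascending mean raw ENMO
   of their member windows, then collapsed into behaviour categories
   (default: sedentary A–E, standing/mixed/slow-ambulatory F–H, brisk
   ambulatory I, running J). Against labelled ground truth the package
   reports the purity matrix (percent of each class per cluster), category
   capture (row sums over a cluster group), average cluster purity
   ACP = (1/N)·Σᵢ Σⱼ n²ᵢⱼ/n_cᵢ, average event purity
   AEP = (1/N)·Σⱼ Σᵢ n²ᵢⱼ/n_eⱼ, their combination ACEP, daily minutes per
   category, and Bland–Altman bias/limits of agreement against a criterion
   instrument.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| window length | 10 s | long enough for ~0.1 Hz spectral resolution, short enough for behavioural homogeneity |
| transition trim | 30 s | removes posture changes at bout edges |
| K | 10 | over-clustering: more clusters than the 9 expected classes |
| restarts / max_iter | 10 / 300 | best-of-restarts by within-cluster sum of squares |
| selection threshold | 0.12 | correlations below this are treated as weak |
| LoA multiplier | 1.96 | 95% limits of agreement, sample SD (n−1) |

## Numerical conventions

- SD/variance are population moments (divide by n); percentiles interpolate
  linearly. These choices are arbitrary but fixed, and the tests pin them.
- The degenerate angle denominator (vector along one axis) resolves to ±90°
  through a two-argument arctangent; an all-zero sample is an error.
- Frequency features use the window's ENMO series (not raw SMV): the 1 g
  gravity offset otherwise dominates the DC-adjacent bins. Plain boxcar
  periodogram, no detrending, DC bin excluded, bin width 1/window-length.
  A spectrally empty window (non-DC power at FFT roundoff, ≤ 1e−20) reports
  (0, 0) by convention.
- Min–max scaling maps a constant column to 0 and does **not** clip unseen
  data: the transform stays affine so distances remain comparable.
- Assignment ties break to the lowest cluster index. An emptied cluster
  during Lloyd iteration is reseeded to the point farthest from its assigned
  centroid.
- Letter ordering ties break on the original cluster index; clusters with no
  member windows sort last.
- ACEP defaults to the literal product ACP·AEP; the diarization literature
  the statistic descends from uses the geometric mean, available as
  `acep(ct, combine="geometric")`. The discrepancy is documented rather than
  resolved.

## The synthetic-data generator

No public recordings accompany the reference purity tables, so the
`simulate` module generates labelled studies with the statistical structure
the pipeline relies on:

- **Static postures** (lying, seated, standing) hold distinct gravity
  orientations plus a slow circular wobble (one cycle per window), a small
  radial sway tone at 0.25 Hz, and white sensor noise. SMV stays near 1 g
  and ENMO near zero. The sway gives the ENMO spectrum a defined
  low-frequency peak; without it the dominant-frequency feature becomes the
  argmax of a noise floor, whose distribution depends on the sampling rate
  and would make the feature meaningless for these windows.
- **Ambulation** (three walking speeds, stairs, running) superposes an
  arm-swing sinusoid at the step cadence on the anterior–posterior axis and
  a circular orientation oscillation at the same cadence. Swing and tilt are
  phase-locked (gait drives both), and the two tilt components run in
  quadrature: with free phases, same-frequency sinusoids interfere with a
  seed-dependent amplitude and archetype feature means would not be stable
  across simulated studies. Swing amplitude increases strictly from
  household movement through walking speeds to running, so cluster intensity
  ordering is recoverable by construction.
- **Household** movement is deliberately heterogeneous — a mixture of
  chores — modelled as a two-level vigor envelope (gentle/vigorous) in
  alternating 30-s blocks aligned with the window grid, modulating both
  swing amplitude and wobble. It also carries a sway tone: in the gentle
  mode the cadence fundamental of ENMO nearly cancels (the phase-locked
  swing × tilt product moves its energy to the second harmonic), and the
  sway keeps the spectrum peaked instead of noise-dominated. Because
  household forms two tight sub-populations, the K = 10 fit consistently
  spends its extra cluster splitting household rather than an activity the
  evaluation conditions on.
- The **left-wrist** option mirrors the x and z axes, matching how the
  device frame flips between wrists.

What the generator does *not* emulate: gait harmonics beyond a single
sinusoid, realistic device noise spectra, drift or temperature artefacts,
non-wear, and between-subject variability. Passing the recovery and
portability tests therefore shows that the pipeline's machinery is correct
and stable under the assumed signal structure — not that the published
capture percentages would be reproduced on real recordings, which are not
redistributable.

## Problem sizes

The laboratory-style default protocol is ~46 min of signal (≈ 280 k samples
at 100 Hz) yielding 225 labelled windows after trimming; recovery statistics
aggregate ten independently seeded studies, and portability is assessed by
fitting on one 100 Hz study and reapplying to an independent 80 Hz study.
These sizes keep every feature of the method exercised — all ten clusters
populated, both wrists and sampling rates represented — while a full run of
the test suite and the acceptance script completes in well under a minute.

## Known limitations

- The canonical 24-feature list is shipped as data; its selection loadings
  cannot be recomputed without the original recordings, and the class
  encoding used for the published selection is unknown (we default to an
  intensity ranking).
- Letter naming by mean ENMO is a convention for comparability; any
  semantic reading of A–J (e.g. "A is lying") must come from labelled data.
- Purity statistics are known to be optimistic under strong class imbalance.
- The signal dialect assumes already-calibrated units of g; autocalibration
  and non-wear detection are out of scope.
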