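# Methods

## Pipeline overview

The detector has five stages, each an independently testable module:

1. **Labeling** (`spotvote.labeling`) — every pixel `p` whose 51 x 51 patch
   lies fully inside the image is a candidate training patch, labeled by the
   round-half-up Euclidean distance to the nearest annotated center
   (classes 0..25) or NEGATIVE if no center is within rounded distance 25.
2. **Classification** (`spotvote.classifier`) — a 27-way softmax classifier
   over patch pixels.
3. **Voting** (`spotvote.voting`) — each positive class probability is
   spread over the ring of matching rounded radius; score patches from the
   sliding-window scan are summed into a score map.
4. **Detection** (`spotvote.detection`) — greedy global-maximum selection
   with circular suppression of radius 25.
5. **Evaluation** (`spotvote.evaluation`) — rank-ordered matching of
   detections to centers within a circular range of radius 25, threshold
   sweep, maximum F-measure.

`VotingParticleDetector` wraps stages 1-5 behind the scikit-learn
estimator protocol.

## Distance quantization and adjointness

Distances are quantized by round-half-up (`floor(d + 0.5)`). The same rule
is used to rasterize rings, so labeling and voting are exact adjoints: a
particle at offset `o` from a patch center receives label `r` exactly when
the ring of class `r` covers `o`. The rings `r = 0..25` partition the
rounded-norm-<= 25 disk (2053 of the 2601 offsets of a 51 x 51 patch); the
548 corner offsets with rounded norm 26..35 belong to no ring, and a patch
whose nearest particle sits there is NEGATIVE. Sub-pixel annotation
coordinates are preserved through I/O and rounded to the nearest pixel only
at labeling time.

## Ring normalization

The classifier probability of class `r` is divided equally among the
`|ring(r)|` pixels of its ring (8r pixels for r >= 1, to within rounding of
the circle). Division conserves total vote mass — the map total equals the
summed positive-class probability over all scanned positions exactly — and
prevents large rings from outvoting small ones. The alternative that copies
the class score to every ring pixel is available (`mode="copy"`) for
comparison but is not the default. The negative-class probability casts no
votes; it still acts through the softmax by deflating the positive scores
on empty patches.

With stride 1 and a perfect classifier, an isolated particle center
receives one full unit of vote mass from each ring radius (26 units total),
and is the unique pixel lying on all rings — the basis of the oracle
localization tests.

## Patch classifier

The label of a patch depends only on the *distance* to the nearest
particle, never the direction, so the decision function is rotationally
symmetric by construction. The bundled classifier therefore uses
rotation-invariant radial features: per-ring mean and per-ring maximum
intensity for rings 0..25 plus the corner region (54 features), fed through
standardization into a multilayer perceptron (two hidden layers, 96 and 64
units, Adam, up to 150 epochs, minibatch 256, learning rate 1e-3, seeded
and deterministic). Ring means detect diffuse mass at a radius; ring maxima
detect a compact spot regardless of how little of the ring it occupies.
The same features are computable for every image pixel at once with one
convolution and one maximum filter per ring, which makes dense stride-1
scoring cheap; the filter path and the per-patch path agree to numerical
precision and are cross-checked in the tests.

The classifier is pluggable behind a one-method protocol
(`score_positions(image, centers) -> (n, 27)` scores). A raw-pixel feature
mode (`features="raw"`) exists as a fallback, and the
`OracleDistanceClassifier` emits the one-hot true label, which isolates
voting/detection correctness from learning error. The binary baseline
(`method="binary"`) uses the identical feature/MLP stack with 2 outputs;
its positive training patches are exact center crops (tolerance 0) by
default, optionally multiplied by dihedral flips/rotations and +-1 px
shifts to a requested sample count; the alternative definition "any patch
containing a center" is available via `binary_tolerance=25`.

## Synthetic data generator

The generator emulates the imaging regime the detector targets: small
bright spots with ambiguous edges on a noisy background, with deliberate
close pairs. Defaults (one image): 256 x 256 px, 30 particles rendered as
isotropic Gaussian profiles with sigma ~ N(3.0, 0.5) px (floored at 0.9),
peak amplitude U(0.4, 0.9) above a 0.08 background, additive Gaussian pixel
noise sigma 0.03, clipped to [0, 1] (saturation). 10% of particles are
placed within one spot diameter of an existing particle so their profiles
merge; the remaining particles keep >= 28 px pairwise separation — just
above the 25 px suppression radius, which is the method's intrinsic
resolution limit — and all centers stay >= 26 px from the border so a full
patch centered on any particle fits inside the image. Images are floating
point internally and 8-bit grayscale on disk.

Annotation subjectivity is modeled by displacing each training center with
an independent uniform *integer* offset on the Chebyshev square
`[-e, e]^2`, clipped to image bounds — the simplest bounded model of a
pixel "error range". Evaluation ground truth is never perturbed.

What the generator does **not** emulate: realistic microscope PSFs and
shot-noise statistics, intensity vignetting, background structure
(cytoplasm texture, out-of-focus light), aspherical or size-varying
particle populations, and densities where most particles touch. Passing
the end-to-end tests therefore demonstrates correctness of the
labeling/voting/detection machinery and learnability of the distance task
under controlled conditions — not performance on real micrographs.

## Detection and evaluation conventions

* Suppressed pixels are set to `-inf`, so they can never resurface
  regardless of the threshold.
* Equal maxima are broken by smallest row-major index (determinism).
* Suppression-disk membership uses exact (unrounded) Euclidean distance
  <= 25; the returned detections are therefore pairwise > 25 px apart.
* The input map is never mutated; detection works on a copy.
* The threshold sweep defaults to 200 evenly spaced values from 0 to the
  map maximum. Because a greedy run at a higher threshold is a prefix of
  the run at a lower one, the sweep detects once at the lowest threshold
  and truncates the ranked list — verified equivalent to re-running
  suppression per threshold — and F is defined 0 where P + R = 0.
* Match radius defaults to the suppression radius (25 px). Detections
  claim centers in rank order, each taking its nearest unclaimed center.
* Multi-image evaluation pools TP/FP/FN across images at each common
  threshold before computing P, R, F.

## Numerical choices

* Score-map accumulation has two engines: a scatter-add reference loop and
  the default per-class FFT convolution of the position/probability lattice
  with the ring kernel. They agree to ~1e-12 relative; FFT rounding can
  produce ~-1e-15 values, which are clipped to 0 to honor the
  nonnegativity invariant.
* All stochastic steps (placement, sampling, MLP initialization,
  perturbation) take explicit integer seeds; experiment replicate seeds are
  spawned via `numpy.random.SeedSequence`.
* Patch extraction forbids any padding: patch centers closer than 25 px to
  the border are neither sampled for training nor scanned at test time, so
  border pixels receive votes from fewer positions (documented behavior).

## Experiment design

Desk-scale study conditions (chosen so the full comparison runs in minutes
on one CPU): 10 training and 5 held-out test images per replicate seed,
5,000 positive + 5,000 negative training patches, stride 5 scanning, three
replicate seeds. `run_method_comparison` reports the pooled held-out
maximum F-measure per method and stride; `run_noise_robustness` retrains
both methods at each training-annotation error range (0, 5, 10 px by
default) and reports the F decrease relative to zero error.

## Known limitations

* The binary baseline's MLP responds much more sharply to center offset
  than a pooled convolutional classifier would: trained on exact center
  crops it can miss particles that fall between stride-5 grid points, and
  moderate annotation noise can *raise* its recall by acting as shift
  augmentation. Comparisons with the baseline at stride > 1 should be read
  with this in mind (stride 1 removes the grid-offset effect).
* With a 25 px match radius at native 256 x 256 scale, localization errors
  up to ~10 px are invisible to the F-measure; studies of fine localization
  should shrink the match radius or upsample images before scoring.
* The voting range is isotropic: all directions receive the same vote, so
  dense regions accumulate systematically more mass than sparse ones and a
  single global threshold trades the two off. Direction-aware voting is
  out of scope.
* Greedy suppression makes pairs closer than the suppression radius
  mutually exclusive by construction; the expected ceiling on recall under
  the default generator is 1 minus the cluster fraction.
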