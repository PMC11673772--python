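# Methods

## The problem

Automatic bait casters in aquaculture need a signal for when a school is
actually feeding.  The behavioral signature is spatial: when feed hits the
water, fish that were wandering evenly across the tank rush to the bait and
pack into one region, feed quietly there, and later disperse.  `faivar`
recognizes that signature from a sequence of per-frame binary fish
segmentation masks — it does not care how the masks were produced (a trained
semantic-segmentation network, a simple intensity threshold, or the built-in
simulator), only that each frame classifies every pixel as fish or
background.

## The statistic

Each frame is split into four equal quadrants (1 upper-left, 2 upper-right,
3 lower-left, 4 lower-right; for odd dimensions the top/left halves take the
extra row/column).  For quadrant *i* with pixel area `A_total`, fish-pixel
count `A_fish`, and largest 8-connected fish component `A_max`:

    FishAreaRatio_i = 100 · A_fish / A_total
    AreaMaxRatio_i  = 100 · A_max  / A_total
    FAI_i           = FishAreaRatio_i + AreaMaxRatio_i        ∈ [0, 200]

`FAI` (Feeding Activity Index) responds both to how many fish occupy a
quadrant and to how tightly they cluster (occluding, overlapping fish merge
into one large component, which is a feature: occlusion during feeding is
the regime the index exploits).  Ratios are percentages, so thresholds are
scale-free — resolution never matters and frames are never resized.

The temporal statistic compares each frame with the frame `L` frames earlier
(default `L = 20`):

    FAIdiff_i  = FAI_{t−L,i} − FAI_{t,i}
    AvgFAIdiff = ¼ Σ_i FAIdiff_i
    FAIvar     = ¼ Σ_i (FAIdiff_i − AvgFAIdiff)²

the *population* variance (divisor 4) of the four lagged differences.  The
subtraction order is immaterial: only the variance is consumed, and it is
invariant to a global sign flip.  `FAIvar` is near zero when the spatial
distribution is stable — calm wandering *and* quiet clustered feeding — and
spikes when the school redistributes rapidly: at feeding onset (one quadrant
surges while the others drain) and at dispersal (the reverse).

## From spikes to labels

A bare rule "feeding iff FAIvar > threshold" mislabels the two longest
stretches of a real trial: quiet mid-feeding frames (low variance, school
parked on the bait) and the dispersal spike itself (high variance, but the
meal is over).  The classifier therefore runs a three-state machine
(UNKNOWN → NON_FEEDING ⇄ FEEDING) in which above-threshold spikes are
*transitions* and below-threshold frames hold state:

* **trend** = `max_i FAI_i(t) − max_i FAI_i(t−L)`, the change of the peak
  quadrant FAI over the lag window.  Rising peak ⇒ aggregation, falling
  peak ⇒ dispersal.  Taking the max at each time separately (rather than
  tracking one quadrant's own change) keeps the sign correct during the
  brief hand-over when the emptying bait quadrant stops being dominant.
* **onset**: from NON_FEEDING (or UNKNOWN), `FAIvar > threshold` and
  `trend ≥ +√FAIvar` ⇒ FEEDING.
* **offset**: from FEEDING, `FAIvar > threshold` and `trend ≤ −√FAIvar`
  ⇒ NON_FEEDING.
* **coherence** (`|trend| ≥ √FAIvar`): the peak quadrant's change must be at
  least the RMS dispersion of the four differences, i.e. the crowded
  quadrant must be what carries the spike.  Genuine onsets and offsets
  satisfy this with a wide margin; borderline spikes whose variance comes
  from diffuse multi-quadrant drift with a near-flat peak (common in the
  tail of a dispersal) do not, and must not flip the state.  The condition
  is parameter-free.
* **one transition per spike**: after a transition fires, the machine is
  disarmed until `FAIvar` falls back below the threshold.  A spike is one
  event; without this, the tail of a dispersal spike can fire a phantom
  onset the moment a filling neighbour quadrant becomes dominant.

The first `L` frames are UNKNOWN (warm-up; the lagged difference does not
exist) and are excluded from accuracy metrics by default.  UNKNOWN resolves
to NON_FEEDING at the first post-warm-up decision unless that decision is
itself a valid onset.  `mode="raw-threshold"` exposes the bare rule for
comparison.

This state machine is an explicit reconstruction: the underlying method
specifies only the variance statistic and the threshold, and narrates the
episode structure; the transition mechanics above are this package's design,
chosen as the minimal machinery that reproduces the narrated structure
robustly (verified over 60 simulator seeds during development).

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `lag` | 20 | frames | window of the FAI difference; longer for slow-feeding species |
| `threshold` | 100 | FAIvar units (percent²) | species/deployment-specific; 50 suits small intense feeders |
| `fish_class` | 1 | palette index | for VOC-style label PNGs |
| `mode` | `state-machine` | — | or `raw-threshold` |

The lag is a frame count, deliberately not wall-clock time: capture rate is
deployment metadata (record it via `--fps-note`), not an input to the
algorithm.

## The simulator

`synthetic_sim` generates what the method assumes: N fish of elliptical
footprint in a rectangular tank view moving through WANDER → GATHER → FEED →
DISPERSE phases, rendered as the boolean union of ellipses with reflecting
boundaries, plus per-frame ground truth (GATHER and FEED are FEEDING — bait
is in the water from the start of the approach; WANDER and DISPERSE are
NON_FEEDING).

Defaults, chosen as a desk-scale version of a typical feeding trial and then
frozen: 256×256 px frame, 30 fish with semi-axes 12–18 × 5–8 px, phases
120/60/140/80 frames (400 total), bait at (192, 192) — inside quadrant 4 —
wander step 3 px/frame, gather speed 6 px/frame, feed jitter 1.5 px/frame,
disperse speed 4 px/frame, cluster radius 40 px.  Two dynamics details are
load-bearing for realism:

* each fish has a fixed *feeding station* inside the cluster, with station
  radii sampled linearly so the pack is densest at the bait itself (fish
  crowd the food); GATHER steers to the station, FEED jitters around it with
  mean reversion.  A school that instead diffused freely inside the cluster
  disk would slowly deform into barely-connected lobes whose largest
  component flickers frame to frame — slow rearrangement, not the low-motion
  clustered feeding the FEED phase represents;
* one global random stream seeded from the config, consumed in a fixed
  per-frame order (motion, then a speckle field drawn even when the speckle
  rate is zero), so enabling speckle noise never perturbs trajectories.

What the simulator does **not** emulate: water-surface optics (splash,
glare, refraction), fish-body deformation while swimming, collision
avoidance, depth/size changes, partial segmentation failures beyond i.i.d.
speckle.  Passing end-to-end tests on simulated masks therefore demonstrates
that the statistic and classifier behave as designed on the aggregation
signature they target — not that any particular upstream segmentation model
is accurate on real footage.

## ECA block

`eca_attention` implements Efficient Channel Attention as a standalone
fixed-weight computation: per-channel global average pooling, a 1-D
correlation of length-k (odd) across neighboring channel descriptors with
zero padding at the channel ends, a sigmoid gate in (0, 1), and channel-wise
rescaling.  `adaptive_kernel_size` provides the usual channel-adaptive rule
(nearest odd to `(log2 C + 1)/2`).  It is shipped as a verified numeric
building block and interface example for segmentation backbones; training a
network around it is out of scope.

## Numerical and edge-case choices

* 8-connectivity for components (diagonal fish-body pixels merge; the
  conservative "one fish = one region" choice).
* Components are found per quadrant after cropping; a fish straddling a
  quadrant border contributes one component to each side, by design.
* Empty sub-mask: all ratios 0.  Zero-area sub-mask, frames smaller than
  2×2, non-consecutive frame indices, even ECA kernels, equal render
  intensities: errors, not silent defaults.
* Dominant-quadrant ties break to the lowest index.
* All FAI arithmetic is double precision; equality with brute-force oracles
  is asserted at 1e-12 relative tolerance in the tests.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the full default simulation
(400 frames at 256×256) on five seeds, oracle-check the statistics on 1,000
random masks up to 32×32, and round-trip 100 random mask PNGs in both
grayscale and palette form; the whole suite completes in well under a
minute on one CPU.

## Known limitations

* `A_max` is a discontinuous statistic: a one-pixel bridge opening or
  closing moves it by a whole component.  The coherence condition makes the
  classifier robust to the resulting variance flicker, but the per-frame
  FAI series itself is not smooth.
* A school feeding exactly on a quadrant boundary splits its largest
  component across two sub-images, damping the FAI response; the method
  inherits this from its fixed 2×2 partition.
* Thresholds do not adapt online; species-appropriate values must be chosen
  per deployment.
* Dropped frames abort analysis (sequencing error) rather than being
  interpolated; the lag difference is only meaningful on consecutive frames.
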