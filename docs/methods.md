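# Methods

This note records the model as implemented, the parameter conventions,
the design choices made where the published description leaves room, and
what the synthetic validation scenes do and do not establish.

## Model structure and processing order

The network is a per-frame state machine over an element lattice the
same size as the (down-scaled) input frame. One processing step equals
one frame. The canonical order within a step is: frame-pair absolute
difference → second-order e-potentials → threshold → cluster filter →
update of the four direction-selective inhibitory layers → local motion
vectors → ground-shadow suppression → coherence and overstimulation
checks → risk combination → steering. The first valid e-potentials exist
at the third frame; the first two frames carry a `warm_up` flag and
report zero risk. Because the first inhibitory values are stored at the
third frame, direction selectivity is meaningful from the fourth frame
on.

Grey values are mapped linearly from the native integer range onto
[0, 9.9] without rounding (the historical working range of the
algorithm); RGB input is collapsed with ITU-R BT.601 luma weights, and
down-scaling uses anti-aliased area resampling. Frames are indexed from
0; element coordinates are (col, row) with row 0 at the top, so the
preferred direction 270° points toward the lower frame border.

## Excitation

The e-potential is the absolute difference of successive frame-pair
luminance changes. It is exactly zero for any sequence whose frame-pair
differences are constant in time — uniform illumination ramps cancel to
float round-off. The film threshold is `0.71·contrast + 0.378` by
default (Michelson contrast of the first frame unless configured
otherwise), but an explicit per-run threshold takes precedence: the
per-film values actually used in practice (0.2 for low-contrast, 0.7 for
high-contrast material) do not follow the formula, so the formula is a
convenience default, not the authority.

The cluster rule keeps an excited element only if *more than* 10 excited
elements (focal element included, the multi-agent `in-radius`
convention) lie within Euclidean distance 3 on the lattice. Counts are
taken against the pre-filter layer, making the pass synchronous and
order-independent. A consequence worth knowing: the filter is not
idempotent on sparse speckle — a second application can erode further —
but it is stable on the compact blobs it is meant to keep.
Neighbourhoods are clipped at the frame border; the image is not a
torus.

## Danger zone and risk

Membership is enumerated once: Euclidean distance to the configured
center ≤ radius, and the element's row inside the central band
`[0.25·H, 0.75·H]` (exclusion bands are fractions of the full frame
height). `R_coll` weights the zone sum of supra-threshold e-potentials
by the excited fraction w/s. `R_dist` adds `gain/d_k` (gain 10) over
members with e-potential above 0.5 — on the thresholded layer this is
equivalent to demanding both the film threshold and the fixed 0.5 level
— and `0 < d_k < r/2` in element units; an element exactly at the center
is excluded. `R_dist` joins the total only when more than 15 members
qualify. All percentage and count comparisons in the network are strict
(`>`), including the 40% overstimulation rule, the 50% coherence rule,
the 20% shadow rule and the steering threshold 6.

Suspension (overstimulation or coherent motion) zeroes the reported
total risk for that frame rather than freezing the last value; the
component terms are still reported for diagnosis. When both rules fire
on the same frame, the reason is recorded as `coherent_motion`: global
agreement of motion vectors is the more specific indication of
self-motion, while overstimulation alone can accompany any large
stimulus.

## Lateral inhibition and its delay

Each layer's inhibitory hemicircle is the set of lattice offsets with
Euclidean length ≤ 3 strictly on one side of the focal element — exactly
11 offsets, confirmed by enumeration; the other three layers are exact
quarter-turn rotations (equal up to float summation order at run time).
`I_dist = 0.35 · Σ E_k/d_k` is sampled from the **current** step's
thresholded, cluster-filtered e-layer and then stored; it first acts on
the **next** step's e-potentials — the one-processing-step delay that
creates direction selectivity. Stored inhibition decays by
`2 × counter`; when fresh inhibition exceeds the decayed value by more
than 1.5 it replaces the store and the counter restarts, else the
counter advances by one per step. Negative decayed inhibition and
negative i-potentials are clamped to zero. An array with inhibitors on
its right responds to rightward motion: excitation trails the object,
so its delayed inhibition lands behind the preferred-direction path and
on top of the null-direction path.

## Motion vectors, coherence, shadows

A vector exists where the four layers together hold more than 9 active
elements (i > 0.1) within radius 3. One layer dominating every other by
strictly more than 4 sets the vector; exactly two dominating layers 90°
apart set the bisecting diagonal; opposed (180°) dominance is
contradictory and yields no vector. Coherence takes the maximum, over
the eight directions, of the fraction of vector-bearing elements within
±45° — a window of three adjacent directions. Note the structural
consequence: if vectors concentrate in two perpendicular cardinal
directions, the diagonal window between them collects both masses, so
minimal synthetic scenes with little directional diversity are flagged
as coherent far more readily than natural footage, where flow spreads
over many directions. Shadow classification fires when strictly more
than 20% of the elements in the lower half of the zone (rows below the
zone-center row) carry vectors in {225°, 270°, 315°}; those elements get
e- and i-potentials zeroed before the risk and steering sums of the same
step. Steering advice is withheld on suspended frames; the raw force is
still reported.

## Synthetic study scenes

The generator produces the canonical looming-detector stimuli on a
110 × 200 element lattice at 29 frames/s — the working resolution of the
original traffic-film experiments — with a static noise background
(σ = 0.05 grey units) and a dark-object/bright-ground contrast of 0.75,
comfortably above the 0.7 threshold used for high-contrast material.

* **Looming square** — centred, growing from side 3 to 90 over 60
  frames, by default along the inverse time-to-contact law (constant
  approach speed), so expansion accelerates into the final frames.
  Because sub-element growth is rasterized, the per-frame risk trace is
  spiky; the meaningful signature, and what the tests assert, is the
  non-decreasing risk *envelope* with its peak in the final approach
  phase.
* **Translating bar** — a 40 × 10 bar (a car-sized silhouette at this
  resolution) crossing at 2.5 elements/frame. Its uniform motion
  direction triggers the coherent-motion rule on essentially every
  active frame, so the scene reports zero unsuspended risk — the
  crossing-object analogue of staying below any alert threshold.
  Direction selectivity is therefore validated on the layer state
  itself: the rightward-preferring layer's total i-potential exceeds
  the leftward one on every post-warm-up frame.
* **Camera shake** — a static scene of scattered high-contrast square
  patches (8 px on a 14 px grid) seen through random rigid shifts of up
  to ±3 elements. Patch edges survive the cluster filter and yield
  unanimous motion vectors, raising the coherent-motion flag with zero
  reported risk. A dense-noise texture variant instead excites nearly
  every element and drives the overstimulation rule.
* **Global flicker** — spatially uniform random luminance jumps:
  overstimulation without directional structure, so the overstimulation
  reason is observed in isolation.
* **Ground shadows** — full-road dark stripes appearing at a horizon
  line just below the image center and sweeping down at 3 elements/frame
  (stripe height 12, one stripe every 9 frames), darkening
  geometrically toward full contrast as the car drives into the shaded
  stretch; vertical scenery stripes drift outward through the side
  panels, which lie wholly outside the danger zone. For this scene the
  zone center sits at row 68, below the horizon, as a manually placed
  zone would for a camera aimed slightly downward: stripes then descend
  *toward* the zone center, so peak risk occurs mid-transit when the
  motion vectors that identify the stripe as a shadow are already
  established.

The shadow ablation (suppression on vs off) is run with the
coherent-motion suspension disabled in both arms. This isolates the
mechanism under test: a minimal stripe scene lacks the directional
diversity of real footage, and the coherence rule would otherwise
suspend both arms wholesale (see the structural note above). Within the
ablation, suppression never increases any frame's risk, cuts classified
frames' risk roughly three-fold, and strictly lowers the peak; the peak
margin is modest (≈6%) because classification inevitably lags each
stripe's first frames.

What these scenes do **not** establish: performance on natural footage
with texture, lighting changes, and mixed object motion; behaviour at
other frame rates (the network has no time-constant rescaling rule, so
14 frames/s material is expected to respond more weakly); and any claim
about absolute risk magnitudes, which depend on scene geometry and
contrast.

## Numerical conventions and limitations

Everything is double precision and fully deterministic: reruns are
bit-identical, and all generator randomness flows from explicit seeds.
Kernel sums at frame borders treat outside elements as zero. Rotational
equivariance of the layers holds to float summation order (~1e-13);
discrete decisions (vector dominance, resets) could in principle flip on
exact ties of real-valued sums, which do not occur in the seeded scenes.
Known limitations: the danger zone is static per run (a speed-coupled
zone is a configuration hook only); the steering force is exported
unscaled, leaving gain to the downstream controller; vectors exist only
at 45° precision; and the fixed thresholds (0.5, 0.1, 1.0, 6, margins 4
and counts 9/10/15) are the published operating point — no attempt is
made to re-fit them.
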