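# Methods

## Model overview

`retinahaze` implements a feed-forward model of the retinal circuit applied to
single-image haze removal.  The cascade is: joint max-normalization of the RGB
input → photoreceptor sampling (cone channels R, G, B; rod luminance L;
diffuse-bipolar yellow Y = (R+G)/2) → ON/OFF bipolar difference-of-Gaussians
(DOG) filtering → rod-driven AII amacrine gain modulation → single-opponent
ganglion cells with disinhibitory subunit surrounds → luminance-weighted
fusion of the ON and OFF pathways.  All stages are pointwise or convolutional
operations on float64 planes; the whole pipeline is a pure, deterministic
function of the image and its configuration.

The division of labour among the stages is the scientific core of the model:
the unbalanced DOG attenuates the spatially smooth airlight component (a
uniform field c becomes exactly c·(1−k)); the reciprocal amacrine gains
(ε + BP_L multiplicative on ON, divisive on OFF) restore local contrast; and
the opponent ganglion stage recovers colour saturation while the subunit
mutual inhibition makes the surround inhibition adaptive to stimulus
structure.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `bipolar.sigma_cen` | 0.5 | px | DOG centre width |
| `bipolar.sigma_sur` | 1.0 | px | DOG surround width |
| `bipolar.k` | 0.3 | — | surround sensitivity = haze-removal strength |
| `amacrine.epsilon` | 0.5 | — | gain offset; keeps the modulator near 1 |
| `ganglion.r_cen/r_sur/r_sub` | 1 / 3 / 1 | px | RF radii; σ = r/3, support (2r+1)² |
| `ganglion.A_cen`, `A_s` | 2.0, 2.0 | — | centre and surround sensitivities |
| `ganglion.A_u_on`, `A_u_off` | 0.7, 0.5 | — | subunit (disinhibition) sensitivities |
| `output.mode` | clip | — | final range handling (`clip` or `rescale`) |

Larger `k` removes more haze but more detail; the amacrine stage exists to buy
that detail back.  `A_u` controls how strongly large uniform surrounds quench
their own inhibition; the ON pathway uses a larger value than OFF.

## Numerical choices

* **Boundary policy.** All convolutions use mirror (edge-inclusive reflect)
  padding.  This preserves uniform fields exactly and avoids the artificial
  dark frame that zero padding would inject into centre–surround differences
  at image borders.
* **Kernel truncation.** Where a radius is specified (ganglion stage) the
  support is exactly (2r+1)² with σ = r/3; where only σ is specified (bipolar
  stage) the radius is ceil(3σ).  Kernels are renormalized to sum to 1 after
  truncation, so constant inputs are preserved and the c·(1−k) identity is
  exact.
* **Rectification order.** The subunit rectification max(0, ·) is applied
  pointwise *before* surround pooling, per the cascade order; the ganglion
  output rectification follows the opponent subtraction.
* **Normalization scope.** Bipolar responses are rectified and then each
  polarity is divided by the joint maximum of its cone (R, G, B) planes; the
  Y and L planes are divided by that same joint maximum so relative scales
  within a polarity are preserved, and BP_L stays in [0, 1] as the amacrine
  gain expects.  No re-normalization occurs after the amacrine or ganglion
  stages; the final clip handles range.
* **Colour output.** The pathway-combination equations produce a scalar
  (channel-averaged) output; a colour result requires applying the fusion
  weight channel-wise to each GC_c/GC'_c pair.  The channel-wise reading is
  implemented (it is the only one consistent with a colour model output) and
  the channel mean is kept as a diagnostic pathway output.
* **Fusion weight.** w = f_L of the *normalized input*, not of any processed
  plane: the rod path feeds the fusion directly.
* **Degenerate inputs.** All-zero images, and inputs for which a polarity's
  joint cone maximum vanishes (e.g. a perfectly white image has no OFF
  response), raise a degenerate-input error rather than dividing by zero.

## Synthetic scenes and haze synthesis

Hazy fixtures follow the atmospheric scattering model I = J·t + A·(1−t) with
white airlight and transmission t = 0.8·d from a disparity plane d normalized
to span [0, 1].  The scene generator emulates stereo-benchmark-like content
at desk scale: 6 saturated, piecewise-constant rectangles/discs (exercising
the opponent channels) over a lightly textured background, each object
assigned a depth layer (nearer → larger d), with the disparity plane smoothed
(Gaussian, σ = 1) to avoid step artifacts.  Scenes are bit-reproducible in
the seed.

What the generator does *not* emulate: natural image statistics, shading,
specularity, depth-dependent texture gradients, sensor noise, or non-uniform
airlight.  Passing the recovery tests therefore shows the directional
behaviour of the model under the scattering model — lower MSE to ground truth
and higher local contrast than the hazy input — not photographic-quality
restoration of real scenes.

Because the background receives d = 0 after normalization, its transmission
is 0 and the hazy image there is pure airlight: no enhancement method can
recover that content without inverting the physical model, which this model
deliberately does not do.  The end-to-end MSE improvement is accordingly
modest (the unrecoverable region dominates the error), while the local
contrast gain (~1.3× mean local 5×5 luminance standard deviation at the
default parameters, 128×128 scenes, 5 seeds) is the robust signature.

## In-silico electrophysiology

Both protocols drive the ganglion stage directly from the photoreceptor
channels, so the measured response is a pure function of the opponent
cascade; a flag allows routing through the bipolar/amacrine front end.
Responses are read from the R channel at the centre pixel of the stimulus.
Both runners are deterministic.

**Area–response.**  Geometry: centre/surround/subunit radii 3/10/3 px
(σ = 1, 10/3, 1), A_s = 3, A_cen = 1, on a 25×25 patch.  The stimulus is a
fixed red disc covering the RF centre plus an equi-luminant green annulus
(red (1,0,0) and green (0,1,0) have equal rod luminance) extending to the
stimulus radius over a dark field — the classical area-summation protocol:
growing the stimulus progressively recruits the inhibitory surround.  With
A_u = 0 the response falls monotonically beyond the centre and never
recovers; with increasing A_u the curves are pointwise ordered and a
secondary rise appears at large radii.  The model has an intrinsic
disinhibition threshold here: for a full-intensity green surround the
interior subunit activity is bounded below by 1−A_u, so the pooled
inhibition A_s·m·(1−A_u) (m ≈ 0.66, the surround-kernel mass beyond the
centre disc) exceeds the maximal centre drive (≈ 0.99) whenever
A_u ≲ 1 − 1/(A_s·m) ≈ 0.5.  Below that value the large-radius response sits
at the rectification floor and no secondary rise can occur; at A_u = 0.6 and
0.8 the rise is present (≈ 0.003 and 0.031 respectively).

**Dispersion.**  Geometry: radii 1/3/1 (σ = 1/3, 1, 1/3), A_cen = 1,
A_u = A_s/2, on a 5×5 patch with a red 3×3 block covering the full RF centre.
The white foreground pattern holds its total flux fixed (default 16, i.e.
intensity 0.64 when fully dispersed) while its spatial spread grows with the
dispersive angle: the pattern interpolates linearly between the most
concentrated representable configuration (centre-outward Chebyshev rings
filled to intensity 1) and the uniform spread.  Flux conservation is exact by
construction.  Two provable consequences at A_s = 2 (hence A_u = 1): the
white-over-centre concentration maximizes the pooled opponent inhibition, and
since the subunit term G − blur(G) vanishes for the uniform pattern, the
pooled inhibition scales as (1−s) in the spread fraction s — so the response
with disinhibition increases strictly with angle.  Without disinhibition
(A_u = 0) the surround inhibition exceeds the centre drive at every angle and
the response is exactly constant at the rectification floor, reproducing the
flat no-disinhibition curve.  Only ordinal properties of these curves are
asserted; absolute values depend on the (under-determined) pattern geometry.

## Design choices made where the design was open

* Fig-style experiment sizes "3, 10, 3" are read as *radii* (σ = 1, 10/3, 1).
  Reading them as diameters makes the subunit kernel effectively a delta
  function (σ = 1/6·size) and suppresses the disinhibition signatures; the
  radii reading yields the textbook suppression-and-recovery curves.  The
  5×5-patch dispersion geometry "3×3, 7×7, 3×3" is read as region side
  lengths (radii 1/3/1), the only reading compatible with the patch size.
* Grayscale inputs are replicated to three channels rather than rejected, so
  the pipeline runs on luminance-only imagery.
* ε is fixed at 0.5 and not swept; it is a guard against division by zero
  with a near-unity operating point, not a tuning knob (overridable in the
  config for experimentation).
* The OFF ganglion population applies the identical opponent wiring to the
  modulated OFF planes — the only self-consistent symmetric reading.
* Problem sizes in the tests and the acceptance script (128×128 scenes,
  5 seeds, 25×25 stimulus patches) were chosen as the smallest sizes at which
  every signature is comfortably resolved.

## Known limitations

* The model enhances; it does not invert the scattering model, so regions of
  near-zero transmission remain unrecoverable and dense haze is only
  partially cleared.
* Receptive-field sizes are fixed; contrast-adaptive RF sizing (which would
  help with heterogeneous heavy haze) is out of scope.
* Cortical integration of the ON and OFF streams is not modelled; fusion is
  a pixel-wise luminance-weighted combination.
* No colour management: camera RGB is equated with cone inputs.
* Absolute output magnitudes depend on A_cen; `rescale` mode exists for
  visual inspection when parameters move the output range away from [0, 1].
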