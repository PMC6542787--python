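# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `impsem`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Impactor theory

A round-jet stage is described by orifice diameter `W`, jet-to-plate
ratio `S/W`, volumetric flow `Q`, critical Stokes number `Stk50` and
particle density `ρp`. The cut-off diameter solves
`d² Cc(d) = 9 μ W Stk50 / (ρp U)` with `U = 4Q/(πW²)`; because the
left-hand side is strictly increasing in `d`, the root is found with
Brent bisection on [1 nm, 100 μm] at 10⁻⁶ relative tolerance. A
closed-form no-slip solution (`Cc ≡ 1`) is available for checking.

Defaults and why:

- Air at 25 °C, 101.325 kPa: ρ = 1.184 kg m⁻³, μ = 1.849×10⁻⁵ Pa s,
  λ = 66.4 nm. `GasState.ambient()` scales ρ by the ideal-gas law, μ by
  a Sutherland law anchored at the 25 °C value, and λ by `T/P`.
- `Stk50 = 0.24` (√Stk50 = 0.49), the standard round-jet design value;
  configurable because published stages vary by ~10 %.
- `ρp = 1000 kg m⁻³` (PSL calibration spheres / unit density
  convention).
- Slip correction uses the three-constant Cunningham form
  `Cc = 1 + Kn(1.257 + 0.4 e^(−1.1/Kn))`.

Stage pressure is an input, never inferred: a final stage mounted
behind a critical orifice runs below ambient pressure, which raises λ
and Cc and lowers the cut-off substantially. At ambient conditions the
0.29 mm / 0.76 L min⁻¹ stage computes to D50 ≈ 172 nm and Re ≈ 3560;
with a known reduced stage pressure both move toward the sharper,
smaller-cut-off regime. The design check flags `Re` outside
[500, 3000] and `S/W` outside [1, 5].

## Collection-efficiency reduction

Fractional removal at one DMA setpoint is
`1 − mean(downstream)/mean(upstream)` over the ≥2-minute averaging
window, with first-order propagation of the two window standard
deviations. The plate efficiency is the difference between the
with-plate and without-plate removals; this assumes identical parasitic
losses in both configurations. The diameter uncertainty is the DMA
transfer-function half width, `Δd/d =` sample/sheath flow ratio
(default 0.1).

The sigmoid `Ceff = cmax/(1 + (D50/d)^(2s))` is fitted in two steps
mirroring the measurement procedure: `cmax` is the unweighted mean of
the efficiency points at or above the 120 nm plateau (its spread is the
cmax uncertainty), then `(D50, s)` are fitted by least squares with
`cmax` fixed — weighted by 1/σ² whenever all point uncertainties are
positive, unweighted otherwise (a joint three-parameter fit is
available behind a flag). Initial guesses are deterministic: `D50` from
linear interpolation of the cmax/2 crossing, `s = 2`. Negative
efficiency points (noise) are retained in the fit but flagged.
An optional diameter range restriction exists because points below
~50 nm are dominated by non-impaction losses; the default fits all
points.

Note a structural bias the package reproduces deliberately: when losses
and impaction compose multiplicatively (as in the generator, and in
reality), the difference method yields `(1 − wall_loss(d))·Ceff(d)`,
not `Ceff(d)`. The plateau estimate absorbs most of this into `cmax`
and the residual bias on `D50` is small compared with its fit
uncertainty (the acceptance run quantifies it at about +2 nm under the
default wall-loss model).

## Segmentation

Dark particles on a bright substrate (bright-field transmission
contrast) are segmented by a manually set global threshold or by a mean
adaptive threshold (pixel < local window mean − offset; window default
51 px, odd), followed by optional hole filling, 8-connected labelling,
a `min_area` filter (default 30 px) and border exclusion. The perimeter
is scikit-image's contour-length approximation; circularity `4πA/P²` is
clipped to 1 because discretization can push ideal disks slightly
above. Aspect ratio is the major/minor axis ratio of the inertia
ellipse. Touching particles are not split: co-deposition is treated as
a sampling condition to avoid (see sampling limits), not a watershed
problem. The reportable detection limit is the ECD of a `min_area`
component, `2·pixel_size·√(min_area/π)` ≈ 23 nm at 3.7 nm px⁻¹.

Blank-frame discard: a frame is dropped when its intensity standard
deviation falls below a floor (default 8 on the 8-bit scale) or its
mean leaves [1, 254]. This removes grid-bar frames where the detector
produces no signal; genuinely empty substrate frames with noise above
the floor are kept and contribute zero counts.

## Deposition pattern

Particle stage positions are the frame stage centre plus the pixel
offset of the centroid. The impact centre is the centroid of particles
with ECD ≥ 240 nm (strong focusing makes them a tight spot under the
nozzle); a user override always wins. Per image and ECD bin
(0–80–160–240–∞ nm by default) the number density is count/imaged area.
Radial distance is normalized by the orifice radius; a signed variant
(projection on the principal axis of the image positions) supports
line-scan plots.

Because the suspended film deflects between grid bars and redistributes
deposition locally, statistics are averaged per TEM grid square before
normalizing: squares are assigned by floor division of centre-aligned
stage coordinates by the 63.5 μm pitch of a 400-mesh grid, the
per-square mean per-image count is computed per bin, and fractions over
squares (summing to 1 per populated bin) are fitted against absolute
radius with a Gaussian `a·exp(−(r−r0)²/2σ²)`, bounds `r0 ≥ 0`,
`σ ∈ (0, 5]`. Fits wider than the radial data span are flagged
unconstrained (flat profiles); non-convergent bins return no fit. A
coverage check flags imaging sequences that stop short of 1.5 orifice
radii, the extent needed to capture the broad ring deposited by sizes
just above the cut-off. A chi-square test over equal-area annuli
provides the uniformity check used for sub-cut-off deposits.

## Size distributions

The SEM PSD pools ECD counts from all non-discarded frames of a
sequence onto linear bins (default width 10 nm) with √N uncertainties.
Pooling equals per-image averaging times the frame count; since every
downstream comparison normalizes to unit sum, the two conventions are
interchangeable and pooling keeps the √N bookkeeping exact. Bins whose
midpoint falls below the configured detection limit are flagged
`highly_uncertain`.

SMPS scans are averaged channel-wise (scan standard deviation as
uncertainty). Channel numbers `N_ch = dN/dlogDp · Δlog₁₀Dp` are
distributed onto linear bins proportionally to log-overlap, which
conserves the total number over the covered range to floating-point
precision. The collection-efficiency correction multiplies each bin by
`Ceff` at the geometric bin midpoint (arithmetic midpoint when the
lower edge is 0) and adds the fitted-curve parameter uncertainty as a
relative band in quadrature.

Shape comparison restricts both distributions to midpoints ≥ `D50`
(below it the image statistics are unreliable), normalizes to unit sum
— chosen over a fitted scale factor for transparency — and reports mode
positions, the peak-height ratio and the maximum absolute bin-fraction
difference.

## Concentration and sampling time

`Sp = tQC` with the loading limits 3.9×10⁶ and 6.7×10⁷ particles;
these were established for a PSD dominated by 100–200 nm particles and
may shift with particle bounce or very different size ranges — the
planner treats them as configuration. The optimal time is the geometric
midpoint of the window because the limits sit about a decade apart and
loading plots are log-log; an arithmetic option exists. The `A`
calibration sums `N_d/Ceff(d)` only over bins at or above the fitted
`D50` — sub-cut-off bins are excluded, never extrapolated. With
densities in μm⁻², `A` carries units of μm² (an effective collection
area); output metadata records this convention. Calibration and
estimation are exact algebraic inverses on a single sample; across
samples `A` is the mean with its sample standard deviation.

## Synthetic data: what it emulates, what it does not

- **Deposition model.** Above the cut-off, deposit radii are
  `|Normal(μ(d)·R, σ(d)·R)|` with uniform angle, with
  `μ(d) = exp(−(d−D50)/300 nm)` (clipped to [0, 1.5]) and
  `σ(d) = 0.4·exp(−(d−D50)/600 nm)`. These decays are configuration
  chosen to reproduce the qualitative focusing ordering — ring near one
  orifice radius just above the cut-off, tight central spot for the
  largest sizes — not fitted physics. Below the cut-off, deposition is
  uniform over a disc of 2R with a 0.1 collection fraction (diffusive
  deposition is roughly an order of magnitude sparser than impaction).
  The |Normal| law has a mild 1/r density cusp at the origin; area-
  uniform frame placement samples it without bias.
- **Micrograph rendering.** Anti-aliased dark disks/ellipses (area-
  preserving ellipse axes, so ECD equals the nominal diameter) at
  intensity 50 on a 200 substrate with additive Gaussian noise
  (default σ = 5); overlapping objects merge, as they do in real
  frames. Not modelled: focus/astigmatism blur, substrate texture,
  charging artefacts, agglomerate morphology.
- **CPC experiment.** Upstream series are Poisson around a mean count;
  downstream means compose wall loss and (with plate) `1 − Ceff`
  multiplicatively. Default wall loss `0.15 + 0.77·e^(−(d−20)/25 nm)`
  reproduces heavy diffusion/evaporation losses for 20 nm particles
  decaying to a 15 % floor above ~120 nm.
- **SMPS.** Multimodal lognormal `dN/dlogDp` on 64 geometric channels
  over 17.5–532.8 nm, per-scan multiplicative Gaussian noise (5 %),
  5 scans.

Passing tests on these fixtures demonstrates that the analysis chain is
internally consistent and unbiased under its own assumptions; it does
not validate the physics of a particular impactor, the bounce behaviour
of real particles, or segmentation robustness to real image artefacts.

## End-to-end cross-validation study

`synthetic.simulate_validation_study` draws deposit sizes from the
Ceff-corrected, rebinned SMPS distribution (the collection probability
is already contained in `Ceff`, so the model's separate sub-cut-off
thinning is disabled there), deposits them with the focusing law,
renders 96 frames of 1024² px at 3.7 nm px⁻¹ placed uniformly at random
inside the 1.5 R disc, segments them, and compares the pooled SEM
histogram with the corrected SMPS distribution above `D50`. Uniform
area placement keeps the per-image-averaged PSD an unbiased estimator
of the deposit PSD (a line scan through the exact centre would
over-weight the central density cusp). Default aerosol: modes
(140 nm, gsd 1.2, 1500 cm⁻³) and (210 nm, gsd 1.15, 400 cm⁻³);
150 000 deposited particles yield roughly 1 000–1 200 segmented
particles — enough that the modal bin is statistically stable while the
whole study runs in ~10 s. A one-bin mode shift (≈10 nm) can still
occur through counting noise plus occasional co-deposition merges,
matching the agreement level expected of the physical comparison.

## Known limitations

- No mobility-to-ECD conversion for non-spherical or non-unit-density
  particles; the cross-validation logic assumes spheres of unit
  density.
- Touching particles are counted as one; heavily loaded samples bias
  the PSD high. Use the sampling planner to avoid that regime.
- The difference method's wall-loss bias on `cmax` is inherent to the
  procedure and is documented rather than corrected.
- Stage pressure must be supplied for low-pressure stages; ambient
  defaults overestimate the final-stage cut-off.
- EDS/elemental classification, particle-bounce physics and nozzle CFD
  are out of scope.
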