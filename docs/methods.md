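# Methods

## Problem and model

Photoacoustic (PA) amplitude at a target is proportional to the local
optical fluence, which decays with depth. Quantitative PA imaging
therefore needs a depth-dependent fluence correction, but the effective
attenuation coefficient of the tissue in view is rarely known in advance.
`pafluence` implements a two-part remedy:

1. **Aperture geometry parameter.** Diffuse fluence from a source obeys a
   generalized law

       phi(r)  ∝  (c / r)^b · phi0 · exp(−mueff · r)

   where `mueff = sqrt(3·mua·(mua + (1−g)·mus))` and the power-law
   exponent `b` captures geometric spread: `b = 1` for an isotropic point
   source in a scattering-dominant medium, `b = 2` when absorption
   dominates (ballistic 1/r² spread), and `b = 0` for a plane source.
   Finite apertures fall in between because light "sidescatters" past the
   aperture edges; a 30 × 2 mm rectangular fiber output converges to
   `b ≈ 0.5`. `b` is intrinsic to the aperture: one voxel Monte Carlo run
   in *any* scattering-dominant medium fixes it, because every soft
   tissue in the bundled optics table has a scattering-to-absorption
   ratio above 100:1 and all such media share the same exponent.

2. **Displacement-based mueff estimation.** Imaging a fixed target while
   the optical path length `r` changes (tank translation, or tissue
   compression quantified as strain ΔL/L) yields an amplitude trace
   P(r). Multiplying by `r^b` removes the geometric term; the log of the
   remainder is linear in `r` with slope `−mueff`. A stride-1
   moving-window OLS gives local estimates; their arithmetic mean over
   the converged range is the bulk value used for compensation,
   `gain(r) = (r/r_ref)^b · exp(+mueff·(r − r_ref))`.

## Monte Carlo engine

Standard voxel hop–drop–spin transport: exponential step sampling against
the local `mut = mua + mus`, exact ray traversal across voxel boundaries,
`w·mua/mut` deposited per interaction, Henyey–Greenstein deflection
sampling (mean cosine `g`), uniform azimuth, Russian roulette below 1e−4
of the launch weight with survival probability 0.1 (standard MCML-style
values). Fluence uses the absorbed-weight estimator
`deposit / (mua · voxel volume)` per launched photon; it converges to the
track-length estimator and keeps per-voxel bookkeeping to one add.

Numerical choices worth knowing:

- **Boundary condition**: by default the outer faces apply unpolarized
  Fresnel reflection against an exterior index of 1 (air), including
  total internal reflection; transmitted photons terminate as escaped.
  This matters for the aperture geometry parameter: with a perfectly
  absorbing exterior (the index-matched mode, available as
  `boundary="matched"`), the illuminated face acts as a photon sink that
  steepens the shallow decay and raises the rectangular aperture's b
  from ~0.5 to ~0.58. The `b ≈ 0.5` plateau of a 30 × 2 mm aperture on a
  tissue surface is a property of the tissue–air interface, so the
  reflecting boundary is the physically meaningful default. Specular
  reflection of the incident beam at entry is not modeled (it is a
  constant factor on the launched power and cancels in every fit).
- **Boundary crossings overshoot by 1e−5 voxel** so the position always
  advances by more than a float ulp; direction components below 1e−8 are
  treated as in-plane. Without the overshoot, photons launched exactly on
  a voxel corner (the centered point source) with a tiny negative
  direction component stall in an infinite loop. The total path-length
  bias is ~2e−6 mm per crossing, orders of magnitude below the voxel size.
- **Energy audit**: launched = absorbed + escaped + roulette-killed −
  roulette-added holds to float precision; without the roulette terms the
  balance is statistical and is asserted at ≤0.5%.
- **NA model**: collimated face sources may tilt the launch direction by
  a polar angle uniform in solid angle up to `asin(NA/n)`; this is a
  declared model choice, adequate for the NA ≈ 0.2 fibers of interest.
- **Source placement**: the point source sits at the volume center; face
  sources (full-face plane, rectangular aperture) launch from the z = 0
  face, centered laterally. Placement is part of the source spec.

### Profile extraction and variance reduction

The raw convention samples fluence along the source normal at voxel
centers (`mode="axial"`). For fitting, the package exploits source
symmetry: spherical-shell averages for point sources (`mode="radial"`)
and per-depth lateral means for face sources (`mode="lateral_mean"`,
default patch ±3.0 mm along the 30 mm axis and ±0.4 mm along the 2 mm
axis of the rectangular aperture — inside the laterally consistent
central region; a quarter of the face for the plane). Shell/patch
averaging reduces Monte Carlo variance by two to three orders of
magnitude at fixed photon count, which is what makes desk-scale runs
(48 mm cube, 0.2 mm voxels, 3e5–1.5e6 photons, seconds to ~2 minutes on
one CPU) usable where the original problem size (72 mm cube, 0.1 mm
voxels, 1e8 photons, GPU) would be needed for single-column profiles.
That configuration remains expressible.

### Windowed fits

`estimate_b` regresses `ln(phi·exp(+mueff·r))` on `ln r` per window;
`estimate_mueff_windowed` regresses `ln(p·r^b)` on `r`. Windows default
to a **2 mm physical span** (20 samples at 0.1 mm pitch; the sample count
adapts as `round(2 mm / pitch)` at other pitches), slide one sample at a
time, and use the mean `r` of the window as the center. Windows
containing any non-positive sample are skipped and flagged rather than
clipped — clipping a noise floor would bias the log fit. The windowed b
values collapse to a scalar by the **median over window centers in
1–10 mm**: below ~1 mm (about one transport mean free path) the field is
pre-diffusive, beyond ~10 mm Monte Carlo profiles become photon starved;
the median is robust to the surviving far-field noise. The mueff
aggregation uses the arithmetic mean over the stated depth or strain
range, matching the "average over the constant regime" convention.

### Attenuation rate by regime

The windowed b fit divides out the known exponential decay of the medium.
In the diffusive regime (`mus' > mua`) that rate is `mueff`. When
absorption dominates reduced scattering, transport stays ballistic and
the profile decays at the Beer–Lambert rate `mua + mus` instead — the
diffusion formula does not govern that regime, and using it would make
the recovered exponent drift with depth instead of sitting at b = 2.
`dominant_attenuation()` selects the appropriate rate and is used
wherever "the known attenuation" is required for a defined-ratio medium.

## Diffusion oracles

Closed-form infinite-medium Green's functions (point:
`phi0·exp(−mueff·r)/(4πDr)` with `D = 1/(3(mua+mus'))`; plane:
`(mueff/2mua)·phi0·exp(−mueff·r)`) serve as independent oracles for the
Monte Carlo engine's log-slopes and for exact b = 1 / b = 0 fixtures. A
finite-aperture approximation superposes point kernels over the aperture
with a midpoint rule at 0.25 mm pitch (tunable); it reproduces the point
and plane limits to <1% and puts the 30 × 2 mm aperture's b in the 0.3–0.7
band, cross-checking the MC result by an independent route. No
extrapolated-boundary corrections are included; agreement is only claimed
beyond ~1 transport mean free path, matching the 1–10 mm fit range.

## Synthetic experiments

The generator emulates the two bench protocols with the forward model
`p = P0·(1/r)^b·exp(−mueff·r)`:

- **translation**: path sweeps 5 → 30 mm at 0.25 mm/s, 10 Hz framing
  (0.025 mm/frame, 1000 frames);
- **displacement**: path shrinks 20 → 17 mm at 0.10 mm/s, 10 Hz
  (0.01 mm/frame), reported against strain with a 20 mm initial length.

Noise is multiplicative Gaussian (σ = 0.05 default) plus a rectified
additive floor defaulting to 1% of the clean-trace peak; the bench noise
was never characterized, so this model is declared rather than derived.
The **milk ladder** assigns each concentration `mueff = 0.025 +
0.0016·c[% v/v]` (0.029–0.065 mm⁻¹ across 2.5–25%): the water baseline
reflects ~0.014 mm⁻¹ absorption at 1064 nm, and each percent of fat-free
milk adds a small amount of reduced scattering, keeping mueff linear in
concentration over this dilute range. The displacement analog uses the
bundled muscle properties at 700 nm (mueff = 0.353 mm⁻¹). An optional
near-field "ballistic bump" (excess decay above the diffusive model
within a configurable onset depth, off by default) reproduces the
near-source overestimate seen before photons become diffuse; larger onset
depths emulate weaker scattering, moving convergence deeper.

What the generator does *not* emulate: acoustic bandwidth and
attenuation, speckle, target localization error, refraction at the tank
wall, or any real milk/tissue optics beyond the stated law. Passing
recovery tests therefore demonstrates correctness of the inversion under
the stated forward and noise model, not field performance on instruments.

## Design decisions that were genuinely open

- Median (not mean) for collapsing windowed b; mean for the mueff
  aggregate — robustness where outliers are expected vs. the plain
  average of a converged plateau.
- Absorbed-weight rather than track-length fluence estimator (simpler
  bookkeeping; equivalent in expectation).
- OLS on log-amplitude rather than a nonlinear exponential fit —
  deterministic, matches the windowed-linearization procedure.
- Per-window exclusion (never clipping) of non-positive amplitudes.
- The proportionality constants c and P0 are absorbed into fit
  intercepts; no code object represents them.
- Optical path for the displacement mode is taken directly from the
  trace; no refraction correction.

## Known limitations

- No Fresnel/mismatched-boundary physics; no polarization; no
  time-resolved transport; CPU only.
- The two-parameter model (b, mueff) cannot separate mua from mus —
  that decomposition is ill-posed for this acquisition.
- Compensation treats depth as the optical path supplied per sample;
  oblique 2D illumination geometries (integrated US/PA probes with
  elevational fiber bundles) are out of scope.
- b for apertures is validated on the central ±7.5 mm of the field;
  accuracy degrades toward the lateral aperture edges.
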